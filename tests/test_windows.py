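"""Windowed heterozygosity: brute-force oracle, missing-data handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rohscan.windows import (
    build_windows,
    windows_from_sites,
    window_table_from_genotypes,
    sliding_mean,
    mean_het,
    read_windows,
    write_windows,
)
from conftest import write_vcf, write_bed, make_window_table


def brute_force_windows(chrom_lengths, window, mask, het_sites, missing_sites):
    """Site-by-site reference: iterate every bp of every chromosome."""
    out = []
    for chrom, L in chrom_lengths.items():
        callable_bp = set()
        for c, s, e in mask:
            if c == chrom:
                callable_bp.update(range(s, e))
        het = {p for c, p in het_sites if c == chrom}
        miss = {p for c, p in missing_sites if c == chrom}
        for start in range(0, L, window):
            end = min(start + window, L)
            n_call = n_het = 0
            for p in range(start, end):
                if p not in callable_bp or p in miss:
                    continue
                n_call += 1
                if p in het:
                    n_het += 1
            out.append((chrom, start, end, n_call, n_het))
    return out


class TestBuildWindows:
    def test_matches_site_by_site_count(self, tmp_path):
        """Window counts equal an exhaustive per-bp count on a random
        fixture with a patchy mask, missing genotypes, hom-alt and
        multi-allelic records."""
        rng = np.random.default_rng(7)
        chrom_lengths = {"chr1": 120_000, "chr2": 73_000}
        window = 20_000
        mask = []
        for chrom, L in chrom_lengths.items():
            pos = 0
            while pos < L:
                s = pos + int(rng.integers(0, 15_000))
                e = min(L, s + int(rng.integers(1_000, 30_000)))
                if e > s:
                    mask.append((chrom, s, e))
                pos = e + 1
        rows, het_sites, missing_sites = [], [], []
        for chrom, L in chrom_lengths.items():
            sites = np.sort(rng.choice(L, size=60, replace=False))
            for p in sites:
                p = int(p)
                r = rng.random()
                if r < 0.4:
                    rows.append((chrom, p, "A", "C", "0/1"))
                    het_sites.append((chrom, p))
                elif r < 0.55:
                    rows.append((chrom, p, "A", "C,G", "1/2"))  # het too
                    het_sites.append((chrom, p))
                elif r < 0.7:
                    rows.append((chrom, p, "A", "C", "./."))
                    missing_sites.append((chrom, p))
                else:
                    rows.append((chrom, p, "A", "C", "1/1"))  # hom-alt
        vcf = write_vcf(tmp_path / "t.vcf", chrom_lengths, rows)
        bed = write_bed(tmp_path / "m.bed", mask)
        got = build_windows(vcf, bed, window_size=window, min_callable=1)
        expected = brute_force_windows(
            chrom_lengths, window, mask, het_sites, missing_sites
        )
        assert len(got) == len(expected)
        for row, (chrom, start, end, n_call, n_het) in zip(
            got.itertuples(index=False), expected
        ):
            assert (row.chrom, row.start, row.end) == (chrom, start, end)
            assert row.n_callable == n_call, (chrom, start)
            assert row.n_het == n_het, (chrom, start)

    def test_multi_sample_vcf_rejected(self, tmp_path):
        vcf = write_vcf(tmp_path / "m.vcf", {"chr1": 1000},
                        [("chr1", 5, "A", "C", "0/1")], extra_samples=2)
        with pytest.raises(ValueError, match="3 samples"):
            build_windows(vcf)

    def test_unknown_contig_rejected(self, tmp_path):
        vcf = write_vcf(tmp_path / "u.vcf", {"chr1": 1000},
                        [("chr1", 5, "A", "C", "0/1")])
        with pytest.raises(ValueError, match="chr1"):
            build_windows(vcf, chrom_lengths={"chr2": 1000})

    def test_unsorted_vcf_rejected(self, tmp_path):
        vcf = write_vcf(tmp_path / "s.vcf", {"chr1": 1000},
                        [("chr1", 500, "A", "C", "0/1"),
                         ("chr1", 5, "A", "C", "0/1")])
        with pytest.raises(ValueError, match="sorted"):
            build_windows(vcf)

    def test_haploid_x_genotypes_not_het(self, tmp_path):
        vcf = write_vcf(tmp_path / "x.vcf", {"chrX": 60_000},
                        [("chrX", 10, "A", "C", "1"),
                         ("chrX", 20, "A", "C", "0/1")])
        rec = build_windows(vcf, min_callable=1)
        assert rec.n_het.sum() == 1  # only the diploid-looking error call
        assert rec.is_x.all()

    def test_snv_only_skips_indels(self, tmp_path):
        vcf = write_vcf(tmp_path / "i.vcf", {"chr1": 60_000},
                        [("chr1", 10, "A", "ACGT", "0/1"),
                         ("chr1", 20, "A", "C", "0/1")])
        assert build_windows(vcf, min_callable=1).n_het.sum() == 2
        assert build_windows(vcf, min_callable=1, snv_only=True).n_het.sum() == 1


class TestWindowsFromSites:
    def test_direct_ratio_at_threshold(self):
        """10 het / 50,000 callable = 0.0002, the strict threshold."""
        rec = windows_from_sites(
            {"chr1": 50_000}, {"chr1": np.arange(10) * 1000}
        )
        assert rec.het.iloc[0] == pytest.approx(2e-4)

    def test_window_outside_mask_is_no_data(self):
        rec = windows_from_sites(
            {"chr1": 100_000}, {}, mask_intervals={"chr1": np.array([[0, 50_000]])}
        )
        assert rec.n_callable.tolist() == [50_000, 0]
        assert np.isnan(rec.het.iloc[1])

    def test_partition_covers_chromosome(self):
        rec = windows_from_sites({"chr1": 123_456}, {})
        assert (rec.end - rec.start).sum() == 123_456
        assert rec.start.iloc[0] == 0
        assert (rec.start.values[1:] == rec.end.values[:-1]).all()

    def test_missing_gt_excluded_from_both_counts(self):
        rec = windows_from_sites(
            {"chr1": 50_000},
            {"chr1": np.array([10, 20])},
            missing_positions={"chr1": np.array([30, 40])},
        )
        assert rec.n_callable.iloc[0] == 49_998
        assert rec.n_het.iloc[0] == 2

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_count_invariants(self, data):
        L = data.draw(st.integers(10, 5_000))
        w = data.draw(st.integers(5, 2_000))
        n_sites = data.draw(st.integers(0, 50))
        seed = data.draw(st.integers(0, 2**16))
        rng = np.random.default_rng(seed)
        het = rng.choice(L, size=min(n_sites, L), replace=False)
        miss = rng.choice(L, size=min(10, L), replace=False)
        het = np.setdiff1d(het, miss)
        mc = data.draw(st.integers(1, w))
        rec = windows_from_sites(
            {"c": L}, {"c": het}, missing_positions={"c": miss},
            window_size=w, min_callable=mc,
        )
        assert ((rec.n_het >= 0) & (rec.n_het <= rec.n_callable)).all()
        assert (rec.n_callable <= rec.end - rec.start).all()
        defined = rec.het.notna()
        assert (defined == (rec.n_callable >= mc)).all()
        assert (rec.end - rec.start).sum() == L
        assert rec.n_het.sum() == het.size


class TestMissingDataInvariance:
    def test_random_missingness_leaves_mean_unbiased(self, small_sim):
        """Deleting callable sites at random must not shift E[het]."""
        cfg, truth, genotypes, records = small_sim
        base = mean_het(records, "autosomes")
        rng = np.random.default_rng(99)
        thinned_het, thinned_miss = {}, {}
        for chrom, L in genotypes.chrom_lengths.items():
            extra = rng.choice(L, size=L // 5, replace=False)  # drop 20%
            old_miss = genotypes.missing[chrom]
            thinned_miss[chrom] = np.union1d(old_miss, extra)
            thinned_het[chrom] = np.setdiff1d(genotypes.het[chrom], extra)
        rec2 = windows_from_sites(
            genotypes.chrom_lengths, thinned_het,
            missing_positions=thinned_miss, x_name=cfg.x_name,
        )
        thinned = mean_het(rec2, "autosomes")
        n_call = rec2.loc[~rec2.is_x, "n_callable"].sum()
        se = np.sqrt(base * (1 - base) / n_call)
        assert abs(thinned - base) < 4 * se


class TestMeanHet:
    def test_weighted_mean_hand_example(self):
        rec = make_window_table([10 / 50_000, 30 / 50_000])
        assert mean_het(rec, "autosomes") == pytest.approx(4e-4)

    def test_all_zero(self):
        rec = make_window_table([0.0, 0.0, 0.0])
        assert mean_het(rec) == 0.0

    def test_equals_concatenated_window(self, small_sim):
        """Weighted mean == het of one giant window over the same sites."""
        _, _, genotypes, records = small_sim
        auto = records[~records.is_x & records.het.notna()]
        assert mean_het(records, "autosomes") == pytest.approx(
            auto.n_het.sum() / auto.n_callable.sum(), rel=0, abs=0
        )

    def test_empty_subset_errors(self):
        rec = make_window_table([np.nan, np.nan])
        with pytest.raises(ValueError, match="no defined windows"):
            mean_het(rec)


class TestSlidingMean:
    def test_constant_series_is_identity(self):
        rec = make_window_table([0.002] * 30)
        sm = sliding_mean(rec, span=500_000)
        assert np.allclose(sm.het_smooth, 0.002)

    def test_single_defined_window_keeps_value(self):
        rec = make_window_table([np.nan, 0.0015, np.nan])
        sm = sliding_mean(rec, span=150_000)
        assert sm.het_smooth.iloc[1] == pytest.approx(0.0015)

    def test_alternating_values_average_interior(self):
        rec = make_window_table([0.001, 0.003] * 6)
        sm = sliding_mean(rec, span=200_000)  # 4-window span
        assert np.allclose(sm.het_smooth.iloc[2:-2], 0.002)

    def test_does_not_cross_chromosomes(self):
        a = make_window_table([0.001] * 4, chrom="chr1")
        b = make_window_table([0.005] * 4, chrom="chr2")
        sm = sliding_mean(pd.concat([a, b], ignore_index=True), span=200_000)
        assert np.allclose(sm.loc[sm.chrom == "chr1", "het_smooth"], 0.001)
        assert np.allclose(sm.loc[sm.chrom == "chr2", "het_smooth"], 0.005)

    def test_span_below_window_width_errors(self):
        rec = make_window_table([0.001] * 4)
        with pytest.raises(ValueError, match="span"):
            sliding_mean(rec, span=10_000)


class TestRoundTrip:
    def test_tsv_round_trip(self, small_sim, tmp_path):
        *_, records = small_sim
        p = tmp_path / "w.tsv"
        write_windows(records, p)
        back = read_windows(p)
        pd.testing.assert_frame_equal(
            back, records.reset_index(drop=True), check_exact=False
        )
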