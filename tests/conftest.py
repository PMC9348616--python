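"""Shared fixtures: tiny hand-written VCF/mask files and window tables."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from rohscan import SimConfig, sample_tracts, synthesize_genotypes
from rohscan.windows import window_table_from_genotypes


def write_vcf(path: Path, contigs: dict[str, int], rows, sample: str = "s1",
              extra_samples: int = 0) -> Path:
    """Minimal VCF v4.2 writer for hand-crafted test inputs.

    ``rows`` are (chrom, pos0, ref, alt, gt) with 0-based positions; the
    same GT string is repeated for any extra samples.
    """
    names = [sample] + [f"s{i + 2}" for i in range(extra_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for chrom, pos0, ref, alt, gt in rows:
            gts = "\t".join([gt] * (1 + extra_samples))
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def write_bed(path: Path, intervals) -> Path:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    return path


def make_window_table(het_values, n_callable=50_000, window=50_000,
                      chrom="chr1", is_x=False) -> pd.DataFrame:
    """Window table from a list of het values (NaN = no data).

    ``n_het`` is back-computed so that ``n_het / n_callable`` equals the
    requested het exactly; undefined windows get zero callable sites.
    """
    rows = []
    for i, h in enumerate(het_values):
        if h is None or (isinstance(h, float) and np.isnan(h)):
            nc, nh, hv = 0, 0, np.nan
        else:
            nc = n_callable if np.isscalar(n_callable) else n_callable[i]
            nh = int(round(h * nc))
            hv = nh / nc
        rows.append({"chrom": chrom, "start": i * window, "end": (i + 1) * window,
                     "n_callable": nc, "n_het": nh, "het": hv, "is_x": is_x})
    return pd.DataFrame(rows)


def interval_total(intervals) -> int:
    return sum(e - s for s, e in intervals)


def interval_jaccard(a: dict, b: dict) -> float:
    """bp Jaccard of two {chrom: [(start, end), ...]} interval sets."""
    inter = union = 0
    for chrom in set(a) | set(b):
        ia = sorted(a.get(chrom, []))
        ib = sorted(b.get(chrom, []))
        inter += _inter_len(ia, ib)
        union += interval_total(ia) + interval_total(ib)
    union -= inter
    return inter / union if union else float("nan")


def _inter_len(ia, ib) -> int:
    i = j = out = 0
    while i < len(ia) and j < len(ib):
        s = max(ia[i][0], ib[j][0])
        e = min(ia[i][1], ib[j][1])
        if e > s:
            out += e - s
        if ia[i][1] < ib[j][1]:
            i += 1
        else:
            j += 1
    return out


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic desk-scale simulation shared across tests."""
    cfg = SimConfig(
        chrom_lengths={f"chr{i + 1}": 4_000_000 for i in range(5)},
        x_name="chrX",
        x_length=4_000_000,
        g=10.0,
        f_target=0.2,
        seed=11,
    )
    truth = sample_tracts(cfg)
    genotypes = synthesize_genotypes(truth, cfg)
    records = window_table_from_genotypes(genotypes)
    return cfg, truth, genotypes, records
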