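"""Missing-data-aware windowed heterozygosity from a single-sample VCF.

Per fixed-width window the estimator is

    het = n_het / n_callable

where ``n_het`` counts heterozygous genotypes and ``n_callable`` counts
positions that are inside the callable mask and not missing a genotype.
Sites with a missing genotype are excluded from numerator and denominator,
so random missingness leaves the expectation unchanged.  Windows with fewer
than ``min_callable`` callable sites carry no estimate (``het`` is NaN):
a masked desert is "no data", not "homozygous".

The window table is a pandas DataFrame with columns
``chrom start end n_callable n_het het is_x`` — the atomic record of the
whole pipeline.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .simulate import GenotypeSet

__all__ = [
    "WINDOW_COLUMNS",
    "build_windows",
    "windows_from_sites",
    "window_table_from_genotypes",
    "sliding_mean",
    "mean_het",
    "read_windows",
    "write_windows",
    "window_width",
]

WINDOW_COLUMNS = ["chrom", "start", "end", "n_callable", "n_het", "het", "is_x"]

DEFAULT_WINDOW = 50_000


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Sort and merge possibly-overlapping half-open intervals."""
    if iv.shape[0] == 0:
        return iv.reshape(0, 2).astype(np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out_s = [int(iv[0, 0])]
    out_e = [int(iv[0, 1])]
    for s, e in iv[1:]:
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.stack([out_s, out_e], axis=1).astype(np.int64)


def _coverage_at(bounds: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Callable bp in [0, x) for each boundary x, given merged intervals."""
    if intervals.shape[0] == 0:
        return np.zeros(bounds.size, dtype=np.int64)
    starts = intervals[:, 0]
    lens = intervals[:, 1] - intervals[:, 0]
    cum = np.concatenate([[0], np.cumsum(lens)])
    idx = np.searchsorted(starts, bounds, side="right")
    cov = cum[idx].astype(np.int64)
    has_prev = idx >= 1
    prev = idx[has_prev] - 1
    partial_missing = np.clip(
        intervals[prev, 1] - bounds[has_prev], 0, lens[prev]
    )
    cov[has_prev] -= partial_missing
    return cov


def _sorted_unique(a: np.ndarray) -> np.ndarray:
    """Sorted unique positions; no-op for already sorted-unique input."""
    if a.size <= 1:
        return a
    d = np.diff(a)
    if np.all(d > 0):
        return a
    a = np.sort(a)
    keep = np.empty(a.size, dtype=bool)
    keep[0] = True
    np.not_equal(a[1:], a[:-1], out=keep[1:])
    return a[keep]


def _points_in_intervals(pos: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    if intervals.shape[0] == 0 or pos.size == 0:
        return np.zeros(pos.size, dtype=bool)
    idx = np.searchsorted(intervals[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] = pos[ok] < intervals[idx[ok], 1]
    return ok


def windows_from_sites(
    chrom_lengths: dict[str, int],
    het_positions: dict[str, np.ndarray],
    missing_positions: dict[str, np.ndarray] | None = None,
    mask_intervals: dict[str, np.ndarray] | None = None,
    window_size: int = DEFAULT_WINDOW,
    min_callable: int | None = None,
    x_name: str = "chrX",
) -> pd.DataFrame:
    """Window table from per-chromosome site arrays.

    This is the counting core shared by the VCF reader and the simulator's
    in-memory path, so both routes apply identical semantics:

    * ``n_callable`` = mask bp in the window minus missing-genotype sites
      that lie inside the mask;
    * ``n_het`` counts heterozygous positions inside the mask and not
      missing;
    * ``mask_intervals=None`` means the whole chromosome is callable.

    Every bp of every chromosome belongs to exactly one window; the last
    window of a chromosome may be a partial one.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    if min_callable is None:
        min_callable = window_size // 10
    missing_positions = missing_positions or {}

    frames = []
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window_size))
        starts = np.arange(n_win, dtype=np.int64) * window_size
        ends = np.minimum(starts + window_size, length)
        if mask_intervals is not None and chrom in mask_intervals:
            iv = _merge_intervals(np.asarray(mask_intervals[chrom], dtype=np.int64))
            if iv.size and (iv[0, 0] < 0 or iv[-1, 1] > length):
                raise ValueError(
                    f"mask interval outside chromosome {chrom} (length {length})"
                )
        elif mask_intervals is not None:
            iv = np.empty((0, 2), dtype=np.int64)
        else:
            iv = np.array([[0, length]], dtype=np.int64)

        bounds = np.concatenate([starts, [length]])
        cov = _coverage_at(bounds, iv)
        n_callable = np.diff(cov)

        miss = np.asarray(missing_positions.get(chrom, np.empty(0)), dtype=np.int64)
        if miss.size:
            miss = _sorted_unique(miss)
            miss = miss[_points_in_intervals(miss, iv)]
            n_callable = n_callable - np.bincount(
                miss // window_size, minlength=n_win
            )

        het = np.asarray(het_positions.get(chrom, np.empty(0)), dtype=np.int64)
        if het.size:
            het = _sorted_unique(het)
            if het[0] < 0 or het[-1] >= length:
                raise ValueError(
                    f"heterozygous site outside chromosome {chrom} "
                    f"(length {length})"
                )
            keep = _points_in_intervals(het, iv)
            if miss.size:
                keep &= ~np.isin(het, miss, assume_unique=True, kind="sort")
            het = het[keep]
        n_het = np.bincount(het // window_size, minlength=n_win) if het.size else np.zeros(
            n_win, dtype=np.int64
        )
        if np.any(n_het > n_callable):
            raise ValueError(
                f"more heterozygous than callable sites in a window on {chrom}; "
                "mask and VCF disagree"
            )

        with np.errstate(invalid="ignore", divide="ignore"):
            het_vals = np.where(
                n_callable >= max(min_callable, 1),
                n_het / np.maximum(n_callable, 1),
                np.nan,
            )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_callable": n_callable.astype(np.int64),
                    "n_het": n_het.astype(np.int64),
                    "het": het_vals,
                    "is_x": chrom == x_name,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["window_size"] = int(window_size)
    out.attrs["min_callable"] = int(min_callable)
    return out


def window_table_from_genotypes(
    genotypes: GenotypeSet,
    window_size: int = DEFAULT_WINDOW,
    min_callable: int | None = None,
) -> pd.DataFrame:
    """Window table straight from a simulated genotype stream (no files).

    Missing sites are treated exactly as the fixture writer treats them:
    excluded from the callable denominator.
    """
    return windows_from_sites(
        chrom_lengths=genotypes.chrom_lengths,
        het_positions=genotypes.het,
        missing_positions=genotypes.missing,
        mask_intervals=None,
        window_size=window_size,
        min_callable=min_callable,
        x_name=genotypes.x_name,
    )


def _read_mask_bed(path, chroms: set[str]) -> dict[str, np.ndarray]:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
        comment="#",
    )
    out: dict[str, np.ndarray] = {}
    for chrom, grp in bed.groupby("chrom", sort=False):
        if chrom not in chroms:
            raise ValueError(f"mask chromosome {chrom!r} not in chromosome table")
        out[str(chrom)] = grp[["start", "end"]].to_numpy(dtype=np.int64)
    return out


def _is_snv(ref: str, alts) -> bool:
    if len(ref) != 1:
        return False
    for a in alts or ():
        if a is None:
            continue
        if len(a) != 1 or not a.isalpha():
            return False
    return True


def build_windows(
    vcf_path,
    mask_path=None,
    window_size: int = DEFAULT_WINDOW,
    min_callable: int | None = None,
    x_name: str = "chrX",
    chrom_lengths: dict[str, int] | None = None,
    snv_only: bool = False,
) -> pd.DataFrame:
    """Window table from a single-sample VCF plus an optional callable mask.

    Parameters
    ----------
    vcf_path:
        VCF v4.2 with exactly one sample and a GT field.  Contig lengths are
        taken from the header unless ``chrom_lengths`` overrides them.
    mask_path:
        BED of callable intervals (0-based half-open).  ``None`` means the
        whole genome is callable — appropriate only when the variant caller
        emitted every site.
    snv_only:
        Ignore records whose REF or called ALT alleles are not single
        bases; the site stays callable.

    Any genotype with two distinct called alleles counts as heterozygous;
    a genotype with any missing allele counts as a missing site.
    """
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ValueError(
                f"expected a single-sample VCF, got {len(samples)} samples"
            )
        if chrom_lengths is None:
            chrom_lengths = {
                name: contig.length
                for name, contig in vf.header.contigs.items()
            }
            if not chrom_lengths or any(
                length is None for length in chrom_lengths.values()
            ):
                raise ValueError(
                    "VCF header lacks contig lengths; pass chrom_lengths explicitly"
                )

        het_pos: dict[str, list[int]] = {}
        miss_pos: dict[str, list[int]] = {}
        seen_chroms: list[str] = []
        last_pos = -1
        for rec in vf:
            chrom = rec.chrom
            if chrom not in chrom_lengths:
                raise ValueError(
                    f"VCF record on {chrom!r} absent from chromosome table"
                )
            if not seen_chroms or seen_chroms[-1] != chrom:
                if chrom in seen_chroms:
                    raise ValueError(f"VCF not sorted: {chrom} appears twice")
                seen_chroms.append(chrom)
                last_pos = -1
            if rec.start < last_pos:
                raise ValueError(
                    f"VCF not sorted at {chrom}:{rec.pos}"
                )
            last_pos = rec.start
            if snv_only and not _is_snv(rec.ref or "", rec.alts):
                continue
            gt = rec.samples[0].get("GT")
            if gt is None or len(gt) == 0 or any(a is None for a in gt):
                miss_pos.setdefault(chrom, []).append(rec.start)
            elif len(set(gt)) > 1:
                het_pos.setdefault(chrom, []).append(rec.start)

    mask = None
    if mask_path is not None:
        mask = _read_mask_bed(mask_path, set(chrom_lengths))

    return windows_from_sites(
        chrom_lengths=chrom_lengths,
        het_positions={c: np.array(v, dtype=np.int64) for c, v in het_pos.items()},
        missing_positions={c: np.array(v, dtype=np.int64) for c, v in miss_pos.items()},
        mask_intervals=mask,
        window_size=window_size,
        min_callable=min_callable,
        x_name=x_name,
    )


def window_width(records: pd.DataFrame) -> int:
    """The uniform window width of a table (terminal partials excluded)."""
    widths = records["end"] - records["start"]
    return int(widths.max())


def sliding_mean(records: pd.DataFrame, span: int) -> pd.DataFrame:
    """Centered sliding mean of window heterozygosity for plotting.

    The mean at each window is taken over defined-het windows within
    ``span`` bp (``span // width`` windows), never crossing a chromosome
    boundary; undefined windows are excluded from the mean and get the mean
    of their defined neighbours.  Returns a copy with a ``het_smooth``
    column.
    """
    width = window_width(records)
    if span < width:
        raise ValueError(
            f"span ({span} bp) must be at least the window width ({width} bp)"
        )
    k = max(1, span // width)
    out = records.copy()
    out["het_smooth"] = (
        out.groupby("chrom", sort=False)["het"]
        .transform(lambda s: s.rolling(k, center=True, min_periods=1).mean())
    )
    return out


def mean_het(records: pd.DataFrame, subset: str = "autosomes") -> float:
    """Callable-site-weighted mean heterozygosity: sum n_het / sum n_callable.

    ``subset`` is ``"autosomes"``, ``"x"``, ``"all"``, or a boolean mask
    aligned with ``records``.  Only windows with a defined estimate enter
    the sums.
    """
    if isinstance(subset, str):
        if subset == "autosomes":
            sel = ~records["is_x"]
        elif subset == "x":
            sel = records["is_x"]
        elif subset == "all":
            sel = pd.Series(True, index=records.index)
        else:
            raise ValueError(f"unknown subset {subset!r}")
    else:
        sel = pd.Series(np.asarray(subset, dtype=bool), index=records.index)
    sel = sel & records["het"].notna()
    if not sel.any():
        raise ValueError("no defined windows in requested subset")
    sub = records.loc[sel]
    return float(sub["n_het"].sum() / sub["n_callable"].sum())


def write_windows(records: pd.DataFrame, path) -> None:
    records.to_csv(
        path, sep="\t", index=False, na_rep="NA", columns=WINDOW_COLUMNS
    )


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        na_values="NA",
        dtype={
            "chrom": str,
            "start": np.int64,
            "end": np.int64,
            "n_callable": np.int64,
            "n_het": np.int64,
            "het": float,
            "is_x": bool,
        },
    )
    missing_cols = set(WINDOW_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"window table missing columns: {sorted(missing_cols)}")
    return df
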