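"""Segment window heterozygosity tables into runs of homozygosity.

A window is *strict* when its heterozygosity is defined and below the
strict threshold (reference value 0.0002 per site).  A window is
*rescuable* when its heterozygosity is below the rescue threshold
(reference 0.0004) and the callable-weighted mean heterozygosity of the
surrounding 1 MB — centered on the window, including it, clipped at the
chromosome ends — is below the strict threshold.  An ROH segment is a
maximal run of strict windows in which *isolated* rescuable windows are
absorbed: rescued windows are never adjacent to one another and never form
a segment endpoint, so rescues can extend a run of homozygosity but never
create one.  Runs never cross chromosome boundaries and, by default, never
cross no-data windows.

``call_roh`` is the production implementation (vectorized classification,
linear scan).  ``roh_oracle`` is an independent reference that enumerates
every candidate interval and checks the run definition directly; it exists
so the two can be compared exhaustively in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import ThresholdCalibration
from .windows import window_width

__all__ = [
    "RohSegment",
    "call_roh",
    "roh_oracle",
    "segments_to_frame",
    "write_roh_bed",
    "read_roh_bed",
]

DEFAULT_MIN_REPORT_LEN = 1_000_000
DEFAULT_NEIGHBORHOOD = 1_000_000

# window classes
_NODATA, _HIGH, _STRICT, _RESCUABLE = 0, 1, 2, 3


@dataclass(frozen=True)
class RohSegment:
    """One run of homozygosity, on window boundaries, 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_windows: int
    n_rescued: int
    mean_het: float

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.n_rescued > self.n_windows:
            raise ValueError("n_rescued exceeds n_windows")


def _check_sorted(grp: pd.DataFrame, chrom: str) -> None:
    starts = grp["start"].to_numpy()
    ends = grp["end"].to_numpy()
    if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
        raise ValueError(f"windows on {chrom} are unsorted or overlapping")


def _classify_chrom(
    grp: pd.DataFrame,
    cal: ThresholdCalibration,
    width: int,
    neighborhood: int,
) -> np.ndarray:
    """Vectorized window classification for one chromosome."""
    starts = grp["start"].to_numpy(dtype=np.int64)
    ends = grp["end"].to_numpy(dtype=np.int64)
    n_het = grp["n_het"].to_numpy(dtype=np.int64)
    n_call = grp["n_callable"].to_numpy(dtype=np.int64)
    het = grp["het"].to_numpy(dtype=float)
    n = len(grp)

    defined = ~np.isnan(het)
    partial = (ends - starts) < width
    usable = defined & (~partial | (n_call >= width // 2))

    cls = np.full(n, _NODATA, dtype=np.int8)
    cls[usable] = _HIGH
    strict = usable & (het < cal.t_strict)
    cls[strict] = _STRICT

    cand = usable & ~strict & (het < cal.t_rescue)
    if np.any(cand):
        centers = (starts + ends) / 2.0
        lo = centers - neighborhood / 2.0
        hi = centers + neighborhood / 2.0
        j_lo = np.searchsorted(ends, lo, side="right")
        j_hi = np.searchsorted(starts, hi, side="left")
        cum_h = np.concatenate([[0], np.cumsum(n_het)])
        cum_c = np.concatenate([[0], np.cumsum(n_call)])
        region_h = cum_h[j_hi] - cum_h[j_lo]
        region_c = cum_c[j_hi] - cum_c[j_lo]
        ok = region_c > 0
        region_mean = np.full(n, np.inf)
        region_mean[ok] = region_h[ok] / region_c[ok]
        cls[cand & (region_mean < cal.t_strict)] = _RESCUABLE
    return cls


def _segments_from_classes(
    grp: pd.DataFrame,
    cls: np.ndarray,
    chrom: str,
    min_report_len: int,
    bridge_nodata: int,
) -> list[RohSegment]:
    """Linear scan turning a class string into trimmed, maximal segments."""
    n = len(cls)
    # rescuable windows adjacent to another rescuable can join no segment
    iso = cls == _RESCUABLE
    adj = np.zeros(n, dtype=bool)
    adj[:-1] |= iso[:-1] & iso[1:]
    adj[1:] |= iso[1:] & iso[:-1]
    member = (cls == _STRICT) | (iso & ~adj)

    runs: list[tuple[int, int]] = []  # inclusive window-index ranges
    i = 0
    while i < n:
        if not member[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and member[j + 1]:
            j += 1
        a, b = i, j
        while a <= b and cls[a] != _STRICT:
            a += 1
        while b >= a and cls[b] != _STRICT:
            b -= 1
        if a <= b:
            runs.append((a, b))
        i = j + 1

    if bridge_nodata > 0 and len(runs) > 1:
        merged = [runs[0]]
        for a, b in runs[1:]:
            pa, pb = merged[-1]
            gap = cls[pb + 1 : a]
            if 0 < gap.size <= bridge_nodata and np.all(gap == _NODATA):
                merged[-1] = (pa, b)
            else:
                merged.append((a, b))
        runs = merged

    starts = grp["start"].to_numpy(dtype=np.int64)
    ends = grp["end"].to_numpy(dtype=np.int64)
    n_het = grp["n_het"].to_numpy(dtype=np.int64)
    n_call = grp["n_callable"].to_numpy(dtype=np.int64)

    segments = []
    for a, b in runs:
        seg_start = int(starts[a])
        seg_end = int(ends[b])
        if seg_end - seg_start < min_report_len:
            continue
        idx = np.arange(a, b + 1)
        in_run = member[idx]  # excludes bridged no-data windows
        tot_c = int(n_call[idx][in_run].sum())
        tot_h = int(n_het[idx][in_run].sum())
        segments.append(
            RohSegment(
                chrom=chrom,
                start=seg_start,
                end=seg_end,
                n_windows=int(in_run.sum()),
                n_rescued=int((cls[idx] == _RESCUABLE)[in_run].sum()),
                mean_het=tot_h / tot_c if tot_c else float("nan"),
            )
        )
    return segments


def call_roh(
    records: pd.DataFrame,
    cal: ThresholdCalibration,
    min_report_len: int = DEFAULT_MIN_REPORT_LEN,
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
    bridge_nodata: int = 0,
    include_x: bool = False,
) -> list[RohSegment]:
    """Call runs of homozygosity from a window table.

    Parameters
    ----------
    records:
        Window table (sorted within chromosomes, non-overlapping).
    cal:
        Strict/rescue thresholds, calibrated or fixed.
    min_report_len:
        Segments shorter than this are dropped (default 1 MB, the usual
        F_ROH cutoff).  Segments of exactly this length are kept.
    neighborhood:
        Width in bp of the region whose mean heterozygosity must stay below
        the strict threshold for a window to be rescuable (default 1 MB).
    bridge_nodata:
        Allow runs to span up to this many consecutive no-data windows
        (default 0: no-data breaks every run).
    include_x:
        Segment the X chromosome too.  Off by default: in a male the X is
        haploid and trivially homozygous.
    """
    if cal is None:
        raise ValueError("a ThresholdCalibration is required")
    if min_report_len < 0:
        raise ValueError("min_report_len must be non-negative")
    if len(records) == 0:
        return []
    width = window_width(records)
    if neighborhood < width:
        raise ValueError("neighborhood must be at least one window wide")

    segments: list[RohSegment] = []
    for chrom, grp in records.groupby("chrom", sort=False):
        if grp["is_x"].any() and not include_x:
            continue
        grp = grp.reset_index(drop=True)
        _check_sorted(grp, str(chrom))
        cls = _classify_chrom(grp, cal, width, neighborhood)
        segments.extend(
            _segments_from_classes(
                grp, cls, str(chrom), min_report_len, bridge_nodata
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Independent reference implementation (tests only; no efficiency contract).
# ---------------------------------------------------------------------------


def _oracle_classify(grp: pd.DataFrame, cal, width: int, neighborhood: int) -> list[str]:
    """Per-window classes via direct per-window loops (no shared code)."""
    rows = list(grp.itertuples(index=False))
    classes = []
    for w in rows:
        if np.isnan(w.het):
            classes.append("nodata")
            continue
        if (w.end - w.start) < width and w.n_callable < width // 2:
            classes.append("nodata")
            continue
        if w.het < cal.t_strict:
            classes.append("strict")
            continue
        if w.het < cal.t_rescue:
            center = (w.start + w.end) / 2.0
            lo, hi = center - neighborhood / 2.0, center + neighborhood / 2.0
            th = tc = 0
            for v in rows:
                if v.end > lo and v.start < hi:
                    th += v.n_het
                    tc += v.n_callable
            if tc > 0 and th / tc < cal.t_strict:
                classes.append("rescuable")
                continue
        classes.append("high")
    return classes


def roh_oracle(
    records: pd.DataFrame,
    cal: ThresholdCalibration,
    min_report_len: int = DEFAULT_MIN_REPORT_LEN,
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
    include_x: bool = False,
) -> list[RohSegment]:
    """Reference ROH caller: enumerate intervals, keep the maximal valid ones.

    An interval of windows is valid when every window is strict or
    rescuable, both endpoints are strict, and no two rescuable windows are
    adjacent.  Reported segments are the valid intervals not contained in a
    longer valid interval.  Quadratic time; for tests only.
    """
    if len(records) == 0:
        return []
    width = window_width(records)
    segments: list[RohSegment] = []
    for chrom, grp in records.groupby("chrom", sort=False):
        if grp["is_x"].any() and not include_x:
            continue
        grp = grp.reset_index(drop=True)
        _check_sorted(grp, str(chrom))
        classes = _oracle_classify(grp, cal, width, neighborhood)
        n = len(classes)
        valid: list[tuple[int, int]] = []
        for i in range(n):
            if classes[i] not in ("strict", "rescuable"):
                continue
            for j in range(i, n):
                c = classes[j]
                if c not in ("strict", "rescuable"):
                    break
                if c == "rescuable" and j > i and classes[j - 1] == "rescuable":
                    break
                if classes[i] == "strict" and c == "strict":
                    valid.append((i, j))
        maximal = [
            (i, j)
            for (i, j) in valid
            if not any(
                (a <= i and j <= b) and (a, b) != (i, j) for (a, b) in valid
            )
        ]
        for i, j in sorted(maximal):
            seg_start = int(grp.loc[i, "start"])
            seg_end = int(grp.loc[j, "end"])
            if seg_end - seg_start < min_report_len:
                continue
            tot_c = int(grp.loc[i:j, "n_callable"].sum())
            tot_h = int(grp.loc[i:j, "n_het"].sum())
            segments.append(
                RohSegment(
                    chrom=str(chrom),
                    start=seg_start,
                    end=seg_end,
                    n_windows=j - i + 1,
                    n_rescued=sum(
                        1 for k in range(i, j + 1) if classes[k] == "rescuable"
                    ),
                    mean_het=tot_h / tot_c if tot_c else float("nan"),
                )
            )
    return segments


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "length": s.length,
                "n_windows": s.n_windows,
                "n_rescued": s.n_rescued,
                "mean_het": s.mean_het,
            }
            for s in segments
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "length",
            "n_windows",
            "n_rescued",
            "mean_het",
        ],
    )


def write_roh_bed(segments: list[RohSegment], path) -> None:
    """BED: chrom start end ROH_<n> length n_windows n_rescued mean_het."""
    with open(path, "w") as fh:
        for k, s in enumerate(segments, start=1):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tROH_{k}\t{s.length}\t"
                f"{s.n_windows}\t{s.n_rescued}\t{s.mean_het:.6g}\n"
            )


def read_roh_bed(path) -> list[RohSegment]:
    segments = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            segments.append(
                RohSegment(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    n_windows=int(f[5]),
                    n_rescued=int(f[6]),
                    mean_het=float(f[7]),
                )
            )
    return segments
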