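"""Inbreeding summaries: F_ROH, length spectrum, and tract-length dating.

F_ROH is the fraction of the autosomal genome inside runs of homozygosity
at or above a length cutoff; the denominator is autosomal bp in windows
with a defined heterozygosity estimate, so heavily masked regions count in
neither numerator nor denominator.

Dating rests on the expectation that an identity-by-descent tract from an
inbreeding event ``g`` generations back has exponential length with mean
``map_mb_per_morgan / (2 g)`` MB (default map scale 100 MB/Morgan): each
of the 2g meioses since the common ancestor breaks the tract at
recombination.  Inverting, a tract of L MB points to g = 100 / (2 L)
generations — a 5 MB tract to 10 generations, a 50 MB tract to 1.

When estimating the mean tract length from called ROH the raw mean is
biased: tracts are truncated by the reporting cutoff (only ROH >= cutoff
are seen) and censored by chromosome ends.  Both biases have an exact
correction for exponential lengths (memorylessness):

    mean = sum_i (L_i - cutoff) / #uncensored

where a segment touching a chromosome end counts as censored (it appears
in the numerator but not the denominator).  This is the maximum-likelihood
estimator for an exponential under left truncation and right censoring.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roh import RohSegment

__all__ = [
    "InbreedingSummary",
    "AgeEstimate",
    "summarize",
    "length_spectrum",
    "generations_from_length",
    "length_from_generations",
    "estimate_mean_tract_length",
    "estimate_generations",
    "proportion_heterozygous",
]

DEFAULT_CUTOFFS = (1_000_000, 5_000_000)
DEFAULT_MAP_MB = 100.0


@dataclass(frozen=True)
class AgeEstimate:
    """Generations since inbreeding implied by a tract length."""

    length_mb: float
    generations: float
    map_mb_per_morgan: float


@dataclass
class InbreedingSummary:
    """Headline summaries of one ROH analysis.

    Attributes
    ----------
    f_roh:
        Length cutoff (bp) -> fraction of autosomal defined-window bp
        inside ROH at least that long.
    spectrum:
        (bin_start_mb, bin_end_mb, total_roh_bp) in 1 MB bins.
    het_outside, het_inside:
        Callable-weighted mean heterozygosity of defined autosomal windows
        outside / inside ROH (NaN when a side is empty).
    frac_homozygous_windows:
        Fraction of defined autosomal windows below the strict threshold.
    frac_homoz_in_long_roh:
        Of those, the fraction lying in ROH >= ``long_roh_cutoff``.
    longest_roh:
        (chrom, length bp) of the longest segment, or None.
    """

    f_roh: dict[int, float]
    spectrum: list[tuple[float, float, int]]
    het_outside: float
    het_inside: float
    frac_homozygous_windows: float
    frac_homoz_in_long_roh: float
    longest_roh: tuple[str, int] | None
    denominator_bp: int = 0
    long_roh_cutoff: int = 5_000_000
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "f_roh": {str(k): v for k, v in self.f_roh.items()},
            "spectrum": [list(b) for b in self.spectrum],
            "het_outside": self.het_outside,
            "het_inside": self.het_inside,
            "frac_homozygous_windows": self.frac_homozygous_windows,
            "frac_homoz_in_long_roh": self.frac_homoz_in_long_roh,
            "longest_roh": list(self.longest_roh) if self.longest_roh else None,
            "denominator_bp": self.denominator_bp,
            "long_roh_cutoff": self.long_roh_cutoff,
            "extras": self.extras,
        }

    def write(self, path) -> None:
        def _clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, list):
                return [_clean(v) for v in x]
            return x

        with open(path, "w") as fh:
            json.dump(_clean(self.to_dict()), fh, indent=2)
            fh.write("\n")


def _window_in_segments(
    grp: pd.DataFrame, segs: list[RohSegment]
) -> np.ndarray:
    """Which windows of one chromosome lie inside a segment.

    Segment boundaries are window boundaries, so membership is by window
    start position.
    """
    starts = grp["start"].to_numpy(dtype=np.int64)
    inside = np.zeros(starts.size, dtype=bool)
    for s in segs:
        inside |= (starts >= s.start) & (starts < s.end)
    return inside


def summarize(
    records: pd.DataFrame,
    segments: list[RohSegment],
    cutoffs=DEFAULT_CUTOFFS,
    t_strict: float = 2e-4,
    long_roh_cutoff: int = 5_000_000,
) -> InbreedingSummary:
    """Compute the summary block from a window table and called ROH."""
    rec_chroms = set(records["chrom"].unique())
    seg_chroms = {s.chrom for s in segments}
    if seg_chroms - rec_chroms:
        raise ValueError(
            f"segments on chromosomes missing from the window table: "
            f"{sorted(seg_chroms - rec_chroms)}"
        )

    auto = records.loc[~records["is_x"]].copy()
    defined = auto.loc[auto["het"].notna()]
    denom_bp = int((defined["end"] - defined["start"]).sum())

    cutoffs = sorted(int(c) for c in cutoffs)
    f_roh: dict[int, float] = {}
    for c in cutoffs:
        bp = sum(s.length for s in segments if s.length >= c)
        f_roh[c] = bp / denom_bp if denom_bp else 0.0

    by_chrom: dict[str, list[RohSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)

    inside_mask = pd.Series(False, index=auto.index)
    for chrom, grp in auto.groupby("chrom", sort=False):
        segs = by_chrom.get(str(chrom), [])
        if segs:
            inside_mask.loc[grp.index] = _window_in_segments(grp, segs)

    def _weighted(sub: pd.DataFrame) -> float:
        sub = sub.loc[sub["het"].notna()]
        tot = sub["n_callable"].sum()
        return float(sub["n_het"].sum() / tot) if tot else float("nan")

    het_inside = _weighted(auto.loc[inside_mask])
    het_outside = _weighted(auto.loc[~inside_mask])

    homoz = defined["het"] < t_strict
    n_def = int(len(defined))
    frac_homoz = float(homoz.sum() / n_def) if n_def else float("nan")

    long_segs = {
        chrom: [s for s in segs if s.length >= long_roh_cutoff]
        for chrom, segs in by_chrom.items()
    }
    n_homoz_in_long = 0
    for chrom, grp in defined.groupby("chrom", sort=False):
        segs = long_segs.get(str(chrom), [])
        if not segs:
            continue
        inside = _window_in_segments(grp, segs)
        n_homoz_in_long += int((inside & (grp["het"] < t_strict)).sum())
    n_homoz = int(homoz.sum())
    frac_in_long = n_homoz_in_long / n_homoz if n_homoz else float("nan")

    longest = max(segments, key=lambda s: s.length, default=None)
    return InbreedingSummary(
        f_roh=f_roh,
        spectrum=length_spectrum(segments),
        het_outside=het_outside,
        het_inside=het_inside,
        frac_homozygous_windows=frac_homoz,
        frac_homoz_in_long_roh=frac_in_long,
        longest_roh=(longest.chrom, longest.length) if longest else None,
        denominator_bp=denom_bp,
        long_roh_cutoff=int(long_roh_cutoff),
    )


def length_spectrum(
    segments: list[RohSegment], bin_mb: float = 1.0
) -> list[tuple[float, float, int]]:
    """Total ROH bp per length bin (left-closed [k, k+1) MB by default).

    Each segment's *full* length is added to the bin containing its length.
    Empty bins between occupied ones are reported as zeros so the spectrum
    plots directly.
    """
    if bin_mb <= 0:
        raise ValueError(f"bin width must be positive, got {bin_mb}")
    if not segments:
        return []
    lengths_mb = np.array([s.length / 1e6 for s in segments])
    lo = math.floor(lengths_mb.min() / bin_mb)
    hi = math.floor(lengths_mb.max() / bin_mb)
    out = []
    for k in range(lo, hi + 1):
        b0, b1 = k * bin_mb, (k + 1) * bin_mb
        bp = int(
            sum(s.length for s, L in zip(segments, lengths_mb) if b0 <= L < b1)
        )
        out.append((b0, b1, bp))
    return out


def generations_from_length(
    length_mb: float, map_mb_per_morgan: float = DEFAULT_MAP_MB
) -> AgeEstimate:
    """Generations since inbreeding for a tract of ``length_mb`` MB.

    g = map_mb_per_morgan / (2 * length_mb): a 5 MB tract dates the event
    to ~10 generations back under a 100 MB/Morgan map.
    """
    if length_mb <= 0:
        raise ValueError(f"tract length must be positive, got {length_mb}")
    if map_mb_per_morgan <= 0:
        raise ValueError("map_mb_per_morgan must be positive")
    return AgeEstimate(
        length_mb=float(length_mb),
        generations=map_mb_per_morgan / (2.0 * length_mb),
        map_mb_per_morgan=float(map_mb_per_morgan),
    )


def length_from_generations(
    generations: float, map_mb_per_morgan: float = DEFAULT_MAP_MB
) -> float:
    """Expected tract length (MB) for an event ``generations`` back."""
    if generations <= 0:
        raise ValueError(f"generations must be positive, got {generations}")
    return map_mb_per_morgan / (2.0 * generations)


def estimate_mean_tract_length(
    segments: list[RohSegment],
    chrom_lengths: dict[str, int],
    min_len: int = 1_000_000,
) -> float:
    """Truncation- and censoring-corrected mean ROH length, in MB.

    Segments shorter than ``min_len`` are excluded (and the cutoff is
    subtracted from every retained length — exact for exponential lengths);
    segments touching a chromosome end are right-censored and contribute
    length but not a count.  Requires at least one uncensored segment.
    """
    kept = [s for s in segments if s.length >= min_len]
    if not kept:
        raise ValueError(f"no segments at least {min_len} bp long")
    excess = 0.0
    n_uncensored = 0
    for s in kept:
        if s.chrom not in chrom_lengths:
            raise ValueError(f"segment chromosome {s.chrom!r} has no known length")
        excess += s.length - min_len
        censored = s.start == 0 or s.end >= chrom_lengths[s.chrom]
        if not censored:
            n_uncensored += 1
    if n_uncensored == 0:
        raise ValueError(
            "every segment touches a chromosome end; mean length is not "
            "identifiable (chromosomes too short for the tract scale)"
        )
    return excess / n_uncensored / 1e6


def estimate_generations(
    segments: list[RohSegment],
    chrom_lengths: dict[str, int],
    min_len: int = 1_000_000,
    map_mb_per_morgan: float = DEFAULT_MAP_MB,
) -> AgeEstimate:
    """Date the inbreeding event from the corrected mean ROH length."""
    mean_mb = estimate_mean_tract_length(segments, chrom_lengths, min_len)
    return generations_from_length(mean_mb, map_mb_per_morgan)


def proportion_heterozygous(genotypes) -> float:
    """Proportion of non-missing loci that are heterozygous (pHt).

    Accepts per-locus genotypes as allele pairs (tuples/lists), strings
    like ``"152/154"``, or None for a missing locus.
    """
    n = 0
    n_het = 0
    for g in genotypes:
        if g is None:
            continue
        if isinstance(g, str):
            for sep in ("/", "|"):
                if sep in g:
                    alleles = g.split(sep)
                    break
            else:
                raise ValueError(f"cannot parse genotype {g!r}")
        else:
            alleles = list(g)
        if any(a is None or a in (".", "") for a in alleles):
            continue
        n += 1
        if len(set(alleles)) > 1:
            n_het += 1
    if n == 0:
        raise ValueError("all loci missing; pHt undefined")
    return n_het / n
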