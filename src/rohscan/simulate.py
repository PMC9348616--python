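"""Simulate single-individual inbred diploid genomes with known IBD tracts.

The generative model realizes the three heterozygosity regimes seen in
windowed scans of an inbred genome sequenced at moderate depth:

* background diversity outside identity-by-descent (IBD) tracts —
  heterozygous sites appear per bp with probability ``theta_bg``;
* near-zero true heterozygosity inside IBD tracts — only genotyping error
  contributes, per bp with probability ``epsilon``;
* a haploid X chromosome on which *all* apparent heterozygosity is error,
  giving an internal calibration of the error floor.

IBD tract lengths are exponential with mean ``map_mb_per_morgan / (2 g)``
megabases for an inbreeding event ``g`` generations back, the classical
expectation for the length of a segment surviving ``2 g`` meioses on a
genetic map with ``map_mb_per_morgan`` MB per Morgan.  Tracts are placed
uniformly with rejection of overlaps until a target genome fraction is
covered; the realized fraction ``f_true`` is the simulation's ground truth
for the ROH-based inbreeding coefficient F_ROH.

Missingness is per-site Bernoulli: a missing site is uncallable, drops out
of the callable mask, and can carry no variant call.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimConfig",
    "SimTruth",
    "GenotypeSet",
    "TractPlacementError",
    "default_chromosomes",
    "sample_tracts",
    "synthesize_genotypes",
    "write_fixture",
]

# 28 autosomes spanning ~1.9 GB at scale=1, descending in size, plus one X.
_N_AUTOSOMES = 28
_GENOME_BP = 1_904_000_000
_X_BP = 95_000_000
_X_NAME = "chrX"


class TractPlacementError(RuntimeError):
    """Raised when the requested IBD coverage cannot be placed."""


def default_chromosomes(scale: float = 0.01) -> tuple[dict[str, int], str, int]:
    """Default karyotype: 28 autosomes (~1.9 GB total at scale=1) plus an X.

    Parameters
    ----------
    scale:
        Multiplier on every chromosome length.  The default 0.01 yields a
        ~19 MB desk-scale genome that preserves the chromosome count and
        relative sizes.

    Returns
    -------
    (autosome lengths by name, X chromosome name, X length in bp)
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    # Linear size gradient 110 MB .. 26 MB, mean 68 MB, total 1.904 GB.
    sizes = np.linspace(110e6, 26e6, _N_AUTOSOMES)
    autosomes = {
        f"chr{i + 1}": int(round(sizes[i] * scale)) for i in range(_N_AUTOSOMES)
    }
    return autosomes, _X_NAME, int(round(_X_BP * scale))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated genome.

    Attributes
    ----------
    chrom_lengths:
        Autosome name -> length in bp.  The X is given separately.
    x_name, x_length:
        Name and length of the haploid X chromosome.
    g:
        Generations since the inbreeding event (> 0).
    f_target:
        Intended fraction of the autosomal genome inside IBD tracts.
    theta_bg:
        Per-site background heterozygosity probability outside tracts.
    epsilon:
        Per-site false-heterozygote (error) probability, applied everywhere
        including inside tracts and on the haploid X.
    miss_rate:
        Per-site probability that a position is uncallable.
    map_mb_per_morgan:
        Genetic map scale; 100 MB/Morgan is the standard mammalian value
        used to convert tract length to generations.
    seed:
        Random seed; identical configs give byte-identical fixtures.
    max_attempts:
        Cap on tract placement attempts before giving up.
    """

    chrom_lengths: dict[str, int]
    x_name: str = _X_NAME
    x_length: int = int(_X_BP * 0.01)
    g: float = 10.0
    f_target: float = 0.18
    theta_bg: float = 2.7e-3
    epsilon: float = 1e-4
    miss_rate: float = 0.05
    map_mb_per_morgan: float = 100.0
    seed: int = 0
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must name at least one autosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        if self.x_name in self.chrom_lengths:
            raise ValueError(f"X chromosome {self.x_name!r} also listed as autosome")
        if self.x_length <= 0:
            raise ValueError(f"x_length must be positive, got {self.x_length}")
        if not 0.0 <= self.f_target <= 1.0:
            raise ValueError(f"f_target must be in [0, 1], got {self.f_target}")
        if self.g <= 0:
            raise ValueError(f"g must be positive, got {self.g}")
        for nm in ("theta_bg", "epsilon", "miss_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{nm} must be in [0, 1), got {v}")
        if self.f_target > 0 and not self.epsilon < self.theta_bg:
            raise ValueError(
                "epsilon must be smaller than theta_bg, otherwise IBD tracts are "
                f"indistinguishable from background (epsilon={self.epsilon}, "
                f"theta_bg={self.theta_bg})"
            )
        if self.map_mb_per_morgan <= 0:
            raise ValueError("map_mb_per_morgan must be positive")

    @classmethod
    def default(cls, scale: float = 0.01, **overrides) -> "SimConfig":
        """Config with the default karyotype at the given scale."""
        autosomes, x_name, x_length = default_chromosomes(scale)
        kwargs = dict(
            chrom_lengths=autosomes, x_name=x_name, x_length=x_length
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def autosomal_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def mean_tract_bp(self) -> float:
        """Expected IBD tract length: map_mb_per_morgan / (2 g), in bp."""
        return self.map_mb_per_morgan / (2.0 * self.g) * 1e6

    @property
    def all_chrom_lengths(self) -> dict[str, int]:
        """Autosomes plus the X, in emission order."""
        out = dict(self.chrom_lengths)
        out[self.x_name] = self.x_length
        return out

    def to_dict(self) -> dict:
        return {
            "chrom_lengths": dict(self.chrom_lengths),
            "x_name": self.x_name,
            "x_length": self.x_length,
            "g": self.g,
            "f_target": self.f_target,
            "theta_bg": self.theta_bg,
            "epsilon": self.epsilon,
            "miss_rate": self.miss_rate,
            "map_mb_per_morgan": self.map_mb_per_morgan,
            "seed": self.seed,
            "max_attempts": self.max_attempts,
        }

    def config_hash(self) -> str:
        payload = repr(sorted(self.to_dict().items(), key=lambda kv: kv[0]))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth IBD tracts of one simulated genome.

    ``tracts`` are half-open (chrom, start, end) intervals, sorted and
    non-overlapping within each chromosome; none lie on the X.  ``f_true``
    is the realized fraction of autosomal bp inside tracts — the quantity
    F_ROH estimates.
    """

    tracts: tuple[tuple[str, int, int], ...]
    f_true: float
    g: float
    seed: int

    def tracts_on(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) for one chromosome, sorted."""
        pairs = [(s, e) for c, s, e in self.tracts if c == chrom]
        if not pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(pairs), dtype=np.int64)

    @property
    def total_tract_bp(self) -> int:
        return int(sum(e - s for _, s, e in self.tracts))


@dataclass
class GenotypeSet:
    """Per-site genotype stream of one simulated individual.

    ``het`` maps chromosome -> sorted positions (0-based) of heterozygous
    calls; on the X these are all error calls.  ``missing`` maps chromosome
    -> sorted positions of uncallable sites.  Heterozygous and missing
    positions are disjoint: a missing site carries no call.
    """

    het: dict[str, np.ndarray]
    missing: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    x_name: str = _X_NAME

    def n_het(self, chrom: str) -> int:
        return int(self.het.get(chrom, np.empty(0)).size)


def _rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(2)
    return np.random.default_rng(kids[0]), np.random.default_rng(kids[1])


def sample_tracts(config: SimConfig) -> SimTruth:
    """Place IBD tracts on the autosomes until ``f_target`` coverage.

    Tract lengths are exponential with mean ``config.mean_tract_bp``; start
    positions are uniform over the autosomal genome.  A tract overlapping an
    existing tract is rejected and redrawn; tracts running past a chromosome
    end are truncated there and their truncated length counts toward
    coverage (matching how ROH are measured on real chromosomes).
    Deterministic given ``config.seed``.
    """
    rng, _ = _rng_streams(config.seed)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    target_bp = config.f_target * total

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    covered = 0
    attempts = 0
    cum = np.concatenate([[0], np.cumsum(lengths)])
    while covered < target_bp and config.f_target > 0:
        attempts += 1
        if attempts > config.max_attempts:
            budget = ", ".join(
                f"{c}={config.chrom_lengths[c]}bp" for c in chroms[:5]
            )
            raise TractPlacementError(
                f"could not reach f_target={config.f_target} after "
                f"{config.max_attempts} attempts (covered {covered}/{total} bp); "
                f"chromosome budget too small for mean tract "
                f"{config.mean_tract_bp / 1e6:.2f} MB: {budget}..."
            )
        pos = int(rng.integers(total))
        ci = int(np.searchsorted(cum, pos, side="right") - 1)
        chrom = chroms[ci]
        start = pos - int(cum[ci])
        length = rng.exponential(config.mean_tract_bp)
        end = min(int(config.chrom_lengths[chrom]), start + int(np.ceil(length)))
        if end <= start:
            continue
        if any(end > s and start < e for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        covered += end - start

    tracts = tuple(
        (c, s, e) for c in chroms for s, e in sorted(placed[c])
    )
    return SimTruth(
        tracts=tracts, f_true=covered / total, g=config.g, seed=config.seed
    )


def _bernoulli_positions(rng: np.random.Generator, length: int, p: float) -> np.ndarray:
    """Positions of per-site Bernoulli(p) successes on [0, length).

    Uses geometric inter-success gaps, so the result is exact (independent
    per site), sorted, and duplicate-free without materializing the genome.
    """
    if p <= 0.0 or length <= 0:
        return np.empty(0, dtype=np.int64)
    out = []
    pos = -1
    expected = int(length * p) + 1
    while True:
        n = max(64, int(1.2 * expected) + 8 * int(np.sqrt(expected)))
        gaps = rng.geometric(p, size=n)
        cand = pos + np.cumsum(gaps)
        if cand[-1] >= length:
            out.append(cand[cand < length])
            break
        out.append(cand)
        pos = int(cand[-1])
        expected = max(1, int((length - pos) * p))
    return np.concatenate(out).astype(np.int64)


def _in_intervals(pos: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside sorted half-open intervals."""
    if intervals.shape[0] == 0 or pos.size == 0:
        return np.zeros(pos.size, dtype=bool)
    idx = np.searchsorted(intervals[:, 0], pos, side="right") - 1
    inside = idx >= 0
    inside[inside] = pos[inside] < intervals[idx[inside], 1]
    return inside


def synthesize_genotypes(truth: SimTruth, config: SimConfig) -> GenotypeSet:
    """Realize the per-site noise model over the genome of ``config``.

    Autosomes: heterozygous with probability ``theta_bg`` outside tracts,
    zero inside; error heterozygotes with probability ``epsilon``
    everywhere; uncallable with probability ``miss_rate``.  X: error
    heterozygotes and missingness only.  Deterministic given the config
    seed.
    """
    truth_chroms = {c for c, _, _ in truth.tracts}
    unknown = truth_chroms - set(config.chrom_lengths)
    if unknown:
        raise ValueError(f"truth tracts on chromosomes absent from config: {unknown}")

    _, rng = _rng_streams(config.seed)
    het: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for chrom, length in config.all_chrom_lengths.items():
        is_x = chrom == config.x_name
        if is_x:
            bg = np.empty(0, dtype=np.int64)
        else:
            bg = _bernoulli_positions(rng, length, config.theta_bg)
            tr = truth.tracts_on(chrom)
            bg = bg[~_in_intervals(bg, tr)]
        err = _bernoulli_positions(rng, length, config.epsilon)
        miss = _bernoulli_positions(rng, length, config.miss_rate)
        h = np.concatenate([bg, err])
        h.sort(kind="mergesort")  # both inputs sorted already
        if h.size:
            keep = np.empty(h.size, dtype=bool)
            keep[0] = True
            np.not_equal(h[1:], h[:-1], out=keep[1:])
            h = h[keep]
        if miss.size and h.size:
            h = h[~np.isin(h, miss, assume_unique=True, kind="sort")]
        het[chrom] = h
        missing[chrom] = miss
    return GenotypeSet(
        het=het,
        missing=missing,
        chrom_lengths=config.all_chrom_lengths,
        x_name=config.x_name,
    )


def _complement_intervals(missing: np.ndarray, length: int) -> np.ndarray:
    """Callable intervals = [0, length) minus single-bp missing positions."""
    if missing.size == 0:
        return np.array([[0, length]], dtype=np.int64)
    starts = np.concatenate([[0], missing + 1])
    ends = np.concatenate([missing, [length]])
    keep = ends > starts
    return np.stack([starts[keep], ends[keep]], axis=1)


def write_fixture(
    truth: SimTruth,
    genotypes: GenotypeSet,
    config: SimConfig,
    out_dir,
    sample_name: str = "sim",
) -> dict[str, str]:
    """Write the fixture files: VCF, callable mask BED, truth BED, config.

    Returns a dict of logical name -> path.  Files are plain text and
    byte-identical across runs with the same config.
    """
    from pathlib import Path

    out = Path(out_dir)
    if not config.all_chrom_lengths:
        raise ValueError("refusing to write fixture for an empty genome")
    out.mkdir(parents=True, exist_ok=True)

    vcf_path = out / "sim.vcf"
    mask_path = out / "callable_mask.bed"
    truth_path = out / "truth_tracts.bed"
    cfg_path = out / "sim_config.txt"

    # VCF v4.2, one sample, GT only.  Alleles are placeholders: windowed
    # heterozygosity depends only on genotype class, not on the bases.
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscan-simulate\n")
        for chrom, length in config.all_chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_name}\n"
        )
        for chrom in config.all_chrom_lengths:
            pos = genotypes.het.get(chrom)
            if pos is None or pos.size == 0:
                continue
            gt = "0/1"
            lines = "".join(
                f"{chrom}\t{p + 1}\t.\tA\tC\t.\tPASS\t.\tGT\t{gt}\n"
                for p in pos.tolist()
            )
            fh.write(lines)

    with open(mask_path, "w") as fh:
        for chrom, length in config.all_chrom_lengths.items():
            iv = _complement_intervals(genotypes.missing.get(chrom, np.empty(0, np.int64)), length)
            fh.write(
                "".join(f"{chrom}\t{s}\t{e}\n" for s, e in iv.tolist())
            )

    with open(truth_path, "w") as fh:
        for chrom, s, e in truth.tracts:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    with open(cfg_path, "w") as fh:
        cfg = config.to_dict()
        chrom_lengths = cfg.pop("chrom_lengths")
        for key, val in cfg.items():
            fh.write(f"{key} = {val}\n")
        fh.write(f"f_true = {truth.f_true:.10g}\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"chrom {chrom} = {length}\n")

    return {
        "vcf": str(vcf_path),
        "mask": str(mask_path),
        "truth": str(truth_path),
        "config": str(cfg_path),
    }
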