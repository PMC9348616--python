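"""One-command orchestration: simulate/ingest -> windows -> calibrate ->
ROH -> summaries, with a manifest for reproducibility.

Defaults mirror the reference analysis: 50 KB windows, a 99th-percentile
X calibration (or the fixed 0.0002/0.0004 thresholds), 1 MB minimum ROH,
F_ROH cutoffs at 1 and 5 MB, and a 100 MB/Morgan map scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .simulate import SimConfig, sample_tracts, synthesize_genotypes, write_fixture
from .windows import (
    build_windows,
    window_table_from_genotypes,
    write_windows,
    sliding_mean,
    mean_het,
)
from .calibrate import calibrate, fixed_thresholds, write_calibration
from .roh import call_roh, write_roh_bed
from .stats import (
    summarize,
    estimate_generations,
    DEFAULT_CUTOFFS,
    DEFAULT_MAP_MB,
)

log = logging.getLogger("rohscan")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``sim`` (a :class:`SimConfig`) or ``vcf`` must be given.
    ``mask`` is optional in real-input mode; without it every position is
    treated as callable, which inflates denominators wherever the caller
    skipped sites — a warning is logged.
    """

    out_dir: str | Path
    sim: SimConfig | None = None
    vcf: str | Path | None = None
    mask: str | Path | None = None
    chrom_table: str | Path | None = None
    x_name: str = "chrX"
    window_size: int = 50_000
    plot_window: int = 500_000
    min_callable: int | None = None
    percentile: float = 99.0
    min_x_windows: int = 50
    fixed: tuple[float, float] | None = None
    min_roh_len: int = 1_000_000
    neighborhood: int = 1_000_000
    bridge_nodata: int = 0
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    map_mb_per_morgan: float = DEFAULT_MAP_MB
    seed: int = 0
    sim_in_memory: bool = False

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.vcf is None):
            raise ValueError(
                "exactly one of a simulation config or a VCF path is required"
            )
        if self.window_size <= 0 or self.min_roh_len < 0:
            raise ValueError("window_size must be > 0 and min_roh_len >= 0")

    def config_hash(self) -> str:
        payload = {
            k: (v.to_dict() if isinstance(v, SimConfig) else str(v))
            for k, v in vars(self).items()
        }
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_chrom_table(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            out[name] = int(length)
    return out


def run_pipeline(config: RunConfig):
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns ``(manifest, summary)``: the manifest dict (also written as
    ``manifest.json``) and the :class:`~rohscan.stats.InbreedingSummary`.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    counts: dict[str, float] = {}

    if config.sim is not None:
        sim_cfg = config.sim.with_seed(config.seed)
        truth = sample_tracts(sim_cfg)
        genotypes = synthesize_genotypes(truth, sim_cfg)
        counts["f_true"] = truth.f_true
        counts["n_truth_tracts"] = len(truth.tracts)
        truth_path = out / "truth_tracts.bed"
        with open(truth_path, "w") as fh:
            for chrom, s, e in truth.tracts:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        files["truth"] = str(truth_path)
        if config.sim_in_memory:
            records = window_table_from_genotypes(
                genotypes, config.window_size, config.min_callable
            )
        else:
            fixture = write_fixture(truth, genotypes, sim_cfg, out)
            files.update(fixture)
            records = build_windows(
                fixture["vcf"],
                fixture["mask"],
                window_size=config.window_size,
                min_callable=config.min_callable,
                x_name=sim_cfg.x_name,
            )
        x_name = sim_cfg.x_name
        chrom_lengths = sim_cfg.all_chrom_lengths
    else:
        if config.mask is None:
            log.warning(
                "no callable mask given; treating the whole genome as callable"
            )
        chrom_lengths = (
            _read_chrom_table(config.chrom_table) if config.chrom_table else None
        )
        records = build_windows(
            config.vcf,
            config.mask,
            window_size=config.window_size,
            min_callable=config.min_callable,
            x_name=config.x_name,
            chrom_lengths=chrom_lengths,
        )
        x_name = config.x_name
        if chrom_lengths is None:
            chrom_lengths = {
                str(c): int(g["end"].max())
                for c, g in records.groupby("chrom", sort=False)
            }

    windows_path = out / "windows.tsv"
    write_windows(records, windows_path)
    files["windows"] = str(windows_path)
    counts["n_windows"] = int(len(records))
    counts["n_defined_windows"] = int(records["het"].notna().sum())

    # smoothed track for plotting (the sliding-mean line over windows)
    smoothed = sliding_mean(records, span=max(config.plot_window, config.window_size))
    smooth_path = out / "windows_smoothed.tsv"
    smoothed.to_csv(smooth_path, sep="\t", index=False, na_rep="NA")
    files["windows_smoothed"] = str(smooth_path)

    if config.fixed is not None:
        cal = fixed_thresholds(*config.fixed)
    else:
        cal = calibrate(
            records.loc[records["is_x"]].reset_index(drop=True),
            percentile=config.percentile,
            min_windows=config.min_x_windows,
        )
    cal_path = out / "calibration.json"
    write_calibration(cal, cal_path)
    files["calibration"] = str(cal_path)
    counts["t_strict"] = cal.t_strict
    counts["t_rescue"] = cal.t_rescue

    segments = call_roh(
        records,
        cal,
        min_report_len=config.min_roh_len,
        neighborhood=config.neighborhood,
        bridge_nodata=config.bridge_nodata,
    )
    roh_path = out / "roh.bed"
    write_roh_bed(segments, roh_path)
    files["roh"] = str(roh_path)
    counts["n_segments"] = len(segments)
    counts["n_rescued_windows"] = int(sum(s.n_rescued for s in segments))

    summary = summarize(
        records,
        segments,
        cutoffs=config.cutoffs,
        t_strict=cal.t_strict,
    )
    summary.extras["mean_autosomal_het"] = mean_het(records, "autosomes")
    if segments:
        try:
            age = estimate_generations(
                segments,
                chrom_lengths,
                min_len=config.min_roh_len,
                map_mb_per_morgan=config.map_mb_per_morgan,
            )
            summary.extras["mean_tract_length_mb"] = age.length_mb
            summary.extras["generations_since_inbreeding"] = age.generations
        except ValueError as exc:  # all segments censored
            log.warning("tract dating skipped: %s", exc)
    summary_path = out / "summary.json"
    summary.write(summary_path)
    files["summary"] = str(summary_path)

    manifest = {
        "tool": "rohscan",
        "version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "files": files,
        "counts": counts,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
        fh.write("\n")
    for name, path in files.items():
        if not Path(path).exists():
            raise RuntimeError(f"stage output {name} missing at {path}")
    log.info(
        "run complete: %d windows, %d ROH segments, F_ROH cutoffs %s",
        counts["n_windows"],
        counts["n_segments"],
        list(config.cutoffs),
    )
    return manifest, summary
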