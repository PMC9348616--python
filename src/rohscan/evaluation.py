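"""Validation experiments: simulate with known truth, measure recovery.

These drive the package's self-checks: how well F_ROH tracks the true IBD
fraction, whether the X-percentile calibration controls false positives at
the nominal rate, and whether the production ROH scan agrees with the
exhaustive reference implementation.  Problem sizes are desk-scale by
design (a 19 x 10 MB autosome panel rather than a 2 GB genome); the
statistics they estimate are scale-free.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .simulate import SimConfig, sample_tracts, synthesize_genotypes
from .windows import window_table_from_genotypes
from .calibrate import ThresholdCalibration, calibrate, fixed_thresholds
from .roh import call_roh, roh_oracle
from .stats import summarize, estimate_mean_tract_length

__all__ = [
    "recovery_config",
    "run_recovery",
    "recovery_experiment",
    "x_threshold_experiment",
    "class_string_table",
    "oracle_agreement",
    "interval_jaccard",
]

RECOVERY_F_TARGETS = (0.05, 0.18, 0.30)


def recovery_config(f_target: float, seed: int) -> SimConfig:
    """Study conditions for recovery runs: 19 x 10 MB autosomes plus a
    10 MB X, g=10, background het 2.7e-3, error 1e-4."""
    return SimConfig(
        chrom_lengths={f"chr{i + 1}": 10_000_000 for i in range(19)},
        x_name="chrX",
        x_length=10_000_000,
        g=10.0,
        f_target=f_target,
        theta_bg=2.7e-3,
        epsilon=1e-4,
        seed=seed,
    )


def interval_jaccard(a: dict[str, list], b: dict[str, list]) -> float:
    """bp-level Jaccard of two {chrom: [(start, end), ...]} sets."""
    inter = union = 0
    for chrom in set(a) | set(b):
        ia = sorted(a.get(chrom, []))
        ib = sorted(b.get(chrom, []))
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                inter += e - s
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
        union += sum(e - s for s, e in ia) + sum(e - s for s, e in ib)
    union -= inter
    return inter / union if union else float("nan")


def run_recovery(config: SimConfig, min_roh_len: int = 1_000_000) -> dict:
    """One simulate -> windows -> calibrate -> ROH -> summarize cycle.

    Returns truth and recovered quantities, including the bp Jaccard
    between called ROH and the >1 MB truth tracts.
    """
    truth = sample_tracts(config)
    genotypes = synthesize_genotypes(truth, config)
    records = window_table_from_genotypes(genotypes)
    cal = calibrate(records[records.is_x].reset_index(drop=True))
    segments = call_roh(records, cal, min_report_len=min_roh_len)
    summary = summarize(records, segments, cutoffs=(min_roh_len, 5_000_000),
                        t_strict=cal.t_strict)
    truth_iv: dict[str, list] = {}
    for chrom, s, e in truth.tracts:
        if e - s > min_roh_len:
            truth_iv.setdefault(chrom, []).append((s, e))
    called_iv: dict[str, list] = {}
    for s in segments:
        called_iv.setdefault(s.chrom, []).append((s.start, s.end))
    return {
        "f_true": truth.f_true,
        "f_roh": summary.f_roh[min_roh_len],
        "jaccard": interval_jaccard(truth_iv, called_iv),
        "het_outside": summary.het_outside,
        "segments": segments,
        "chrom_lengths": config.all_chrom_lengths,
        "cal": cal,
        "summary": summary,
    }


def recovery_experiment(seed: int, n_sims: int = 20,
                        f_targets=RECOVERY_F_TARGETS) -> dict:
    """Seeded batch of recovery runs cycling through the target fractions.

    Aggregates: mean |F_ROH - f_true|, mean Jaccard, and the pooled
    truncation/censoring-corrected mean tract length (MB) with the implied
    generations-since-inbreeding estimate.
    """
    rows = []
    pooled_segments = []
    pooled_lengths: dict[str, int] = {}
    for i in range(n_sims):
        f_target = f_targets[i % len(f_targets)]
        cfg = recovery_config(f_target, seed=seed * 1000 + i)
        res = run_recovery(cfg)
        rows.append(
            {
                "f_target": f_target,
                "f_true": res["f_true"],
                "f_roh": res["f_roh"],
                "abs_err": abs(res["f_roh"] - res["f_true"]),
                "jaccard": res["jaccard"],
                "het_outside": res["het_outside"],
            }
        )
        # pool segments under per-sim chromosome aliases for one global MLE
        for s in res["segments"]:
            alias = f"sim{i}_{s.chrom}"
            pooled_lengths[alias] = res["chrom_lengths"][s.chrom]
            pooled_segments.append(
                type(s)(chrom=alias, start=s.start, end=s.end,
                        n_windows=s.n_windows, n_rescued=s.n_rescued,
                        mean_het=s.mean_het)
            )
    table = pd.DataFrame(rows)
    mean_len_mb = estimate_mean_tract_length(pooled_segments, pooled_lengths)
    return {
        "table": table,
        "mean_abs_err": float(table["abs_err"].mean()),
        "mean_jaccard": float(table["jaccard"].mean()),
        "mean_het_outside": float(table["het_outside"].mean()),
        "mean_f_roh_at_018": float(
            table.loc[table.f_target == 0.18, "f_roh"].mean()
        ),
        "mean_tract_length_mb": float(mean_len_mb),
        "generations_estimate": float(100.0 / (2.0 * mean_len_mb)),
    }


def x_threshold_experiment(seed: int, n_windows: int = 10_000,
                           epsilon: float = 1e-4,
                           percentile: float = 99.0) -> dict:
    """Error-only X windows: calibrate, then measure the exceedance rate.

    With the threshold at the p-th percentile of the same error
    distribution, the fraction of windows above it should be ~(100-p)%.
    """
    window = 50_000
    cfg = SimConfig(
        chrom_lengths={"a1": window},
        x_name="chrX",
        x_length=n_windows * window,
        epsilon=epsilon,
        f_target=0.0,
        seed=seed,
    )
    truth = sample_tracts(cfg)
    genotypes = synthesize_genotypes(truth, cfg)
    records = window_table_from_genotypes(genotypes, window_size=window)
    x = records[records.is_x].reset_index(drop=True)
    cal = calibrate(x, percentile=percentile)
    vals = x.loc[x.het.notna(), "het"]
    frac = float((vals > cal.t_strict).mean())
    return {"cal": cal, "exceedance": frac, "n": int(len(vals))}


# ---------------------------------------------------------------------------
# Production-vs-oracle agreement fixtures
# ---------------------------------------------------------------------------

_CLASS_HET = {0: 2 / 50_000, 1: 15 / 50_000, 2: 100 / 50_000}  # 3 = no data


def class_string_table(strings, n_callable=None) -> pd.DataFrame:
    """Window table realizing symbolic het-class strings, one string per
    chromosome.

    Classes: 0 low (strict), 1 marginal (rescuable if the neighbourhood is
    quiet), 2 high, 3 no-data.  Whether a marginal window is actually
    rescuable emerges from its neighbours, exactly as in real tables.
    """
    frames = []
    window = 50_000
    for k, s in enumerate(strings):
        s = np.asarray(s, dtype=int)
        n = s.size
        nc = np.full(n, 50_000) if n_callable is None else np.asarray(n_callable[k])
        nc = np.where(s == 3, 0, nc)
        nh = np.array(
            [int(round(_CLASS_HET.get(c, 0) * m)) for c, m in zip(s, nc)]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            het = np.where(nc > 0, nh / np.maximum(nc, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": f"s{k:06d}",
            "start": np.arange(n) * window,
            "end": (np.arange(n) + 1) * window,
            "n_callable": nc,
            "n_het": nh,
            "het": het,
            "is_x": False,
        }))
    return pd.concat(frames, ignore_index=True)


def oracle_agreement(records: pd.DataFrame,
                     cal: ThresholdCalibration | None = None,
                     min_report_len: int = 0) -> bool:
    """True when the linear-scan caller and the exhaustive reference
    produce identical segment lists on the given table."""
    cal = cal or fixed_thresholds(2e-4, 4e-4)
    return call_roh(records, cal, min_report_len=min_report_len) == roh_oracle(
        records, cal, min_report_len=min_report_len
    )


def all_class_strings(max_len: int):
    """Every class string over {low, marginal, high, no-data} up to
    ``max_len`` windows."""
    for n in range(1, max_len + 1):
        yield from itertools.product(range(4), repeat=n)


def random_class_fixture(rng: np.random.Generator, n_windows: int = 200):
    """One random fixture with varying callable counts."""
    classes = rng.choice(4, size=n_windows, p=[0.35, 0.25, 0.25, 0.15])
    n_call = rng.integers(40_000, 50_001, size=n_windows)
    return classes, n_call
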