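"""Homozygosity thresholds calibrated on the haploid X chromosome.

In a male, the single-copy X cannot be heterozygous, so every apparent
heterozygote there is sequencing or mapping error.  The per-window
heterozygosity distribution on the X is therefore a pure error
distribution, and its 99th percentile gives a strict threshold below which
a diploid autosomal window is indistinguishable from fully homozygous.
The rescue threshold, used to bridge isolated marginal windows inside long
runs, defaults to twice the strict threshold (0.0004 vs. 0.0002 per site at
the reference parameterization).

Percentiles use linear interpolation between order statistics
(``numpy.percentile`` with ``method="linear"``), documented here so the
calibration is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdCalibration",
    "CalibrationError",
    "calibrate",
    "fixed_thresholds",
    "read_calibration",
    "write_calibration",
]

DEFAULT_PERCENTILE = 99.0
DEFAULT_MIN_X_WINDOWS = 50
RESCUE_FACTOR = 2.0

#: Reference thresholds: strict 2e-4, rescue 4e-4 per site.
REFERENCE_STRICT = 2e-4
REFERENCE_RESCUE = 4e-4


class CalibrationError(ValueError):
    """Raised when the X-window distribution cannot support calibration."""


@dataclass(frozen=True)
class ThresholdCalibration:
    """Strict/rescue heterozygosity thresholds and their provenance.

    ``source`` is ``"calibrated"`` when derived from X windows,
    ``"fixed"`` when supplied directly (then ``percentile`` is None).
    """

    t_strict: float
    t_rescue: float
    percentile: float | None
    n_x_windows: int
    source: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_strict < self.t_rescue:
            raise CalibrationError(
                f"thresholds must satisfy 0 <= t_strict < t_rescue, got "
                f"t_strict={self.t_strict}, t_rescue={self.t_rescue}"
            )
        if self.source not in ("calibrated", "fixed"):
            raise CalibrationError(f"unknown source {self.source!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def calibrate(
    records: pd.DataFrame,
    percentile: float = DEFAULT_PERCENTILE,
    min_windows: int = DEFAULT_MIN_X_WINDOWS,
    rescue_factor: float = RESCUE_FACTOR,
) -> ThresholdCalibration:
    """Derive thresholds from the X subset of a window table.

    ``t_strict`` is the given percentile of defined X-window het values;
    ``t_rescue`` is ``rescue_factor`` times that.

    Raises
    ------
    CalibrationError
        If non-X windows are passed (sex/ploidy mismatch), too few X
        windows carry an estimate, or the distribution is degenerate
        (percentile zero) — in those cases use :func:`fixed_thresholds`.
    """
    if not 0.0 < percentile < 100.0:
        raise CalibrationError(f"percentile must be in (0, 100), got {percentile}")
    if len(records) and not records["is_x"].all():
        n_bad = int((~records["is_x"]).sum())
        raise CalibrationError(
            f"{n_bad} non-X (diploid) windows passed to X calibration; "
            "subset the table to the haploid X first"
        )
    vals = records.loc[records["het"].notna(), "het"].to_numpy(dtype=float)
    if vals.size < min_windows:
        raise CalibrationError(
            f"only {vals.size} defined X windows (< {min_windows}); "
            "too few to calibrate — use fixed_thresholds(2e-4, 4e-4)"
        )
    t_strict = float(np.percentile(vals, percentile, method="linear"))
    if t_strict <= 0.0:
        raise CalibrationError(
            "degenerate calibration: the X heterozygosity percentile is 0 "
            "(error-free input?) — use fixed_thresholds instead"
        )
    return ThresholdCalibration(
        t_strict=t_strict,
        t_rescue=rescue_factor * t_strict,
        percentile=float(percentile),
        n_x_windows=int(vals.size),
        source="calibrated",
    )


def fixed_thresholds(
    t_strict: float = REFERENCE_STRICT, t_rescue: float = REFERENCE_RESCUE
) -> ThresholdCalibration:
    """Pass user-chosen thresholds through unchanged (source="fixed")."""
    return ThresholdCalibration(
        t_strict=float(t_strict),
        t_rescue=float(t_rescue),
        percentile=None,
        n_x_windows=0,
        source="fixed",
    )


def write_calibration(cal: ThresholdCalibration, path) -> None:
    with open(path, "w") as fh:
        json.dump(cal.to_dict(), fh, indent=2)
        fh.write("\n")


def read_calibration(path) -> ThresholdCalibration:
    with open(path) as fh:
        payload = json.load(fh)
    return ThresholdCalibration(**payload)
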