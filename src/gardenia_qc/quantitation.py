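"""External-standard quantitation and method-validation statistics.

Calibration regresses peak area on the on-column amount X (ng) injected:
area = a*X + b by unweighted ordinary least squares. A sample peak's content
follows the dilution chain of the standard preparation — m grams of powder
extracted to V mL, v microlitres injected:

    X = (area - b) / a                      [ng on column]
    content = X * (V * 1000 / v) / m / 1e6  [mg per g of powder]

With the default preparation (0.1 g, 50 mL, 30 uL) one mg/g of content is
60 ng on column. LOD and LOQ derive from signal-to-noise 3:1 and 10:1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "SamplePrep",
    "RecoveryResult",
    "fit_calibration",
    "lod_loq",
    "quantify",
    "aggregate_contents",
    "recovery",
    "precision_rsd",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-analyte line area = slope * ng + intercept with working limits."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]
    lod_ng: float | None = None
    loq_ng: float | None = None
    channel: int = 254

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.lod_ng is not None and self.loq_ng is not None and self.lod_ng > self.loq_ng:
            raise ValueError("LOD cannot exceed LOQ")


@dataclass(frozen=True)
class SamplePrep:
    """Dilution chain: sample mass, extraction volume, injection volume."""

    sample_mass_g: float = 0.1
    flask_volume_mL: float = 50.0
    injection_volume_uL: float = 30.0

    def __post_init__(self) -> None:
        if min(self.sample_mass_g, self.flask_volume_mL, self.injection_volume_uL) <= 0:
            raise ValueError("all preparation quantities must be positive")

    @property
    def ng_per_mgg(self) -> float:
        """ng on column corresponding to 1 mg/g of content."""
        return (
            self.sample_mass_g
            * 1e6
            / self.flask_volume_mL
            * self.injection_volume_uL
            / 1000.0
        )


@dataclass(frozen=True)
class RecoveryResult:
    analyte: str
    mean_recovery_pct: float
    rsd_pct: float
    n: int


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    channel: int = 254,
    weighting: str | None = None,
) -> CalibrationCurve:
    """OLS of area on ng; linear range = span of the inputs.

    Unweighted by default (the convention for external-standard lines of
    this kind); ``weighting="1/x"`` down-weights the high end of the range.
    R^2 is always the plain coefficient of determination.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("calibration amounts have zero spread")
    if weighting is None:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting requires positive amounts")
        slope, intercept = (
            float(v) for v in np.polyfit(x, y, 1, w=np.sqrt(1.0 / x))
        )
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        linear_range=(float(x.min()), float(x.max())),
        channel=channel,
    )


def lod_loq(noise_sd: float, curve: CalibrationCurve) -> tuple[float, float]:
    """LOD = 3*noise/slope, LOQ = 10*noise/slope (S/N 3:1 and 10:1).

    Noise is expressed on the same (area) scale as the calibration response;
    instruments that measure S/N on peak height will report LOD/LOQ pairs
    that deviate from the fixed 3:10 ratio this formula implies.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    return 3.0 * noise_sd / curve.slope, 10.0 * noise_sd / curve.slope


def quantify(
    area: float,
    curve: CalibrationCurve,
    prep: SamplePrep = SamplePrep(),
    channel: int | None = None,
) -> tuple[float, bool]:
    """Content in mg/g from a peak area, with an in-linear-range flag.

    A ``channel`` differing from the curve's detection wavelength is refused.
    A negative back-calculated amount reports content 0, flagged out-of-range.
    """
    if channel is not None and channel != curve.channel:
        raise ValueError(
            f"area measured at {channel} nm but curve {curve.analyte!r} is "
            f"calibrated at {curve.channel} nm"
        )
    x = (area - curve.intercept) / curve.slope
    if x < 0:
        return 0.0, False
    in_range = curve.linear_range[0] <= x <= curve.linear_range[1]
    return x / prep.ng_per_mgg, in_range


def aggregate_contents(
    table: pd.DataFrame,
    group: Sequence[str],
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample group totals and per-analyte min/max/mean summaries.

    ``table`` is samples x analytes (mg/g). The mean uses the population (n)
    denominator, as aggregate rows of content tables conventionally do.
    """
    if not len(group):
        raise ValueError("analyte group must be non-empty")
    missing = [g for g in group if g not in table.columns]
    if missing:
        raise ValueError(f"analytes not in table: {missing}")
    totals = table[list(group)].sum(axis=1)
    summary = pd.DataFrame(
        {
            "min": table.min(axis=0),
            "max": table.max(axis=0),
            "mean": table.mean(axis=0),
        }
    )
    return totals, summary


def recovery(
    spiked_results: Sequence[tuple[float, float, float]],
    analyte: str = "",
) -> RecoveryResult:
    """Spike recovery: per replicate (found_total, original, added) in mg.

    recovery% = (found - original)/added * 100; needs >= 3 replicates.
    """
    if len(spiked_results) < 3:
        raise ValueError("need >= 3 spiked replicates")
    recs = []
    for found, original, added in spiked_results:
        if added <= 0:
            raise ValueError("added amount must be positive")
        recs.append((found - original) / added * 100.0)
    recs = np.asarray(recs)
    sd = recs.std(ddof=1)
    mean = recs.mean()
    rsd = 0.0 if sd == 0.0 else float(100.0 * sd / mean) if mean != 0 else float("nan")
    return RecoveryResult(
        analyte=analyte,
        mean_recovery_pct=float(mean),
        rsd_pct=rsd,
        n=len(recs),
    )


def precision_rsd(replicate_values: Iterable[float]) -> float:
    """RSD% = 100 * sd(n-1) / mean of replicate measurements."""
    x = np.asarray(list(replicate_values), dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 replicates")
    if x.mean() == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / x.mean())
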