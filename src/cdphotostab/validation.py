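"""ICH-style validation statistics for the HPLC calibration.

Linearity is an OLS fit of detector response on nominal concentration with
standard errors from the usual formulas; the detection limits follow ICH Q2:

    LOD = 3.3 sigma / S,    LOQ = 10 sigma / S,

where S is the calibration slope and sigma the standard deviation of the
intercept (estimated from replicate calibration curves when the series is
replicated, otherwise from the regression residuals).  Accuracy is mean
percent recovery, precision the percent relative standard deviation
(sample, n-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationSeries",
    "LinearityFit",
    "AccuracyPrecision",
    "ValidationReport",
    "fit_linearity",
    "lod",
    "loq",
    "accuracy_precision",
    "validation_report",
    "check_detection_limits",
]

#: relative tolerance when cross-checking quoted LOD/LOQ against 3.3/10 sigma/S
_DL_RTOL = 0.02


@dataclass(frozen=True)
class CalibrationSeries:
    """Calibration data: detector response vs nominal concentration.

    ``replicate`` optionally labels each row with the calibration-curve
    replicate it belongs to (0, 1, 2, ...); with >= 2 complete replicate
    curves the intercept SD used in the detection limits is estimated across
    curves rather than from residuals.
    """

    nominal_concs: np.ndarray
    responses: np.ndarray
    label: str = ""
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.nominal_concs, dtype=float)
        y = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "nominal_concs", x)
        object.__setattr__(self, "responses", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("nominal_concs and responses must match in shape")
        if np.unique(x).size < 5:
            raise ValueError("need >= 5 distinct calibration levels")
        if np.any(x <= 0):
            raise ValueError("nominal concentrations must be > 0")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")
        if self.replicate is not None:
            rep = np.asarray(self.replicate)
            if rep.shape != x.shape:
                raise ValueError("replicate labels must match data length")
            object.__setattr__(self, "replicate", rep)


@dataclass(frozen=True)
class LinearityFit:
    """OLS calibration line with standard errors and Pearson correlation."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    sd_intercept: float
    correlation: float
    n_points: int


class AccuracyPrecision(NamedTuple):
    """Mean percent recovery +/- SD and percent RSD."""

    accuracy_percent: float
    accuracy_sd: float
    rsd_percent: float


@dataclass(frozen=True)
class ValidationReport:
    """Full assay-validation block: linearity, detection limits, accuracy."""

    label: str
    linearity: LinearityFit
    lod: float
    loq: float
    accuracy: AccuracyPrecision | None = None
    flags: tuple[str, ...] = ()


def _single_fit(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res


def fit_linearity(series: CalibrationSeries) -> LinearityFit:
    """OLS of response on concentration with SEs and intercept SD.

    For a single curve the intercept SD falls back to its OLS standard
    error computed from the residuals; with replicate curves it is the
    sample SD of the per-curve intercepts, the quantity the ICH detection
    limits ask for.
    """
    x, y = series.nominal_concs, series.responses
    res = _single_fit(x, y)
    sd_intercept = float(res.intercept_stderr)
    if series.replicate is not None:
        labels = np.unique(series.replicate)
        if labels.size >= 2:
            intercepts = []
            for lab in labels:
                mask = series.replicate == lab
                if np.unique(x[mask]).size >= 2:
                    intercepts.append(_single_fit(x[mask], y[mask]).intercept)
            if len(intercepts) >= 2:
                sd_intercept = float(np.std(intercepts, ddof=1))
    return LinearityFit(
        slope=float(res.slope), intercept=float(res.intercept),
        se_slope=float(res.stderr), se_intercept=float(res.intercept_stderr),
        sd_intercept=sd_intercept, correlation=float(res.rvalue),
        n_points=x.size,
    )


def lod(sd_intercept: float, slope: float) -> float:
    """ICH Q2 limit of detection, 3.3 sigma / S."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if sd_intercept < 0:
        raise ValueError("sd_intercept must be >= 0")
    return 3.3 * sd_intercept / slope


def loq(sd_intercept: float, slope: float) -> float:
    """ICH Q2 limit of quantification, 10 sigma / S (= 10/3.3 x LOD)."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if sd_intercept < 0:
        raise ValueError("sd_intercept must be >= 0")
    return 10.0 * sd_intercept / slope


def accuracy_precision(measured: Sequence[float],
                       nominal: float) -> AccuracyPrecision:
    """Percent recovery statistics of replicate determinations.

    Accuracy is the mean of 100 x measured/nominal with its sample SD;
    precision is 100 x SD/mean of the measurements (percent RSD).
    """
    m = np.asarray(measured, dtype=float)
    if m.size < 2:
        raise ValueError("need >= 2 measurements")
    if nominal <= 0:
        raise ValueError("nominal must be > 0")
    recovery = 100.0 * m / nominal
    mean_m = m.mean()
    rsd = 0.0 if mean_m == 0 else 100.0 * m.std(ddof=1) / mean_m
    return AccuracyPrecision(
        accuracy_percent=float(recovery.mean()),
        accuracy_sd=float(recovery.std(ddof=1)),
        rsd_percent=float(rsd),
    )


def check_detection_limits(sd_intercept: float, slope: float,
                           quoted_lod: float, quoted_loq: float,
                           label: str = "") -> list[str]:
    """Cross-check quoted detection limits against 3.3/10 sigma/S.

    Returns human-readable flags for any quoted value that the standard
    formulas do not reproduce within a couple of percent.  Nothing is
    corrected silently: the recomputed values always come from the inputs.
    """
    flags = []
    calc_lod, calc_loq = lod(sd_intercept, slope), loq(sd_intercept, slope)
    prefix = f"{label}: " if label else ""
    if not np.isclose(calc_lod, quoted_lod, rtol=_DL_RTOL):
        flags.append(
            f"{prefix}quoted LOD {quoted_lod:.3g} M inconsistent with "
            f"3.3 sigma/S = {calc_lod:.3g} M from sigma={sd_intercept:.3g}, "
            f"S={slope:.3g}"
        )
    if not np.isclose(calc_loq, quoted_loq, rtol=_DL_RTOL):
        flags.append(
            f"{prefix}quoted LOQ {quoted_loq:.3g} M inconsistent with "
            f"10 sigma/S = {calc_loq:.3g} M from sigma={sd_intercept:.3g}, "
            f"S={slope:.3g}"
        )
    return flags


def validation_report(
    series: CalibrationSeries,
    accuracy_measured: Sequence[float] | None = None,
    accuracy_nominal: float | None = None,
) -> ValidationReport:
    """Assemble linearity, detection limits and (optionally) accuracy."""
    lin = fit_linearity(series)
    acc = None
    if accuracy_measured is not None:
        if accuracy_nominal is None:
            raise ValueError("accuracy_nominal required with accuracy_measured")
        acc = accuracy_precision(accuracy_measured, accuracy_nominal)
    return ValidationReport(
        label=series.label, linearity=lin,
        lod=lod(lin.sd_intercept, lin.slope),
        loq=loq(lin.sd_intercept, lin.slope),
        accuracy=acc,
    )
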