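"""Complex stoichiometry: Job's continuous-variation method and conductometry.

In Job's method the host and guest mole fractions are varied at fixed total
concentration; the mole fraction at which the complexation signal (here a
change in absorbance) peaks reveals the stoichiometry — a maximum at 0.5
means a 1:1 complex.  Conductometric titration locates the equivalence
point instead: the conductivity falls linearly with host concentration with
a slope change ("sharp curve") at the stoichiometric break, found here by
exhaustive two-segment continuous piecewise-linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "JobSeries",
    "StoichiometryResult",
    "ConductivitySeries",
    "BreakpointFit",
    "jobs_peak",
    "fit_breakpoint",
    "BREAK_SSE_IMPROVEMENT",
]

#: Minimum fractional SSE improvement of the two-segment fit over a single
#: line for the break to count as significant (heuristic).
BREAK_SSE_IMPROVEMENT = 0.20


@dataclass(frozen=True)
class JobSeries:
    """Continuous-variation series: signal change vs host mole fraction."""

    mole_fractions: np.ndarray
    delta_a: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.mole_fractions, dtype=float)
        y = np.asarray(self.delta_a, dtype=float)
        object.__setattr__(self, "mole_fractions", x)
        object.__setattr__(self, "delta_a", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("mole_fractions and delta_a must match in shape")
        if x.size < 5:
            raise ValueError("need >= 5 points for a Job's plot")
        if np.any((x <= 0) | (x >= 1)) or np.any(np.diff(x) <= 0):
            raise ValueError("mole fractions must be strictly increasing "
                             "within (0, 1)")
        if np.any(y < 0):
            raise ValueError("delta_a must be >= 0")


@dataclass(frozen=True)
class StoichiometryResult:
    """Peak location of a Job's plot and the inferred host:guest ratio."""

    peak_fraction: float
    ratio_text: str
    method: str  # "grid-max" or "parabolic-refine"


@dataclass(frozen=True)
class ConductivitySeries:
    """Conductivity (uS/cm) vs host concentration (M), >= 6 points."""

    concs: np.ndarray
    conductivity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.concs, dtype=float)
        y = np.asarray(self.conductivity, dtype=float)
        object.__setattr__(self, "concs", x)
        object.__setattr__(self, "conductivity", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("concs and conductivity must match in shape")
        if x.size < 6:
            raise ValueError("need >= 6 points for a breakpoint fit")
        if np.any(np.diff(x) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class BreakpointFit:
    """Two-segment continuous piecewise-linear fit of a conductometric curve.

    ``significant`` is False when the two-segment fit does not improve the
    single-line SSE by at least :data:`BREAK_SSE_IMPROVEMENT` — i.e. the data
    are effectively one straight line and the breakpoint is not meaningful.
    """

    breakpoint: float
    slope_left: float
    slope_right: float
    intercept: float
    sse: float
    sse_single_line: float
    significant: bool


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float | None:
    """Vertex abscissa of the parabola through three points (None if flat)."""
    x0, x1, x2 = x
    y0, y1, y2 = y
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if denom == 0:
        return None
    num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    return x1 - 0.5 * num / denom


def jobs_peak(series: JobSeries) -> StoichiometryResult:
    """Locate the Job's-plot maximum and infer the host:guest ratio.

    The grid argmax is refined by the vertex of the parabola through the
    peak and its neighbours when the peak is interior.  The ratio is
    ``round(x/(1-x)) : 1`` (or its reciprocal), so a peak at 0.5 reads
    "1 : 1".  A flat series has no peak and is rejected.
    """
    x, y = series.mole_fractions, series.delta_a
    if np.all(y == y[0]):
        raise ValueError("delta_a is constant: no peak")
    i = int(np.argmax(y))
    peak = float(x[i])
    method = "grid-max"
    if 0 < i < x.size - 1:
        vertex = _parabolic_vertex(x[i - 1:i + 2], y[i - 1:i + 2])
        if vertex is not None and x[i - 1] <= vertex <= x[i + 1]:
            peak, method = float(vertex), "parabolic-refine"
    r = peak / (1.0 - peak)
    if r >= 1.0:
        ratio = f"{round(r)} : 1"
    else:
        ratio = f"1 : {round(1.0 / r)}"
    return StoichiometryResult(peak_fraction=peak, ratio_text=ratio,
                               method=method)


def _two_segment_sse(x: np.ndarray, y: np.ndarray, bp: float):
    """Least-squares continuous two-segment fit with a hinge at ``bp``.

    Basis (1, x, max(0, x - bp)) keeps the segments joined at the break.
    Returns (sse, intercept, slope_left, slope_right).
    """
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - bp)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    return sse, float(coef[0]), float(coef[1]), float(coef[1] + coef[2])


def fit_breakpoint(series: ConductivitySeries,
                   min_points_per_segment: int = 3) -> BreakpointFit:
    """Locate the conductometric break by exhaustive candidate search.

    Every interior data abscissa leaving at least ``min_points_per_segment``
    points on each side is tried as the hinge of a continuous two-segment
    least-squares fit; the SSE-minimising candidate wins (ties toward the
    lower concentration).  The fit is compared against a single straight
    line to decide whether the break is significant.
    """
    x, y = series.concs, series.conductivity
    n = x.size
    lo, hi = min_points_per_segment - 1, n - min_points_per_segment
    if lo > hi:
        raise ValueError(
            f"series of {n} points cannot hold {min_points_per_segment} "
            "points per segment"
        )
    candidates = x[lo:hi + 1]
    best = None
    for bp in candidates:
        sse, intercept, s_left, s_right = _two_segment_sse(x, y, bp)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(bp), intercept, s_left, s_right)
    sse, bp, intercept, s_left, s_right = best
    # single-line comparison
    design1 = np.column_stack([np.ones_like(x), x])
    coef1, _, _, _ = np.linalg.lstsq(design1, y, rcond=None)
    resid1 = y - design1 @ coef1
    sse1 = float(resid1 @ resid1)
    significant = sse1 > 0 and sse <= (1.0 - BREAK_SSE_IMPROVEMENT) * sse1
    return BreakpointFit(
        breakpoint=bp, slope_left=s_left, slope_right=s_right,
        intercept=intercept, sse=sse, sse_single_line=sse1,
        significant=significant,
    )
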