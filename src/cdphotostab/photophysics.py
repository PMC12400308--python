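"""Fluorescence-based complexation analysis.

Cyclodextrin complexation quenches the intrinsic fluorescence of the guest
drug.  Two standard treatments of a quenching titration are implemented:

* Stern-Volmer: F0/F = 1 + Ksv [Q], fitted by OLS of F0/F on [Q]; the slope
  is the quenching constant Ksv (L mol^-1).
* Double-logarithmic binding plot: log10((F0-F)/F) = log10 K + n log10 [Q];
  the slope is the number of binding sites n and 10^intercept the binding
  constant K.

Entrapment efficiency (percent of drug held in the host cavity, inferred
from the fluorescence of non-entrapped drug) and percent fluorescence loss
share the arithmetic 100 (F0-F)/F0 but answer different questions, so both
are exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinetics import _ols_line

__all__ = [
    "QuenchingSeries",
    "QuenchingFit",
    "BindingFit",
    "stern_volmer_fit",
    "binding_fit",
    "percent_fluorescence_loss",
    "entrapment_efficiency",
]

logger = logging.getLogger(__name__)

#: |intercept - 1| beyond which the Stern-Volmer fit is flagged in the log.
SV_INTERCEPT_TOLERANCE = 0.1


@dataclass(frozen=True)
class QuenchingSeries:
    """Fluorescence titration: intensity F vs quencher (CD) concentration.

    ``f0`` is the quencher-free intensity; invariant 0 < F <= F0 for a pure
    quencher.  Concentrations are molar, strictly increasing.
    """

    quencher_concs: np.ndarray
    f0: float
    f: np.ndarray
    ph: float = 7.0
    cd_type: str = "gamma"

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_concs, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "quencher_concs", q)
        object.__setattr__(self, "f", f)
        if q.ndim != 1 or f.shape != q.shape:
            raise ValueError("quencher_concs and f must be 1-D, equal length")
        if q.size == 0:
            raise ValueError("empty concentration list")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("quencher concentrations must be positive and "
                             "strictly increasing")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if np.any(f <= 0) or np.any(f > self.f0 * (1 + 1e-12)):
            raise ValueError("require 0 < F <= F0 at every concentration")


@dataclass(frozen=True)
class QuenchingFit:
    """Stern-Volmer regression result.

    The intercept is estimated, not constrained: the model value is 1, and a
    marked deviation is a diagnostic of curvature (mixed static/dynamic
    quenching), which this analysis does not attempt to resolve.
    """

    ksv: float
    intercept: float
    r_squared: float
    se_ksv: float


@dataclass(frozen=True)
class BindingFit:
    """Double-log binding regression: constant K (L mol^-1) and sites n."""

    big_k: float
    n_sites: float
    r_squared: float


def stern_volmer_fit(series: QuenchingSeries) -> QuenchingFit:
    """OLS of F0/F on [Q]; the slope is Ksv."""
    if series.quencher_concs.size < 3:
        raise ValueError("need >= 3 points for the Stern-Volmer fit")
    ratio = series.f0 / series.f
    slope, intercept, r2, se = _ols_line(series.quencher_concs, ratio)
    if abs(intercept - 1.0) > SV_INTERCEPT_TOLERANCE:
        logger.warning(
            "Stern-Volmer intercept %.3f deviates from 1 by more than %.1f: "
            "possible curvature or baseline error", intercept,
            SV_INTERCEPT_TOLERANCE,
        )
    return QuenchingFit(ksv=slope, intercept=intercept, r_squared=r2,
                        se_ksv=se)


def binding_fit(series: QuenchingSeries) -> BindingFit:
    """OLS of log10((F0-F)/F) on log10 [Q]; slope = n, 10^intercept = K."""
    if series.quencher_concs.size < 3:
        raise ValueError("need >= 3 points for the binding fit")
    deficit = series.f0 - series.f
    if np.any(deficit <= 0):
        bad = series.quencher_concs[deficit <= 0][0]
        raise ValueError(
            f"F = F0 at [Q] = {bad:g} M: log[(F0-F)/F] undefined"
        )
    y = np.log10(deficit / series.f)
    x = np.log10(series.quencher_concs)
    slope, intercept, r2, _se = _ols_line(x, y)
    return BindingFit(big_k=10.0 ** intercept, n_sites=slope, r_squared=r2)


def percent_fluorescence_loss(f0: float, f: float) -> float:
    """Percent loss of fluorescence on complexation, 100 (F0 - F)/F0."""
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    return 100.0 * (f0 - f) / f0


def entrapment_efficiency(f0: float, f_free: float) -> float:
    """Percent of drug entrapped in the host, from non-entrapped fluorescence.

    ``f_free`` is the fluorescence of the drug remaining free in solution;
    full entrapment gives 100, no entrapment 0.
    """
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    if not 0.0 <= f_free <= f0:
        raise ValueError(
            f"non-entrapped fluorescence {f_free:g} outside [0, F0={f0:g}]"
        )
    return 100.0 * (f0 - f_free) / f0
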