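"""First-order photolysis kinetics and the CD-concentration secondary regression.

A photolysis run at fixed pH and cyclodextrin concentration gives a time
course of remaining drug; the log-linear fit of that course yields the
apparent first-order rate constant kobs (k0 when no CD is present).  Across
a series of CD concentrations kobs falls linearly,

    kobs = k0 - k2 [CD],

and the negated slope of that secondary regression is the second-order
photochemical interaction constant k2 (M^-1 min^-1) — the strength of the
photostabilization by the host.  A grid of fits over pH assembles into a
kobs-pH profile whose minimum locates the most photostable formulation pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CD_LABELS",
    "TimeCourse",
    "RateFit",
    "InteractionFit",
    "PHProfile",
    "MinimumRate",
    "fit_first_order",
    "fit_interaction",
    "build_profile",
    "minimum_rate_ph",
    "stabilization_percent",
]

CD_LABELS = ("none", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class TimeCourse:
    """One photolysis experiment: remaining-drug response vs irradiation time.

    Parameters
    ----------
    times
        Sampling times in minutes, nonnegative and strictly increasing.
    responses
        Remaining-drug signal (peak area, absorbance or concentration);
        strictly positive so the log transform is defined.
    ph
        Solution pH in [0, 14].
    cd_type
        One of ``none``, ``alpha``, ``beta``, ``gamma``.
    cd_conc
        Cyclodextrin concentration in M (0 when ``cd_type`` is ``none``).
    initial_conc
        Nominal drug concentration in M.
    """

    times: np.ndarray
    responses: np.ndarray
    ph: float = 7.0
    cd_type: str = "none"
    cd_conc: float = 0.0
    initial_conc: float = 5.0e-5

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "responses", r)
        if t.ndim != 1 or r.shape != t.shape:
            raise ValueError("times and responses must be 1-D and equal length")
        if t.size < 3:
            raise ValueError(f"need >= 3 time points, got {t.size}")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if np.any(r <= 0) or not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite and > 0 (log transform)")
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH {self.ph} outside [0, 14]")
        if self.cd_type not in CD_LABELS:
            raise ValueError(f"cd_type must be one of {CD_LABELS}")
        if self.cd_conc < 0:
            raise ValueError("cd_conc must be >= 0")


@dataclass(frozen=True)
class RateFit:
    """Apparent first-order rate constant from one time course.

    ``k`` is kobs in min^-1 (k0 when ``cd_type`` is ``none``); ``se_k`` is
    the OLS standard error of the slope; ``r_squared`` refers to the
    log-linear fit.  The originating conditions are carried along so fits can
    be regrouped for the secondary regression and the pH profile.
    """

    k: float
    ln_intercept: float
    r_squared: float
    se_k: float
    n_points: int
    ph: float = 7.0
    cd_type: str = "none"
    cd_conc: float = 0.0

    def half_life(self) -> float:
        """Half-life ln2/k in minutes (inf for a non-degrading series)."""
        return np.inf if self.k == 0 else np.log(2.0) / self.k


@dataclass(frozen=True)
class InteractionFit:
    """Second-order interaction constant from the kobs vs [CD] regression."""

    ph: float
    cd_type: str
    k2: float
    k_at_zero_cd: float
    r_squared: float
    se_k2: float
    n_pairs: int


class MinimumRate(NamedTuple):
    """Location of the rate minimum on a pH grid."""

    ph: float
    k: float
    tie: bool


def _ols_line(x: np.ndarray, y: np.ndarray):
    """OLS slope/intercept with slope SE and r^2; exact-fit degeneracy handled.

    scipy's linregress returns nan r for zero-variance y; a constant series
    is a perfect zero-slope line here, so r^2 is reported as 1.
    """
    if np.allclose(y, y[0], rtol=0.0, atol=0.0):
        return 0.0, float(y[0]), 1.0, 0.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue) ** 2, float(res.stderr))


def fit_first_order(tc: TimeCourse) -> RateFit:
    """Fit ln(response) vs time by OLS; the negated slope is kobs.

    First-order decay R(t) = R0 exp(-k t) is linear in log space; the fit is
    unweighted, matching the convention under which the published rate
    constants were derived.  ``se_k`` is the standard OLS slope error, zero
    for an exact fit.
    """
    y = np.log(tc.responses)
    slope, intercept, r2, se = _ols_line(tc.times, y)
    return RateFit(
        k=-slope, ln_intercept=intercept, r_squared=r2, se_k=se,
        n_points=tc.times.size, ph=tc.ph, cd_type=tc.cd_type,
        cd_conc=tc.cd_conc,
    )


def fit_interaction(
    pairs: Sequence[tuple[float, float]],
    ph: float,
    cd_type: str,
) -> InteractionFit:
    """Secondary regression of kobs on [CD]: k2 = -slope, k0 = intercept.

    Parameters
    ----------
    pairs
        (cd_conc [M], kobs [min^-1]) tuples; at least 3, with at least two
        distinct concentrations.
    ph, cd_type
        Conditions the pairs share, carried into the result.

    Values are kept at full precision; any rounding (the published tables
    print k2 to 2 decimals) belongs to the display layer.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (cd_conc, kobs) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValueError(
            f"singular design: all CD concentrations identical ({x[0]:g} M)"
        )
    slope, intercept, r2, se = _ols_line(x, y)
    return InteractionFit(
        ph=ph, cd_type=cd_type, k2=-slope, k_at_zero_cd=intercept,
        r_squared=r2, se_k2=se, n_pairs=arr.shape[0],
    )


@dataclass
class PHProfile:
    """kobs as a function of pH, per CD condition.

    ``k0`` maps pH -> rate constant without CD; ``kobs`` maps
    (pH, cd_type, cd_conc) -> rate constant.  Missing cells are simply
    absent — no imputation.
    """

    k0: dict[float, float] = field(default_factory=dict)
    kobs: dict[tuple[float, str, float], float] = field(default_factory=dict)

    @property
    def ph_grid(self) -> tuple[float, ...]:
        phs = set(self.k0) | {key[0] for key in self.kobs}
        return tuple(sorted(phs))

    def series(self, cd_type: str | None = None,
               cd_conc: float | None = None) -> dict[float, float]:
        """Rate constants by pH for one condition (``None`` -> the k0 series)."""
        if cd_type is None or cd_type == "none":
            return dict(sorted(self.k0.items()))
        out = {}
        for (ph, cd, conc), k in self.kobs.items():
            if cd == cd_type and (cd_conc is None or np.isclose(conc, cd_conc)):
                out[ph] = k
        return dict(sorted(out.items()))


def build_profile(rate_fits: Iterable[RateFit]) -> PHProfile:
    """Assemble rate fits into a pH profile, keyed by (pH, cd_type, cd_conc).

    Raises on conflicting duplicates (same key, different k); exact
    duplicates and arbitrary input order are tolerated.  Requires at least
    two distinct pH values.
    """
    profile = PHProfile()
    for fit in rate_fits:
        if fit.cd_type == "none" or fit.cd_conc == 0.0:
            existing = profile.k0.get(fit.ph)
            if existing is not None and not np.isclose(existing, fit.k):
                raise ValueError(f"conflicting k0 entries at pH {fit.ph}")
            profile.k0[fit.ph] = fit.k
        else:
            key = (fit.ph, fit.cd_type, fit.cd_conc)
            existing = profile.kobs.get(key)
            if existing is not None and not np.isclose(existing, fit.k):
                raise ValueError(f"conflicting kobs entries at {key}")
            profile.kobs[key] = fit.k
    if len(profile.ph_grid) < 2:
        raise ValueError("profile needs >= 2 distinct pH values")
    return profile


def minimum_rate_ph(
    profile: PHProfile,
    cd_type: str | None = None,
    cd_conc: float | None = None,
) -> MinimumRate:
    """pH of minimum photodegradation rate for the selected series.

    Ties (several pH values sharing the minimal rate) resolve toward the
    lowest pH and are reported via the ``tie`` flag.
    """
    series = profile.series(cd_type, cd_conc)
    if len(series) < 2:
        raise ValueError("selected series present at fewer than 2 pH values")
    kmin = min(series.values())
    at_min = sorted(ph for ph, k in series.items() if k == kmin)
    return MinimumRate(ph=at_min[0], k=kmin, tie=len(at_min) > 1)


def stabilization_percent(k0: float, kobs: float) -> float:
    """Percent reduction of the degradation rate, 100 (k0 - kobs)/k0.

    Negative values indicate destabilization (kobs above the CD-free rate).
    """
    if k0 <= 0:
        raise ValueError("k0 must be > 0")
    return 100.0 * (k0 - kobs) / k0
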