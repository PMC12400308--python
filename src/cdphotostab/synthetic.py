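"""Synthetic experimental series with the statistical structure the fits assume.

Every input the analysis consumes can be generated here under a fixed seed:
first-order photolysis time courses whose rate falls linearly with CD
concentration (kobs = k0 - k2 [CD]), Stern-Volmer quenching titrations,
power-law binding titrations, 1:1 continuous-variation (Job) series from the
exact equilibrium quadratic, two-segment conductometric curves, and linear
HPLC calibrations.  Setting ``noise_cv = 0`` turns every generator into the
exact closed-form model, so downstream fits must recover the generating
parameters to machine precision — the backbone of the round-trip tests.

Noise is multiplicative lognormal with unit mean (spectroscopic and
chromatographic signals scale with the measurand), except the calibration
generator, which uses additive Gaussian detector noise.  Each series type
draws from its own seeded stream, so adding one series never perturbs
another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import TimeCourse
from .photophysics import QuenchingSeries
from .stoichiometry import ConductivitySeries, JobSeries
from .validation import CalibrationSeries

__all__ = ["SyntheticConfig"]

_STREAM_CODES = {"timecourse": 1, "quench": 2, "bind": 3, "job": 4,
                 "conduct": 5, "calib": 6}

# default 0-3.2 mM conductometric grid (M)
_DEFAULT_COND_CONCS = tuple(np.linspace(0.2e-3, 3.2e-3, 16))

# default calibration levels, 0.5-5.0 x 10^-5 M
_DEFAULT_CALIB_CONCS = tuple(np.linspace(0.5e-5, 5.0e-5, 10))


@dataclass
class SyntheticConfig:
    """Generating parameters for all synthetic series.

    Rate constants are min^-1 (k0) and M^-1 min^-1 (k2); Ksv, the binding
    constant and the Job association constant are L mol^-1; concentrations
    molar.  ``k2_by_cd`` maps each CD type either to a single k2 or to a
    per-pH map.  ``noise_cv`` is the coefficient of variation of the
    multiplicative response noise; 0 disables noise exactly.
    """

    seed: int = 42
    noise_cv: float = 0.02
    n_timepoints: int = 6
    t_max: float | None = None  # minutes; None -> two half-lives
    r0: float = 100.0           # time-course response at t = 0
    f0: float = 100.0           # quencher-free fluorescence
    k0_by_ph: Mapping[float, float] = field(default_factory=lambda: {7.0: 2.22e-3})
    k2_by_cd: Mapping[str, float | Mapping[float, float]] = field(
        default_factory=lambda: {"alpha": 0.30, "beta": 0.63, "gamma": 0.92})
    cd_concs: Sequence[float] = (0.25e-3, 0.50e-3, 0.75e-3, 1.00e-3, 1.25e-3)
    ksv: float = 3.06e3
    bind_k: float = 3.62e3
    bind_n: float = 1.03
    job_total_conc: float = 1.00e-4
    job_assoc_k: float = 3.62e3
    job_delta_eps: float = 1.0e4   # M^-1 (signal per molar complex)
    cond_breakpoint: float = 2.0e-3          # M
    cond_slopes: tuple[float, float] = (-5.0, -1.0)  # uS/cm per mM
    cond_intercept: float = 160.0            # uS/cm at zero CD
    calib_slope: float = 2.56e10
    calib_intercept: float = 8.48e3
    calib_sd: float = 1.25e4

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if any(k <= 0 for k in self.k0_by_ph.values()):
            raise ValueError("all k0 values must be > 0")
        if any(c <= 0 for c in self.cd_concs):
            raise ValueError("cd_concs must be > 0")
        for val in (self.ksv, self.bind_k, self.bind_n, self.job_total_conc,
                    self.job_assoc_k, self.r0, self.f0):
            if val <= 0:
                raise ValueError("ksv, bind_k, bind_n, job_total_conc, "
                                 "job_assoc_k, r0 and f0 must be > 0")
        # every (pH, CD, conc) combination must imply a positive kobs
        for ph in self.k0_by_ph:
            for cd in self.k2_by_cd:
                for conc in self.cd_concs:
                    self.implied_kobs(ph, cd, conc)

    # -- helpers ----------------------------------------------------------

    def k2_for(self, cd_type: str, ph: float) -> float:
        """Resolve k2 for a CD type (scalar or per-pH map)."""
        val = self.k2_by_cd[cd_type]
        if isinstance(val, Mapping):
            try:
                return val[ph]
            except KeyError:
                raise KeyError(f"no k2 for cd_type={cd_type} at pH {ph}")
        return float(val)

    def implied_kobs(self, ph: float, cd_type: str, cd_conc: float) -> float:
        """kobs = k0 - k2 [CD]; rejects combinations implying decay <= 0."""
        k0 = self.k0_by_ph[ph]
        k2 = 0.0 if cd_type == "none" else self.k2_for(cd_type, ph)
        kobs = k0 - k2 * cd_conc
        if kobs <= 0:
            raise ValueError(
                f"non-positive kobs implied at pH {ph}, {cd_type}-CD, "
                f"[CD] = {cd_conc:g} M (k0 = {k0:g}, k2 = {k2:g})"
            )
        return kobs

    def _rng(self, kind: str, key: str = "") -> np.random.Generator:
        return np.random.default_rng(
            [self.seed, _STREAM_CODES[kind], zlib.crc32(key.encode())]
        )

    def _noise(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Unit-mean lognormal factors with CV = noise_cv (ones when 0)."""
        if self.noise_cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(self.noise_cv ** 2))
        return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)

    # -- generators -------------------------------------------------------

    def generate_time_course(self, ph: float, cd_type: str = "none",
                             cd_conc: float = 0.0) -> TimeCourse:
        """First-order decay R(t) = R0 exp(-kobs t) with multiplicative noise.

        Sampling times default to ``n_timepoints`` uniform points spanning
        two half-lives of the implied kobs (or ``t_max`` when set).
        """
        if ph not in self.k0_by_ph:
            raise KeyError(f"no k0 configured for pH {ph}")
        kobs = (self.k0_by_ph[ph] if cd_type == "none"
                else self.implied_kobs(ph, cd_type, cd_conc))
        t_max = self.t_max if self.t_max is not None else 2 * np.log(2) / kobs
        times = np.linspace(0.0, t_max, self.n_timepoints)
        rng = self._rng("timecourse", f"{ph}|{cd_type}|{cd_conc}")
        responses = self.r0 * np.exp(-kobs * times) * self._noise(rng, times.size)
        return TimeCourse(times=times, responses=responses, ph=ph,
                          cd_type=cd_type, cd_conc=cd_conc)

    def generate_rate_grid(self) -> list[TimeCourse]:
        """Time courses for every (pH, CD, conc) combination plus CD-free runs."""
        courses = [self.generate_time_course(ph) for ph in self.k0_by_ph]
        for ph in self.k0_by_ph:
            for cd in self.k2_by_cd:
                for conc in self.cd_concs:
                    courses.append(self.generate_time_course(ph, cd, conc))
        return courses

    def generate_quenching_series(self, cd_type: str = "gamma",
                                  concs: Sequence[float] | None = None,
                                  ph: float = 7.0,
                                  ksv: float | None = None) -> QuenchingSeries:
        """Stern-Volmer titration F = F0 / (1 + Ksv [Q]) with noise."""
        q = np.asarray(self.cd_concs if concs is None else concs, dtype=float)
        if q.size == 0:
            raise ValueError("empty concentration list")
        ksv = self.ksv if ksv is None else ksv
        if ksv < 0:
            raise ValueError("ksv must be >= 0")
        rng = self._rng("quench", f"{cd_type}|{ph}")
        f = self.f0 / (1.0 + ksv * q) * self._noise(rng, q.size)
        f = np.minimum(f, self.f0)  # noise must not push F above F0
        return QuenchingSeries(quencher_concs=q, f0=self.f0, f=f, ph=ph,
                               cd_type=cd_type)

    def generate_binding_series(self, concs: Sequence[float] | None = None,
                                cd_type: str = "gamma", ph: float = 7.0,
                                bind_k: float | None = None,
                                bind_n: float | None = None) -> QuenchingSeries:
        """Power-law binding titration, (F0-F)/F = K [Q]^n, with noise."""
        q = np.asarray(self.cd_concs if concs is None else concs, dtype=float)
        if q.size == 0:
            raise ValueError("empty concentration list")
        big_k = self.bind_k if bind_k is None else bind_k
        n = self.bind_n if bind_n is None else bind_n
        rng = self._rng("bind", f"{cd_type}|{ph}")
        f = self.f0 / (1.0 + big_k * q ** n) * self._noise(rng, q.size)
        f = np.minimum(f, self.f0)
        return QuenchingSeries(quencher_concs=q, f0=self.f0, f=f, ph=ph,
                               cd_type=cd_type)

    def generate_job_series(self, n_points: int = 11,
                            assoc_k: float | None = None) -> JobSeries:
        """Continuous-variation series from the exact 1:1 equilibrium.

        At host mole fraction x the analytic totals are H = x T and
        G = (1-x) T; the complex concentration is the smaller root of
        c^2 - c (H + G + 1/K) + H G = 0 and the signal is proportional to c.
        The mole-fraction grid is uniform and symmetric about 0.5 (which it
        contains when ``n_points`` is odd).
        """
        if n_points < 5:
            raise ValueError("need n_points >= 5")
        k = self.job_assoc_k if assoc_k is None else assoc_k
        if k <= 0:
            raise ValueError("association constant must be > 0")
        x = np.arange(1, n_points + 1) / (n_points + 1)
        t = self.job_total_conc
        h, g = x * t, (1.0 - x) * t
        b = h + g + 1.0 / k
        c = (b - np.sqrt(b * b - 4.0 * h * g)) / 2.0
        rng = self._rng("job", f"{k}")
        delta_a = self.job_delta_eps * c * self._noise(rng, x.size)
        return JobSeries(mole_fractions=x, delta_a=delta_a)

    def generate_conductivity_series(
        self, concs: Sequence[float] | None = None
    ) -> ConductivitySeries:
        """Two-segment piecewise-linear conductivity with a configured break.

        The conductivity falls with slope ``cond_slopes[0]`` (uS/cm per mM)
        up to the breakpoint and ``cond_slopes[1]`` beyond, continuous at
        the break.
        """
        x = np.asarray(_DEFAULT_COND_CONCS if concs is None else concs,
                       dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        bp = self.cond_breakpoint
        if not x[0] <= bp <= x[-1]:
            raise ValueError(f"breakpoint {bp:g} M outside the series range")
        n_left = int(np.sum(x <= bp))
        n_right = int(np.sum(x >= bp))
        if n_left < 3 or n_right < 3:
            raise ValueError("need >= 3 points on each side of the breakpoint")
        s1, s2 = self.cond_slopes
        x_mm, bp_mm = x * 1e3, bp * 1e3
        y = np.where(
            x_mm <= bp_mm,
            self.cond_intercept + s1 * x_mm,
            self.cond_intercept + s1 * bp_mm + s2 * (x_mm - bp_mm),
        )
        rng = self._rng("conduct", "cond")
        y = y * self._noise(rng, x.size)
        return ConductivitySeries(concs=x, conductivity=y)

    def generate_calibration(self, nominal_concs: Sequence[float] | None = None,
                             replicates: int = 3,
                             label: str = "gamma") -> CalibrationSeries:
        """Linear calibration with additive Gaussian detector noise.

        Each of the ``replicates`` calibration curves covers every nominal
        level; the replicate structure is preserved so the intercept SD can
        be estimated across curves.
        """
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        levels = np.asarray(
            _DEFAULT_CALIB_CONCS if nominal_concs is None else nominal_concs,
            dtype=float)
        if np.unique(levels).size < 5:
            raise ValueError("need >= 5 distinct nominal levels")
        x = np.tile(levels, replicates)
        rep = np.repeat(np.arange(replicates), levels.size)
        rng = self._rng("calib", label)
        noise = (rng.normal(0.0, self.calib_sd, size=x.size)
                 if self.calib_sd > 0 else np.zeros(x.size))
        y = self.calib_slope * x + self.calib_intercept + noise
        return CalibrationSeries(nominal_concs=x, responses=y, label=label,
                                 replicate=rep)
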