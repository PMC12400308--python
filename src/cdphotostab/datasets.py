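"""Published parameter sets for the 5-fluorouracil / cyclodextrin system.

The photodegradation of 5-fluorouracil (5-FU) was characterised over
pH 2.0-12.0 alone and in the presence of alpha-, beta- and gamma-cyclodextrin
(0.25-1.25 mM).  The printed result tables of that study — the observed
first-order rate-constant grid, the second-order interaction constants, the
fluorescence quenching/binding parameters and the HPLC calibration
statistics — are small and serve both as regression inputs (the kobs grid is
re-fit to recover k2) and as generating parameters for the synthetic-data
module (the ``paper2025`` bundle).

Units: rate constants min^-1 (kobs, k0) or M^-1 min^-1 (k2); concentrations
molar; Ksv and K in L mol^-1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CD_TYPES = ("alpha", "beta", "gamma")

#: CD concentrations used throughout the photolysis experiments (M).
CD_CONCS = (0.25e-3, 0.50e-3, 0.75e-3, 1.00e-3, 1.25e-3)

#: Nominal drug concentration in the photolysed solutions (M).
DRUG_CONC = 5.0e-5

#: Irradiation vessel volume (L): 100 ml beaker.
IRRADIATION_VOLUME = 0.1

#: pKa of the single N1-H ionisation of 5-FU.
PKA_5FU = 8.0

#: Lamp intensity of the 30 W TUV tube by ferrioxalate actinometry (quanta/s).
LAMP_QUANTA_PER_S = 5.50e18

# ---------------------------------------------------------------------------
# First-order photodegradation rate constants.
# kobs x 10^3 min^-1 at each (pH, CD concentration) for alpha/beta/gamma-CD,
# and k0 x 10^3 min^-1 without CD.
# ---------------------------------------------------------------------------

_KOBS_ROWS: dict[float, tuple[list[float], list[float], list[float], float]] = {
    # pH: ([alpha x5], [beta x5], [gamma x5], k0), all x 1e-3 min^-1
    2.0: ([3.38, 3.26, 3.15, 3.01, 2.89], [3.30, 3.15, 2.96, 2.85, 2.64],
          [3.19, 2.85, 2.49, 2.16, 1.85], 3.51),
    3.0: ([3.01, 2.89, 2.76, 2.64, 2.56], [2.89, 2.72, 2.50, 2.29, 2.10],
          [2.75, 2.42, 2.15, 1.87, 1.50], 3.10),
    4.0: ([2.50, 2.41, 2.29, 2.19, 2.10], [2.48, 2.26, 2.17, 1.97, 1.80],
          [2.31, 2.06, 1.75, 1.49, 1.14], 2.61),
    5.0: ([2.25, 2.15, 2.04, 1.94, 1.86], [2.19, 2.01, 1.85, 1.69, 1.54],
          [2.09, 1.75, 1.48, 1.16, 0.92], 2.36),
    6.0: ([2.03, 1.95, 1.84, 1.80, 1.75], [1.92, 1.75, 1.56, 1.40, 1.21],
          [1.89, 1.67, 1.36, 1.15, 0.85], 2.11),
    7.0: ([2.12, 2.05, 1.98, 1.89, 1.82], [2.04, 1.85, 1.72, 1.59, 1.38],
          [1.98, 1.75, 1.50, 1.32, 1.05], 2.22),
    8.0: ([2.34, 2.27, 2.13, 2.06, 1.94], [2.24, 2.11, 1.92, 1.72, 1.57],
          [2.17, 1.96, 1.72, 1.49, 1.22], 2.45),
    9.0: ([2.49, 2.38, 2.29, 2.13, 2.04], [2.45, 2.28, 2.09, 1.95, 1.80],
          [2.39, 2.17, 1.89, 1.65, 1.51], 2.59),
    10.0: ([2.69, 2.61, 2.51, 2.44, 2.36], [2.60, 2.45, 2.31, 2.09, 1.98],
           [2.52, 2.39, 2.09, 1.99, 1.73], 2.78),
    11.0: ([3.74, 3.68, 3.62, 3.56, 3.49], [3.69, 3.48, 3.27, 3.06, 2.85],
           [3.54, 3.26, 2.89, 2.50, 2.21], 3.81),
    12.0: ([5.12, 5.03, 4.96, 4.88, 4.81], [4.89, 4.52, 4.06, 3.69, 3.47],
           [4.69, 4.26, 3.69, 3.06, 2.62], 5.22),
}

#: First-order rate constants without CD, k0 (min^-1), keyed by pH.
K0_BY_PH: dict[float, float] = {ph: row[3] * 1e-3 for ph, row in _KOBS_ROWS.items()}

#: Published second-order interaction constants k2 (M^-1 min^-1).
K2_BY_PH_CD: dict[tuple[float, str], float] = {}
for _ph, _vals in {
    2.0: (0.49, 0.65, 1.35), 3.0: (0.46, 0.80, 1.22), 4.0: (0.41, 0.66, 1.16),
    5.0: (0.40, 0.65, 1.17), 6.0: (0.28, 0.71, 1.04), 7.0: (0.30, 0.63, 0.92),
    8.0: (0.40, 0.69, 0.95), 9.0: (0.46, 0.65, 0.91), 10.0: (0.33, 0.64, 0.79),
    11.0: (0.25, 0.84, 1.37), 12.0: (0.31, 1.47, 2.14),
}.items():
    for _cd, _k2 in zip(CD_TYPES, _vals):
        K2_BY_PH_CD[(_ph, _cd)] = _k2

#: Quantum yields of photolysis in the presence of gamma-CD (1.25 mM), by pH.
QY_GAMMA_BY_PH: dict[float, float] = {
    2.0: 0.065, 3.0: 0.053, 4.0: 0.040, 5.0: 0.032, 6.0: 0.030, 7.0: 0.037,
    8.0: 0.043, 9.0: 0.053, 10.0: 0.061, 11.0: 0.078, 12.0: 0.095,
}

# ---------------------------------------------------------------------------
# Fluorescence quenching and binding parameters (25 degC).
# ---------------------------------------------------------------------------

#: Stern-Volmer quenching constants Ksv (L mol^-1) per CD.
KSV_BY_CD: dict[str, float] = {"alpha": 1.10e3, "beta": 1.69e3, "gamma": 3.06e3}

#: Binding constants K (L mol^-1) and site numbers n from the double-log plot.
BINDING_BY_CD: dict[str, tuple[float, float]] = {
    "alpha": (2.89e3, 0.94), "beta": (3.11e3, 0.95), "gamma": (3.62e3, 1.03),
}

# ---------------------------------------------------------------------------
# HPLC calibration statistics per CD context (y = m x + c, x in M).
# sd_intercept is the deviation used in the ICH detection limits
# (LOD = 3.3 sigma/S, LOQ = 10 sigma/S).
# ---------------------------------------------------------------------------

CALIBRATION_BY_CD: dict[str, dict[str, float]] = {
    "alpha": {"slope": 1.68e10, "intercept": 0.40e3, "se_slope": 6.26e3,
              "se_intercept": 4.28e3, "sd_intercept": 1.35e4,
              "lod": 2.65e-6, "loq": 8.40e-6, "correlation": 0.9997,
              "accuracy": 100.0, "accuracy_sd": 1.54, "precision_rsd": 1.54},
    "beta": {"slope": 2.13e10, "intercept": 6.39e3, "se_slope": 4.90e3,
             "se_intercept": 3.35e3, "sd_intercept": 0.16e4,
             "lod": 1.64e-6, "loq": 4.97e-6, "correlation": 0.9998,
             "accuracy": 100.1, "accuracy_sd": 1.24, "precision_rsd": 1.23},
    "gamma": {"slope": 2.56e10, "intercept": 8.48e3, "se_slope": 5.78e3,
              "se_intercept": 3.95e3, "sd_intercept": 1.25e4,
              "lod": 1.61e-6, "loq": 4.88e-6, "correlation": 0.9999,
              "accuracy": 99.65, "accuracy_sd": 1.56, "precision_rsd": 1.57},
}

#: Calibration range of the HPLC assay (M).
CALIBRATION_CONCS = tuple(np.linspace(0.5e-5, 5.0e-5, 10))

#: Job continuous-variation total concentration [drug] + [CD] (M).
JOB_TOTAL_CONC = 1.00e-4


def kobs_table() -> pd.DataFrame:
    """Long-format table of the published kobs grid.

    Columns: ``ph``, ``cd_type``, ``cd_conc_M``, ``kobs_per_min`` — the same
    schema the CSV reader uses, so the printed grid can be pushed straight
    through the secondary (kobs vs [CD]) regression.
    """
    rows = []
    for ph, (a, b, g, _k0) in _KOBS_ROWS.items():
        for cd, vals in zip(CD_TYPES, (a, b, g)):
            for conc, k in zip(CD_CONCS, vals):
                rows.append({"ph": ph, "cd_type": cd, "cd_conc_M": conc,
                             "kobs_per_min": k * 1e-3})
    return pd.DataFrame(rows)


def k0_table() -> pd.DataFrame:
    """Table of CD-free rate constants k0, columns ``ph`` and ``k0_per_min``."""
    return pd.DataFrame(
        {"ph": list(K0_BY_PH), "k0_per_min": list(K0_BY_PH.values())}
    )


def k2_table() -> pd.DataFrame:
    """Published second-order constants, columns ``ph``, ``cd_type``, ``k2``."""
    rows = [{"ph": ph, "cd_type": cd, "k2_per_M_min": k2}
            for (ph, cd), k2 in K2_BY_PH_CD.items()]
    return pd.DataFrame(rows)


def paper2025():
    """Synthetic-data configuration seeded with the published parameter grid.

    Returns a :class:`~cdphotostab.synthetic.SyntheticConfig` whose rate
    constants, quenching/binding constants and calibration line are the
    published values, so a synthetic run regenerates series with the same
    structure and magnitudes as the study.
    """
    from .synthetic import SyntheticConfig  # deferred: avoid import cycle

    k2_by_cd = {cd: {ph: K2_BY_PH_CD[(ph, cd)] for ph in K0_BY_PH}
                for cd in CD_TYPES}
    gamma_k, gamma_n = BINDING_BY_CD["gamma"]
    calib = CALIBRATION_BY_CD["gamma"]
    return SyntheticConfig(
        seed=42,
        k0_by_ph=dict(K0_BY_PH),
        k2_by_cd=k2_by_cd,
        cd_concs=CD_CONCS,
        ksv=KSV_BY_CD["gamma"],
        bind_k=gamma_k,
        bind_n=gamma_n,
        job_total_conc=JOB_TOTAL_CONC,
        job_assoc_k=gamma_k,
        calib_slope=calib["slope"],
        calib_intercept=calib["intercept"],
        calib_sd=calib["sd_intercept"],
    )
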