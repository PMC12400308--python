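"""Photon-flux bookkeeping and photolysis quantum yields.

The lamp intensity Q (quanta/s) comes from chemical actinometry; the mercury
TUV tube emits in five bands (254, 313, 366, 405, 436 nm) of which the drug
absorbs the first two.  The absorbed fraction R is the ratio of the absorbed
band areas to the total emission area.  The quantum yield is the standard
photochemical ratio

    Phi = (initial degradation rate, mol/s) / (absorbed photon flux, einstein/s)

with the initial rate taken as k C V from the first-order fit.  Band areas
for the lamp used in the original photolysis study were not published, so
its printed Phi column cannot be recomputed; this module computes Phi for
any supplied spectrum and rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "LAMP_BANDS",
    "DRUG_ABSORBED_BANDS",
    "EINSTEIN_UNIT_NOTE",
    "LampSpectrum",
    "QuantumYieldResult",
    "quanta_to_einstein",
    "absorbed_ratio",
    "quantum_yield",
]

#: Emission bands of the low-pressure mercury TUV tube (nm).
LAMP_BANDS = (254, 313, 366, 405, 436)

#: Bands absorbed by 5-FU (absorption maximum 266 nm).
DRUG_ABSORBED_BANDS = (254, 313)

#: A lamp intensity of 5.50e18 quanta/s equals 9.13e-6 einstein/s; intensity
#: figures quoted as ~9.1 einstein/s omit the 1e-6 scale and are flagged
#: whenever the conversion runs.
EINSTEIN_UNIT_NOTE = (
    "lamp intensity: 5.50e18 quanta/s = 9.13e-6 einstein/s; a quoted value "
    "of order 9.1 einstein/s implies an omitted 1e-6 factor"
)


@dataclass(frozen=True)
class LampSpectrum:
    """Lamp emission-band areas and actinometric intensity.

    ``band_areas`` maps each of the five band wavelengths (nm) to its
    emission area in arbitrary (common) units; ``intensity_quanta`` is the
    total output in quanta/s.
    """

    band_areas: Mapping[int, float]
    intensity_quanta: float

    def __post_init__(self) -> None:
        areas = dict(self.band_areas)
        object.__setattr__(self, "band_areas", areas)
        if set(areas) != set(LAMP_BANDS):
            raise ValueError(f"band_areas must cover exactly {LAMP_BANDS} nm")
        vals = np.array(list(areas.values()), dtype=float)
        if np.any(vals < 0) or not np.any(vals > 0):
            raise ValueError("band areas must be >= 0 with at least one > 0")
        if self.intensity_quanta <= 0:
            raise ValueError("intensity_quanta must be > 0")


@dataclass(frozen=True)
class QuantumYieldResult:
    """Quantum yield Phi with its absorbed-fraction and flux bookkeeping."""

    phi: float
    r_ratio: float
    absorbed_flux: float  # einstein/s


def quanta_to_einstein(q: float) -> float:
    """Convert a photon rate from quanta/s to einstein/s (divide by N_A)."""
    if q < 0:
        raise ValueError("photon rate must be >= 0")
    return q / Avogadro


def absorbed_ratio(spec: LampSpectrum,
                   absorbed_bands: Iterable[int] = DRUG_ABSORBED_BANDS) -> float:
    """Fraction R of the lamp emission area falling in the absorbed bands."""
    bands = tuple(absorbed_bands)
    unknown = set(bands) - set(LAMP_BANDS)
    if unknown:
        raise ValueError(f"unknown bands {sorted(unknown)}; lamp emits at "
                         f"{LAMP_BANDS} nm")
    total = sum(spec.band_areas.values())
    return sum(spec.band_areas[b] for b in bands) / total


def quantum_yield(
    rate,
    drug_conc: float,
    volume: float,
    spec: LampSpectrum,
    absorbed_bands: Iterable[int] = DRUG_ABSORBED_BANDS,
) -> QuantumYieldResult:
    """Quantum yield of photodegradation from a first-order rate constant.

    Parameters
    ----------
    rate
        A :class:`~cdphotostab.kinetics.RateFit` or a bare rate constant in
        min^-1.
    drug_conc
        Initial drug concentration (M).
    volume
        Irradiated solution volume (L).
    spec
        Lamp spectrum providing band areas and actinometric intensity.
    absorbed_bands
        Bands the drug absorbs; default 254 and 313 nm.

    The numerator is the initial degradation rate k C V in mol/s; the
    denominator the absorbed photon flux R Q / N_A in einstein/s.
    """
    k = float(getattr(rate, "k", rate))
    if k <= 0:
        raise ValueError("rate constant must be > 0")
    if drug_conc <= 0 or volume <= 0:
        raise ValueError("drug_conc and volume must be > 0")
    r = absorbed_ratio(spec, absorbed_bands)
    if r == 0:
        raise ValueError("absorbed fraction R = 0: quantum yield undefined")
    absorbed_flux = quanta_to_einstein(spec.intensity_quanta) * r
    mol_per_s = (k / 60.0) * drug_conc * volume
    return QuantumYieldResult(phi=mol_per_s / absorbed_flux, r_ratio=r,
                              absorbed_flux=absorbed_flux)
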