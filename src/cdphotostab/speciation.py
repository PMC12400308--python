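"""Monoprotic acid-base speciation of the drug.

5-FU ionises once in the accessible pH range (N1-H deprotonation, pKa 8.0)
and forms no cation, so only the neutral and anionic species matter.  The
anion fraction follows the Henderson-Hasselbalch relation

    f_anion = 1 / (1 + 10^(pKa - pH)),

with f_neutral its complement.  Species fractions annotate the kobs-pH
profile: the rate maximum at high pH coincides with near-complete
ionisation, identifying the anion as the photolabile form.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SpeciesFractions", "species_fractions", "DEFAULT_PKA"]

#: N1-H pKa of 5-fluorouracil.
DEFAULT_PKA = 8.0


@dataclass(frozen=True)
class SpeciesFractions:
    """Neutral and anionic fractions at one pH; they sum to 1."""

    ph: float
    pka: float
    f_neutral: float
    f_anion: float


def species_fractions(ph: float, pka: float = DEFAULT_PKA) -> SpeciesFractions:
    """Henderson-Hasselbalch fractions of a monoprotic acid at ``ph``.

    Pure function; pH and pKa outside [0, 14] are accepted (the relation is
    defined everywhere) but are outside the physically sensible range.
    """
    f_anion = 1.0 / (1.0 + 10.0 ** (pka - ph))
    return SpeciesFractions(ph=ph, pka=pka, f_neutral=1.0 - f_anion,
                            f_anion=f_anion)
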