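"""Vesicle geometry vs quantal content vs molar concentration.

A quantal release event empties one vesicle; given the number of
transmitter molecules per quantum (amperometric quantal content) and a
vesicle diameter, the implied intravesicular concentration is

    c = (molecules / N_A) / V(D),    V(D) = (4/3) pi (D/2)^3,

with V converted from nm^3 to litres (1 nm^3 = 1e-24 L).  For the
typical brainstem quantum of ~1e5 molecules in a ~317-nm vesicle this
lands at roughly 10 mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AVOGADRO",
    "QuantalEstimate",
    "sphere_volume",
    "concentration_from_quantum",
    "molecules_from_concentration",
    "estimate",
]

#: Exact SI value (mol^-1).
AVOGADRO = 6.02214076e23

_NM3_TO_LITER = 1e-24


def sphere_volume(diameter_nm: float) -> float:
    """Volume in litres of a sphere of the given diameter in nm."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    return (4.0 / 3.0) * np.pi * (diameter_nm / 2.0) ** 3 * _NM3_TO_LITER


def concentration_from_quantum(molecules: float, diameter_nm: float) -> float:
    """Molar concentration of ``molecules`` inside a sphere of ``diameter_nm``."""
    if molecules < 1:
        raise ValueError("molecules must be >= 1")
    return (molecules / AVOGADRO) / sphere_volume(diameter_nm)


def molecules_from_concentration(concentration_molar: float, diameter_nm: float) -> int:
    """Molecule count giving the stated concentration, nearest integer."""
    if concentration_molar <= 0:
        raise ValueError("concentration must be > 0")
    return int(round(concentration_molar * sphere_volume(diameter_nm) * AVOGADRO))


@dataclass(frozen=True)
class QuantalEstimate:
    molecules_per_quantum: float
    diameter_nm: float
    volume_liters: float
    concentration_molar: float

    @property
    def concentration_mM(self) -> float:
        return 1e3 * self.concentration_molar


def estimate(molecules: float, diameter_nm: float) -> QuantalEstimate:
    """Bundle volume and concentration for one (quantum, diameter) pair."""
    return QuantalEstimate(
        molecules_per_quantum=molecules,
        diameter_nm=diameter_nm,
        volume_liters=sphere_volume(diameter_nm),
        concentration_molar=concentration_from_quantum(molecules, diameter_nm),
    )
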