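"""Negative-mode ESI ion arithmetic.

Proanthocyanidins ionize in negative mode by deprotonation ([M−zH]^z−,
z ∈ {1, 2}) or as a formate adduct ([M+HCOO]⁻, singly charged only).
The m/z convention carries charge by proton removal:

    deprotonated:  m/z = (M − z·m_proton) / z
    formate:       m/z = M + m_HCOO⁻           (44.998203 Da, electron included)

which reproduces printed flavan-3-ol fragment m/z values at 4 decimals
(e.g. 305.0667 for deprotonated gallocatechin).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .formula import FORMATE_MASS, PROTON_MASS

__all__ = [
    "Adduct",
    "IonSpecies",
    "IonError",
    "mz_for_ion",
    "neutral_mass_from_ion",
    "ppm_error",
    "DEPROTONATED_1",
    "DEPROTONATED_2",
    "FORMATE_1",
]


class IonError(ValueError):
    """Unsupported adduct/charge combination or invalid mass."""


class Adduct(enum.Enum):
    DEPROTONATED = "deprotonated"
    FORMATE = "formate"


@dataclass(frozen=True)
class IonSpecies:
    """One negative-mode ion interpretation: adduct kind + charge magnitude."""

    adduct: Adduct = Adduct.DEPROTONATED
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge not in (1, 2):
            raise IonError(f"charge magnitude must be 1 or 2, got {self.charge}")
        if self.adduct is Adduct.FORMATE and self.charge != 1:
            raise IonError("formate adduct is only defined for singly charged ions")

    def __str__(self) -> str:
        if self.adduct is Adduct.FORMATE:
            return "[M+HCOO]-"
        return f"[M-{self.charge}H]{self.charge}-" if self.charge > 1 else "[M-H]-"


DEPROTONATED_1 = IonSpecies(Adduct.DEPROTONATED, 1)
DEPROTONATED_2 = IonSpecies(Adduct.DEPROTONATED, 2)
FORMATE_1 = IonSpecies(Adduct.FORMATE, 1)

#: All ion interpretations the extraction settings allow.
DEFAULT_ION_SPECIES = (DEPROTONATED_1, DEPROTONATED_2, FORMATE_1)


def mz_for_ion(neutral_mass: float, ion: IonSpecies) -> float:
    """m/z of a neutral molecule observed as ``ion``."""
    if neutral_mass <= 0:
        raise IonError(f"neutral mass must be positive, got {neutral_mass}")
    if ion.adduct is Adduct.FORMATE:
        return neutral_mass + FORMATE_MASS
    return (neutral_mass - ion.charge * PROTON_MASS) / ion.charge


def neutral_mass_from_ion(mz: float, ion: IonSpecies) -> float:
    """Exact algebraic inverse of :func:`mz_for_ion`."""
    if mz <= 0:
        raise IonError(f"m/z must be positive, got {mz}")
    if ion.adduct is Adduct.FORMATE:
        return mz - FORMATE_MASS
    return mz * ion.charge + ion.charge * PROTON_MASS


def ppm_error(theoretical: float, experimental: float, *, signed: bool = False) -> float:
    """Relative mass error in parts per million.

    Unsigned by default (mass-error tables report all-positive columns);
    the signed variant uses the (theoretical − experimental)/theoretical
    convention.
    """
    if theoretical <= 0:
        raise IonError(f"theoretical mass must be positive, got {theoretical}")
    err = (theoretical - experimental) / theoretical * 1e6
    return err if signed else abs(err)
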