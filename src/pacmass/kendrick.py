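"""Kendrick mass-defect analysis with the catechin extension unit as base.

The classic Kendrick transform rescales masses so a chosen repeat unit has
integer mass; homologues differing by whole repeat units then share a mass
defect.  Here the repeat unit is the flavan-3-ol extension unit C15H12O6
(catechin less the two hydrogens lost on bond formation, 288.063388 Da):

    Kendrick mass (KM)  = IUPAC (neutral monoisotopic) mass × 288 / m(C15H12O6)
    Kendrick nominal mass (KNM) = round(KM)
    Kendrick mass defect (KMD)  = KNM − KM

Every pure-(epi)catechin polymer lands on KMD −0.0152; adding an oxygen
(a gallocatechin in place of a catechin) shifts (KNM, KMD) by (+16,
+0.0086) and adding a gallate ester (C7H4O4) by (+152, +0.0225), so the
(KNM, KMD) plane resolves composition by inspection.

Kendrick quantities are computed from the *neutral* monoisotopic mass,
not the ion m/z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .formula import ChemicalFormula, monoisotopic_mass, parse_formula

__all__ = [
    "BASE_UNIT",
    "BASE_UNIT_MASS",
    "KendrickPoint",
    "kendrick_transform",
    "kmd_shift",
    "kendrick_plot_data",
    "abundance_plot_data",
]

#: The repeat unit of the modified Kendrick scale.
BASE_UNIT = ChemicalFormula("C15H12O6")
#: Full-precision monoisotopic mass of the base unit (≈ 288.063388 Da).
BASE_UNIT_MASS = monoisotopic_mass(BASE_UNIT)
#: Nominal mass assigned to the base unit on the Kendrick scale.
BASE_UNIT_NOMINAL = 288


@dataclass(frozen=True)
class KendrickPoint:
    """One mass on the modified Kendrick scale."""

    iupac_mass: float
    kendrick_mass: float
    knm: int
    kmd: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def kendrick_transform(neutral_mass: float, *, divisor: float = BASE_UNIT_MASS) -> KendrickPoint:
    """Map a neutral monoisotopic mass onto the Kendrick scale.

    ``divisor`` defaults to the full-precision base-unit mass; pass the
    printed constant 288.0634 for strict emulation of the published
    arithmetic (both reproduce all printed 4-dp values).
    """
    if neutral_mass <= 0:
        raise ValueError(f"mass must be positive, got {neutral_mass}")
    km = neutral_mass * BASE_UNIT_NOMINAL / divisor
    knm = _round_half_away(km)
    return KendrickPoint(iupac_mass=neutral_mass, kendrick_mass=km, knm=knm, kmd=knm - km)


def kmd_shift(delta: ChemicalFormula | str) -> tuple[int, float]:
    """(KNM, KMD) shift caused by adding ``delta`` to any polymer.

    Because the transform is linear, adding a fixed formula moves every
    compound by the same (ΔKNM, ΔKMD) up to rounding in the 4th decimal:
    O → (16, +0.0086); gallate C7H4O4 → (152, +0.0225); one base unit
    C15H12O6 → (288, 0.0) exactly.
    """
    if isinstance(delta, str):
        delta = parse_formula(delta)
    mass = monoisotopic_mass(delta)
    if mass <= 0:
        raise ValueError("delta formula must have positive mass")
    point = kendrick_transform(mass)
    return point.knm, point.kmd


def kendrick_plot_data(db, identified: Iterable[ChemicalFormula | str] = ()) -> pd.DataFrame:
    """KMD-vs-KNM scatter table for a compound database.

    One row per database entry (columns ``knm, kmd, dp, identified``);
    ``identified`` flags entries whose formula was matched in a sample, the
    encircled points of the defect plot.
    """
    wanted = {f if isinstance(f, str) else f.hill() for f in identified}
    rows = []
    for comp in db:
        point = kendrick_transform(comp.neutral_mass)
        rows.append(
            {
                "name": comp.name,
                "formula": comp.formula.hill(),
                "knm": point.knm,
                "kmd": round(point.kmd, 4),
                "dp": comp.dp,
                "identified": comp.formula.hill() in wanted,
            }
        )
    return pd.DataFrame(rows)


def abundance_plot_data(groups, *, logger=None) -> pd.DataFrame:
    """RT-vs-KNM bubble-chart table from matched compound groups.

    Each group contributes one row per (sample, isomer rt): ``sample, knm,
    rt, area`` with area the per-sample summed abundance (dot size).
    Groups without any recorded area are excluded with a warning.
    """
    import logging

    log = logger or logging.getLogger(__name__)
    rows = []
    for group in groups:
        areas: Mapping[str, float] = group.sample_abundance
        if not areas or all(a == 0 for a in areas.values()):
            log.warning("group %s has no recorded peak area; excluded", group.formula)
            continue
        knm = kendrick_transform(monoisotopic_mass(group.formula)).knm
        for sample, area in sorted(areas.items()):
            for rt in group.rt_list:
                rows.append({"sample": sample, "knm": knm, "rt": rt, "area": area})
    return pd.DataFrame(rows, columns=["sample", "knm", "rt", "area"])
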