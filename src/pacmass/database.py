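"""Theoretical proanthocyanidin compound database.

Proanthocyanidins are B-type polymers of four grape-derived flavan-3-ol
monomers: (epi)catechin (``Cat``, C15H14O6), (epi)gallocatechin (``GalCat``,
C15H14O7, pyrogallol B-ring), and their 3-O-gallate esters (``Cat:Gal``
C22H18O10, ``GalCat:Gal`` C22H18O11).  Each interflavan bond (4→8 or 4→6)
removes two hydrogens, so a polymer of composition {unit_i: n_i} has

    formula = Σ n_i · monomer_i  −  (DP − 1) · H2,      DP = Σ n_i.

Epimers and linkage regiochemistry share a formula, so the database is
compositional: one entry per *multiset* of subunits.  Enumerating all
multisets of size 2–10 over the four monomers yields the 996-entry
default database.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .formula import ChemicalFormula, monoisotopic_mass

__all__ = [
    "MonomerUnit",
    "PolymerComposition",
    "CompoundDatabase",
    "DatabaseConfigError",
    "DEFAULT_MONOMERS",
    "MONOMERS_BY_CODE",
    "enumerate_compositions",
    "build_default_database",
    "sequence_isomer_count",
    "parse_composition_name",
]

H2 = ChemicalFormula("H2")


class DatabaseConfigError(ValueError):
    """Invalid enumeration configuration."""


@dataclass(frozen=True)
class MonomerUnit:
    """One flavan-3-ol subunit type.

    ``b_ring_hydroxyls`` is 2 for a catechol B-ring (Cat, Cat:Gal) and 3
    for a pyrogallol B-ring (GalCat, GalCat:Gal); ``has_gallate`` marks the
    3-O-gallate esters.
    """

    code: str
    formula: ChemicalFormula
    has_gallate: bool
    b_ring_hydroxyls: int

    @property
    def mass(self) -> float:
        return self.formula.mass


DEFAULT_MONOMERS: tuple[MonomerUnit, ...] = (
    MonomerUnit("Cat", ChemicalFormula("C15H14O6"), False, 2),
    MonomerUnit("GalCat", ChemicalFormula("C15H14O7"), False, 3),
    MonomerUnit("Cat:Gal", ChemicalFormula("C22H18O10"), True, 2),
    MonomerUnit("GalCat:Gal", ChemicalFormula("C22H18O11"), True, 3),
)

MONOMERS_BY_CODE: dict[str, MonomerUnit] = {m.code: m for m in DEFAULT_MONOMERS}


@dataclass(frozen=True)
class PolymerComposition:
    """A multiset of flavan-3-ol subunits with its derived chemistry.

    ``units`` maps each subunit to its count (counts > 0 only).  The
    formula, neutral monoisotopic mass and canonical display name
    (codes joined by ``-`` in registry order, e.g. ``Cat-Cat-GalCat``)
    are derived.
    """

    units: tuple[tuple[MonomerUnit, int], ...]

    @staticmethod
    def from_counts(counts: dict[MonomerUnit, int] | Iterable[tuple[MonomerUnit, int]]) -> "PolymerComposition":
        items = dict(counts)
        order = {m: i for i, m in enumerate(DEFAULT_MONOMERS)}
        kept = tuple(
            (m, n)
            for m, n in sorted(items.items(), key=lambda kv: order.get(kv[0], len(order)))
            if n > 0
        )
        if not kept:
            raise DatabaseConfigError("a polymer needs at least one subunit")
        if any(n < 0 for _, n in items.items()):
            raise DatabaseConfigError("subunit counts must be non-negative")
        return PolymerComposition(kept)

    def count(self, code: str) -> int:
        for m, n in self.units:
            if m.code == code:
                return n
        return 0

    @property
    def dp(self) -> int:
        """Degree of polymerization."""
        return sum(n for _, n in self.units)

    @property
    def gallate_count(self) -> int:
        return sum(n for m, n in self.units if m.has_gallate)

    @property
    def extra_oxygen_count(self) -> int:
        """Number of pyrogallol (trihydroxylated) B-rings."""
        return sum(n for m, n in self.units if m.b_ring_hydroxyls == 3)

    @property
    def formula(self) -> ChemicalFormula:
        total = ChemicalFormula()
        for m, n in self.units:
            total = total + m.formula * n
        return total - H2 * (self.dp - 1)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def name(self) -> str:
        parts: list[str] = []
        for m, n in self.units:
            parts.extend([m.code] * n)
        return "-".join(parts)

    def __str__(self) -> str:
        return self.name


def parse_composition_name(name: str) -> PolymerComposition:
    """Parse ``"Cat-Cat:Gal"``-style names back into a composition."""
    counts: dict[MonomerUnit, int] = {}
    for code in name.split("-"):
        try:
            m = MONOMERS_BY_CODE[code]
        except KeyError:
            raise DatabaseConfigError(f"unknown subunit code {code!r} in {name!r}")
        counts[m] = counts.get(m, 0) + 1
    return PolymerComposition.from_counts(counts)


def _canonical_sort_key(comp: PolymerComposition) -> tuple:
    # Canonical representative among formula-sharing compositions: maximize
    # GalCat:Gal count, then Cat count, then lexicographic name.
    return (-comp.count("GalCat:Gal"), -comp.count("Cat"), comp.name)


@dataclass
class CompoundDatabase:
    """Ordered collection of polymer compositions with mass/formula indexes."""

    compositions: list[PolymerComposition]
    dp_min: int
    dp_max: int
    subunits: tuple[MonomerUnit, ...]
    _by_formula: dict[str, list[PolymerComposition]] = field(init=False, repr=False)
    _formula_masses: np.ndarray = field(init=False, repr=False)
    _formula_order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_formula: dict[str, list[PolymerComposition]] = {}
        for comp in self.compositions:
            by_formula.setdefault(comp.formula.hill(), []).append(comp)
        for comps in by_formula.values():
            comps.sort(key=_canonical_sort_key)
        self._by_formula = by_formula
        pairs = sorted(
            ((monoisotopic_mass(f), f) for f in by_formula), key=lambda p: p[0]
        )
        self._formula_masses = np.array([p[0] for p in pairs])
        self._formula_order = [p[1] for p in pairs]

    def __len__(self) -> int:
        return len(self.compositions)

    def __iter__(self) -> Iterator[PolymerComposition]:
        return iter(self.compositions)

    def __contains__(self, comp: PolymerComposition) -> bool:
        return comp in self._by_formula.get(comp.formula.hill(), [])

    @property
    def formulas(self) -> list[str]:
        """Distinct formulas, ascending by mass."""
        return list(self._formula_order)

    def candidates_for_formula(self, formula: ChemicalFormula | str) -> list[PolymerComposition]:
        """All compositions sharing ``formula``, canonical representative first."""
        key = formula if isinstance(formula, str) else formula.hill()
        return list(self._by_formula.get(key, []))

    def query_mass(self, neutral_mass: float, ppm_tolerance: float) -> list[tuple[str, float]]:
        """Distinct formulas within ``ppm_tolerance`` (inclusive) of a neutral mass.

        Returns (formula, unsigned ppm error) pairs ordered by |ppm|.  The
        tolerance is relative to the theoretical mass.
        """
        masses = self._formula_masses
        half = ppm_tolerance * 1e-6
        lo = np.searchsorted(masses, neutral_mass / (1 + half) * (1 - 1e-12), side="left")
        hi = np.searchsorted(
            masses, (neutral_mass / (1 - half) if half < 1 else np.inf) * (1 + 1e-12), side="right"
        )
        hits = []
        for i in range(lo, hi):
            theo = masses[i]
            ppm = abs(theo - neutral_mass) / theo * 1e6
            # inclusive bound; the 1e-9 ppm slack absorbs float round-off at
            # the boundary without admitting genuinely out-of-tolerance masses
            if ppm <= ppm_tolerance + 1e-9:
                hits.append((self._formula_order[i], ppm))
        hits.sort(key=lambda p: p[1])
        return hits

    def to_dataframe(self) -> pd.DataFrame:
        """One row per composition with formula, mass, and Kendrick columns."""
        from .kendrick import kendrick_transform

        rows = []
        for comp in self.compositions:
            point = kendrick_transform(comp.neutral_mass)
            rows.append(
                {
                    "name": comp.name,
                    "dp": comp.dp,
                    "n_cat": comp.count("Cat"),
                    "n_galcat": comp.count("GalCat"),
                    "n_catgal": comp.count("Cat:Gal"),
                    "n_galcatgal": comp.count("GalCat:Gal"),
                    "formula": comp.formula.hill(),
                    "neutral_mass": comp.neutral_mass,
                    "knm": point.knm,
                    "kmd": point.kmd,
                }
            )
        return pd.DataFrame(rows)

    def export_csv(self, destination) -> None:
        """Write the database table (masses at 6 dp, KMD at 4 dp).

        Row order is deterministic: DP ascending, then canonical name; two
        exports of the same database are byte-identical.
        """
        df = self.to_dataframe()
        df["neutral_mass"] = df["neutral_mass"].map(lambda m: f"{m:.6f}")
        df["kmd"] = df["kmd"].map(lambda d: f"{d:.4f}")
        df.to_csv(destination, index=False)


def enumerate_compositions(
    dp_min: int = 2,
    dp_max: int = 10,
    subunits: Sequence[MonomerUnit] = DEFAULT_MONOMERS,
) -> CompoundDatabase:
    """Enumerate every subunit multiset with DP in [dp_min, dp_max].

    The entry count is Σ_dp C(dp + s − 1, s − 1) for s subunit types; the
    default four-monomer, DP 2–10 database has 996 entries.
    """
    if not subunits:
        raise DatabaseConfigError("subunit list must not be empty")
    if dp_min < 1 or dp_min > dp_max:
        raise DatabaseConfigError(
            f"invalid DP range [{dp_min}, {dp_max}]: need 1 <= dp_min <= dp_max"
        )
    codes = [m.code for m in subunits]
    if len(set(codes)) != len(codes):
        raise DatabaseConfigError("duplicate subunit codes in enumeration")
    comps: list[PolymerComposition] = []
    for dp in range(dp_min, dp_max + 1):
        for combo in itertools.combinations_with_replacement(subunits, dp):
            counts: dict[MonomerUnit, int] = {}
            for m in combo:
                counts[m] = counts.get(m, 0) + 1
            comps.append(PolymerComposition.from_counts(counts))
    comps.sort(key=lambda c: (c.dp, c.name))
    return CompoundDatabase(comps, dp_min, dp_max, tuple(subunits))


def build_default_database() -> CompoundDatabase:
    """The 996-entry DP 2–10 database over the four grape monomers."""
    return enumerate_compositions(2, 10, DEFAULT_MONOMERS)


def sequence_isomer_count(n_subunit_types: int, dp: int) -> int:
    """Distinct linear sequences for a fixed linkage type: types ** DP.

    E.g. a tetramer over {catechin, gallocatechin} has 2**4 = 16 sequence
    isomers, all sharing the compositional database's handful of formulas.
    """
    if n_subunit_types < 1 or dp < 1:
        raise DatabaseConfigError("subunit-type count and DP must both be >= 1")
    return n_subunit_types ** dp


def multiset_count(n_types: int, dp_min: int, dp_max: int) -> int:
    """Closed-form entry count Σ_dp C(dp + s − 1, s − 1)."""
    return sum(math.comb(dp + n_types - 1, n_types - 1) for dp in range(dp_min, dp_max + 1))
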