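"""Chemical formula arithmetic and monoisotopic masses.

A :class:`ChemicalFormula` is an immutable element → count mapping with
formula algebra (``+``, ``-``, scalar ``*``) and Hill-order rendering
(C first, then H, then remaining elements alphabetically).  Monoisotopic
masses use CODATA/IUPAC values for the most abundant isotope of each
element; flavan-3-ol chemistry only exercises C, H and O, but the element
table is extensible via :func:`register_element`.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from typing import Iterator

__all__ = [
    "ChemicalFormula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FORMATE_MASS",
    "register_element",
]

#: Monoisotopic atomic masses in Da (most abundant isotope).
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton in Da (H atom minus one electron).
PROTON_MASS = 1.007276467
#: Electron rest mass in Da.
ELECTRON_MASS = 0.000548580


def register_element(symbol: str, mass: float) -> None:
    """Register (or override) a monoisotopic atomic mass."""
    if not re.fullmatch(r"[A-Z][a-z]?", symbol):
        raise FormulaError(f"invalid element symbol {symbol!r}")
    if mass <= 0:
        raise FormulaError(f"non-positive mass for element {symbol!r}")
    MONOISOTOPIC_MASSES[symbol] = float(mass)


class FormulaError(ValueError):
    """Malformed formula string or unknown element."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class ChemicalFormula(Mapping):
    """Immutable element-count map, e.g. ``ChemicalFormula("C30H26O12")``.

    Counts are non-negative integers; elements with count zero are dropped
    so two formulas compare equal iff their non-zero counts agree.
    """

    __slots__ = ("_counts",)

    def __init__(self, source: str | Mapping[str, int] | None = None, **counts: int):
        if isinstance(source, str):
            merged = dict(_parse(source))
        elif source is not None:
            merged = dict(source)
        else:
            merged = {}
        merged.update(counts)
        clean: dict[str, int] = {}
        for elem, n in merged.items():
            if not isinstance(n, int):
                raise FormulaError(f"count for {elem!r} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count {n} for element {elem!r}")
            if n:
                clean[elem] = n
        self._counts = clean

    # Mapping interface -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts.get(elem, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, elem: object) -> bool:
        return elem in self._counts

    # Algebra ------------------------------------------------------------
    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self._counts)
        for elem, n in other.items():
            counts[elem] = counts.get(elem, 0) + n
        return ChemicalFormula(counts)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self._counts)
        for elem, n in other.items():
            counts[elem] = counts.get(elem, 0) - n
            if counts[elem] < 0:
                raise FormulaError(
                    f"subtraction drives {elem} below zero: {self} - {other}"
                )
        return ChemicalFormula(counts)

    def __mul__(self, k: int) -> "ChemicalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative int, got {k!r}")
        return ChemicalFormula({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ChemicalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # Rendering ----------------------------------------------------------
    def hill(self) -> str:
        """Render in Hill order: C, H, then other elements alphabetically."""
        parts = []
        rest = sorted(e for e in self._counts if e not in ("C", "H"))
        order = [e for e in ("C", "H") if e in self._counts] + rest
        for elem in order:
            n = self._counts[elem]
            parts.append(elem if n == 1 else f"{elem}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ChemicalFormula({self.hill()!r})"

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return monoisotopic_mass(self)


def _parse(text: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    if not stripped:
        return counts
    for match in _TOKEN.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        pos = match.end()
        elem, digits = match.groups()
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n <= 0:
                raise FormulaError(
                    f"malformed formula {text!r}: non-positive count {digits!r} for {elem}"
                )
        counts[elem] = counts.get(elem, 0) + n
    if pos != len(stripped):
        raise FormulaError(
            f"malformed formula {text!r}: trailing garbage {stripped[pos:]!r}"
        )
    return counts


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string, e.g. ``"C30H26O12"``.

    Round-trips with :meth:`ChemicalFormula.hill`.
    """
    return ChemicalFormula(_parse(text))


def monoisotopic_mass(formula: ChemicalFormula | str | Mapping[str, int]) -> float:
    """Monoisotopic mass of a formula in Da (empty formula → 0.0)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for elem, n in formula.items():
        try:
            total += n * MONOISOTOPIC_MASSES[elem]
        except KeyError:
            raise FormulaError(f"no tabulated monoisotopic mass for element {elem!r}")
    return total


#: m/z shift of the formate adduct [M+HCOO]⁻ (HCOO plus one electron), Da.
FORMATE_MASS = (
    MONOISOTOPIC_MASSES["C"]
    + MONOISOTOPIC_MASSES["H"]
    + 2 * MONOISOTOPIC_MASSES["O"]
    + ELECTRON_MASS
)
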