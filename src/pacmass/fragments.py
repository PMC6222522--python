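"""Diagnostic MS/MS fragment prediction and spectrum annotation.

Flavan-3-ol oligomers fragment in negative mode along three
well-characterized pathways plus small neutral losses:

* **QM** (quinone methide fission) cleaves an interflavan bond.  The
  sub-polymer containing the terminal (bottom) unit leaves as the intact
  deprotonated species; the extension-side sub-polymer leaves 2 Da
  lighter.  The single-unit QM ions are the composition diagnostics:
  e.g. deprotonated catechin 289.0718 (terminal) / 287.0561 (extension),
  gallocatechin 305.0667, catechin gallate 441.0827.
* **HRF** (heterocyclic ring fission) splits the C-ring, losing
  phloroglucinol (C6H6O3, 126.0317 Da) while keeping the B-ring
  substitution pattern on the charged fragment.
* **RDA** (retro-Diels-Alder) cleaves the C-ring losing the
  B-ring-bearing moiety: C8H8O3 (152.0473, catechol B-ring) or C8H8O4
  (168.0423, pyrogallol B-ring).
* Water (18.0106) and, for galloylated species, gallate (C7H4O4,
  152.0110) losses chain onto any of the above.

Fragments are generated *compositionally* (over subunit multisets), the
union over all sequence isomers — mirroring how presence/absence of
diagnostic ions is argued, rather than assuming a known sequence.
Conventional structure labels: HRF product = I (− water = II), QM
products = III, RDA product = IV (− water = V), precursor − gallate = VI.
For galloylated precursors the named structures I/II/IV/V include the
loss of the gallate ester(s), matching observed spectra of galloylated
dimers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .database import H2, MonomerUnit, PolymerComposition
from .formula import ChemicalFormula, FormulaError, monoisotopic_mass
from .ions import DEPROTONATED_1, IonSpecies, mz_for_ion, ppm_error

__all__ = [
    "NEUTRAL_LOSSES",
    "Fragment",
    "AnnotatedPeak",
    "FragmentError",
    "qm_fragments",
    "loss_fragments",
    "generate_fragments",
    "annotate_spectrum",
    "subunit_evidence",
    "annotation_table",
]


class FragmentError(ValueError):
    """Invalid fragmentation request (e.g. gallate loss without a gallate)."""


#: Neutral-loss formulas by pathway label.
NEUTRAL_LOSSES: dict[str, ChemicalFormula] = {
    "phloroglucinol(HRF)": ChemicalFormula("C6H6O3"),
    "rda_catechol": ChemicalFormula("C8H8O3"),
    "rda_pyrogallol": ChemicalFormula("C8H8O4"),
    "water": ChemicalFormula("H2O"),
    "gallate": ChemicalFormula("C7H4O4"),
}

_HRF = "phloroglucinol(HRF)"
_RDA = ("rda_catechol", "rda_pyrogallol")


@dataclass(frozen=True)
class Fragment:
    """A predicted product ion.

    ``formula`` is the neutral form of the ion (m/z follows from the
    deprotonation convention at ``charge``); ``pathway`` is the ordered
    trace of QM splits and neutral losses that produced it.
    """

    formula: ChemicalFormula
    charge: int
    mz: float
    pathway: tuple[str, ...]
    structure: str  # I..VI, "precursor", or "other"
    role: str  # terminal | extension | none

    @property
    def label(self) -> str:
        return " > ".join(self.pathway) if self.pathway else "precursor"


@dataclass(frozen=True)
class AnnotatedPeak:
    """An observed MS/MS peak and its best matching predicted fragment."""

    mz: float
    intensity: float
    fragment: Optional[Fragment]
    ppm: Optional[float]


def _sub_polymer_formula(units: Sequence[tuple[MonomerUnit, int]]) -> ChemicalFormula:
    total = ChemicalFormula()
    size = 0
    for m, n in units:
        total = total + m.formula * n
        size += n
    return total - H2 * (size - 1)


def _classify(pathway: tuple[str, ...]) -> str:
    losses = [p for p in pathway if not p.startswith("QM")]
    if any(p.startswith("QM") for p in pathway):
        return "III" if not losses else "other"
    if not losses:
        return "precursor"
    has_water = "water" in losses
    if _HRF in losses:
        return "II" if has_water else "I"
    if any(l in _RDA for l in losses):
        return "V" if has_water else "IV"
    if set(losses) <= {"gallate", "water"}:
        return "VI"
    return "other"


def _make_fragment(
    formula: ChemicalFormula,
    pathway: tuple[str, ...],
    *,
    charge: int = 1,
    role: str = "none",
    structure: Optional[str] = None,
) -> Fragment:
    return Fragment(
        formula=formula,
        charge=charge,
        mz=mz_for_ion(monoisotopic_mass(formula), IonSpecies(charge=charge)),
        pathway=pathway,
        structure=_classify(pathway) if structure is None else structure,
        role=role,
    )


def _proper_sub_multisets(
    comp: PolymerComposition,
) -> Iterable[tuple[tuple[MonomerUnit, int], ...]]:
    units = comp.units
    ranges = [range(n + 1) for _, n in units]
    for counts in itertools.product(*ranges):
        k = sum(counts)
        if k == 0 or k == comp.dp:
            continue
        yield tuple((units[i][0], c) for i, c in enumerate(counts) if c)


def qm_fragments(comp: PolymerComposition) -> list[Fragment]:
    """Interflavan-cleavage (quinone methide) product ions.

    For every non-empty proper sub-multiset S of the composition the
    terminal-side ion is the deprotonated sub-polymer [poly(S) − H]⁻ and
    the extension-side ion is 2 Da lighter, [poly(S) − 2H − H]⁻.
    Single-unit ions carry terminal/extension role evidence.
    """
    if comp.dp < 2:
        raise FragmentError("quinone methide fission needs at least one interflavan bond")
    frags: list[Fragment] = []
    for sub in _proper_sub_multisets(comp):
        formula = _sub_polymer_formula(sub)
        size = sum(n for _, n in sub)
        desc = "+".join(f"{n}x{m.code}" if n > 1 else m.code for m, n in sub)
        single = sub[0][0].code if size == 1 else None
        frags.append(
            _make_fragment(
                formula,
                (f"QM:terminal({desc})",),
                role="terminal" if single else "none",
            )
        )
        frags.append(
            _make_fragment(
                formula - H2,
                (f"QM:extension({desc})",),
                role="extension" if single else "none",
            )
        )
    return frags


def _loss_applicable(label: str, formula: ChemicalFormula, comp: PolymerComposition, used: dict[str, int]) -> bool:
    if label == "water":
        return True
    if label == "gallate":
        return used.get("gallate", 0) < comp.gallate_count
    ring_cleavages = used.get(_HRF, 0) + used.get("rda_catechol", 0) + used.get("rda_pyrogallol", 0)
    if label == _HRF:
        # each HRF/RDA destroys one C-ring; a unit supports at most one
        return ring_cleavages < comp.dp
    if label in _RDA:
        if used.get("rda_catechol", 0) + used.get("rda_pyrogallol", 0) >= 1:
            return False
        if ring_cleavages >= comp.dp:
            return False
        if label == "rda_catechol":
            return any(m.b_ring_hydroxyls == 2 for m, _ in comp.units)
        return any(m.b_ring_hydroxyls == 3 for m, _ in comp.units)
    return False


def apply_loss(fragment: Fragment, label: str, comp: PolymerComposition) -> Fragment:
    """Apply one named neutral loss to a fragment (validity-checked)."""
    if label not in NEUTRAL_LOSSES:
        raise FragmentError(f"unknown neutral loss {label!r}")
    if label == "gallate" and comp.gallate_count == 0:
        raise FragmentError(f"gallate loss requested on gallate-free composition {comp.name}")
    try:
        formula = fragment.formula - NEUTRAL_LOSSES[label]
    except FormulaError as exc:
        raise FragmentError(str(exc)) from exc
    return _make_fragment(formula, fragment.pathway + (label,), charge=fragment.charge, role=fragment.role)


def loss_fragments(
    precursor: Fragment,
    comp: PolymerComposition,
    max_losses: int = 2,
) -> list[Fragment]:
    """All fragments reachable from ``precursor`` by ≤ ``max_losses`` losses.

    Water may repeat; gallate loss is capped by the composition's gallate
    count; HRF by the unit count (one intact A-ring each); RDA occurs at
    most once and its catechol/pyrogallol variant requires a unit with
    the corresponding B-ring.
    """
    if max_losses < 0:
        raise FragmentError("max_losses must be non-negative")
    out: list[Fragment] = []

    def extend(frag: Fragment, used: dict[str, int], depth: int, last: str) -> None:
        if depth == max_losses:
            return
        for label in NEUTRAL_LOSSES:
            if label < last:  # canonical loss order avoids duplicate combos
                continue
            if not _loss_applicable(label, frag.formula, comp, used):
                continue
            try:
                child = apply_loss(frag, label, comp)
            except FragmentError:
                continue
            out.append(child)
            extend(child, {**used, label: used.get(label, 0) + 1}, depth + 1, label)

    extend(precursor, {}, 0, "")
    return out


def _named_structures(precursor: Fragment, comp: PolymerComposition) -> list[Fragment]:
    # Canonical diagnostic chain; for galloylated species I/II/IV/V shed all
    # gallate esters (the experimentally observed forms), VI sheds one.
    g = comp.gallate_count
    frags: list[Fragment] = []
    gall = ("gallate",) * g

    def chain(first: tuple[str, ...]) -> None:
        frag = precursor
        try:
            for label in first:
                frag = apply_loss(frag, label, comp)
        except FragmentError:
            return
        frags.append(frag)
        try:
            frags.append(apply_loss(frag, "water", comp))
        except FragmentError:
            pass

    chain((_HRF,) + gall)  # I, II
    for rda in _RDA:
        if _loss_applicable(rda, precursor.formula, comp, {}):
            chain((rda,) + gall)  # IV, V
    if g:
        chain(("gallate",))  # VI, VI − H2O
    return frags


def generate_fragments(
    comp: PolymerComposition,
    ion: IonSpecies = DEPROTONATED_1,
    max_losses: int = 2,
) -> list[Fragment]:
    """Full predicted fragment set for a composition.

    Union of: the precursor ion; all QM product ions; neutral-loss chains
    (≤ ``max_losses``) applied to the precursor and to every QM terminal
    fragment; and the named diagnostic structures I/II/IV/V/VI (always
    emitted, even when their loss chain exceeds ``max_losses``).
    Deduplicated on (formula, charge) keeping the shortest pathway;
    ordered by descending m/z.  Product-ion charge is 1 even for doubly
    charged precursors.
    """
    neutral = comp.formula
    precursor = Fragment(
        formula=neutral,
        charge=ion.charge,
        mz=mz_for_ion(monoisotopic_mass(neutral), ion),
        pathway=(),
        structure="precursor",
        role="none",
    )
    # losses always branch from the singly charged deprotonated form
    base = precursor if ion.charge == 1 else _make_fragment(neutral, ())
    pool: list[Fragment] = [precursor]
    pool.extend(loss_fragments(base, comp, max_losses))
    pool.extend(_named_structures(base, comp))
    if comp.dp >= 2:
        qm = qm_fragments(comp)
        pool.extend(qm)
        for frag in qm:
            if frag.role == "extension" or "extension" in frag.pathway[0]:
                continue
            sub_comp = _sub_composition(frag, comp)
            if sub_comp is not None:
                pool.extend(loss_fragments(frag, sub_comp, max_losses))

    best: dict[tuple[ChemicalFormula, int], Fragment] = {}
    for frag in pool:
        key = (frag.formula, frag.charge)
        if key not in best or len(frag.pathway) < len(best[key].pathway):
            best[key] = frag
    return sorted(best.values(), key=lambda f: -f.mz)


def _sub_composition(frag: Fragment, comp: PolymerComposition) -> Optional[PolymerComposition]:
    # Recover the sub-multiset a QM terminal fragment corresponds to, so
    # loss validity (gallates, B-rings) is judged against the sub-polymer.
    desc = frag.pathway[0]
    inner = desc[desc.index("(") + 1 : -1]
    counts: dict[MonomerUnit, int] = {}
    from .database import MONOMERS_BY_CODE

    for token in inner.split("+"):
        if "x" in token and token.split("x")[0].isdigit():
            n, code = token.split("x", 1)
            n = int(n)
        else:
            n, code = 1, token
        unit = MONOMERS_BY_CODE.get(code)
        if unit is None:
            return None
        counts[unit] = counts.get(unit, 0) + n
    return PolymerComposition.from_counts(counts)


def annotate_spectrum(
    peaks: Sequence[tuple[float, float]],
    comp: PolymerComposition,
    tolerance_ppm: float = 20.0,
    ion: IonSpecies = DEPROTONATED_1,
    max_losses: int = 2,
) -> tuple[list[AnnotatedPeak], dict[str, dict[str, bool]]]:
    """Match observed (m/z, intensity) peaks to predicted fragments.

    Each peak takes the in-tolerance fragment with the lowest |ppm|
    (tolerance is relative to the theoretical m/z; 20 ppm default —
    printed flavonoid fragment values routinely deviate that much).
    Returns the annotated peaks plus per-subunit terminal/extension QM
    evidence (see :func:`subunit_evidence`).
    """
    if not peaks:
        raise FragmentError("spectrum has no peaks")
    fragments = generate_fragments(comp, ion=ion, max_losses=max_losses)
    annotated: list[AnnotatedPeak] = []
    for mz, intensity in peaks:
        best: Optional[tuple[float, Fragment]] = None
        for frag in fragments:
            err = ppm_error(frag.mz, mz)
            if err <= tolerance_ppm and (best is None or err < best[0]):
                best = (err, frag)
        if best is None:
            annotated.append(AnnotatedPeak(mz, intensity, None, None))
        else:
            annotated.append(AnnotatedPeak(mz, intensity, best[1], best[0]))
    return annotated, subunit_evidence(annotated, comp)


def subunit_evidence(
    annotated: Iterable[AnnotatedPeak],
    comp: PolymerComposition,
) -> dict[str, dict[str, bool]]:
    """Which subunit types show terminal/extension QM ions in a spectrum.

    The absence of an expected single-unit ion is itself diagnostic: a
    spectrum of a (epi)catechin–(epi)catechin-gallate dimer shows no
    gallocatechin ion at 305.0667, ruling out a gallocatechin unit.
    """
    evidence = {
        m.code: {"terminal": False, "extension": False} for m, _ in comp.units
    }
    for peak in annotated:
        frag = peak.fragment
        if frag is None or frag.role not in ("terminal", "extension"):
            continue
        desc = frag.pathway[0]
        code = desc[desc.index("(") + 1 : -1]
        if code in evidence and len(frag.pathway) == 1:
            evidence[code][frag.role] = True
    return evidence


def annotation_table(annotated: Iterable[AnnotatedPeak]) -> pd.DataFrame:
    """Annotation CSV layout: ``observed_mz, intensity, fragment_formula,
    theoretical_mz, ppm_error, pathway, structure_label``."""
    rows = []
    for peak in annotated:
        frag = peak.fragment
        rows.append(
            {
                "observed_mz": peak.mz,
                "intensity": peak.intensity,
                "fragment_formula": frag.formula.hill() if frag else "",
                "theoretical_mz": round(frag.mz, 4) if frag else "",
                "ppm_error": round(peak.ppm, 1) if frag else "",
                "pathway": frag.label if frag else "",
                "structure_label": frag.structure if frag else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "observed_mz",
            "intensity",
            "fragment_formula",
            "theoretical_mz",
            "ppm_error",
            "pathway",
            "structure_label",
        ],
    )
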