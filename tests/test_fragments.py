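"""Diagnostic fragment generation and MS/MS annotation."""

import pytest

from pacmass import (
    annotate_spectrum,
    annotation_table,
    generate_fragments,
    loss_fragments,
    monoisotopic_mass,
    parse_composition_name,
    qm_fragments,
)
from pacmass.fragments import (
    NEUTRAL_LOSSES,
    Fragment,
    FragmentError,
    apply_loss,
    subunit_evidence,
)
from pacmass.ions import DEPROTONATED_1, IonSpecies, mz_for_ion

# Observed peak list of a (epi)catechin-(epi)catechin-gallate dimer tandem
# spectrum: precursor, gallate/water losses, HRF, RDA, and both QM ions.
DIMER_GALLATE_PEAKS = [
    (729.1488, 120.0),
    (577.1350, 900.0),
    (559.1221, 300.0),
    (451.1044, 200.0),
    (433.0946, 150.0),
    (425.0854, 100.0),
    (407.0770, 1000.0),
    (289.0717, 400.0),
    (287.0559, 350.0),
]




def contains_mz(fragments_or_mzs, value, tol=1e-4):
    """4-dp agreement: |theory - printed| below one rounding ulp."""
    mzs = [getattr(f, "mz", f) for f in fragments_or_mzs]
    return any(abs(m - value) < tol for m in mzs)

@pytest.fixture(scope="module")
def dimer_gallate():
    return parse_composition_name("Cat-Cat:Gal")


@pytest.fixture(scope="module")
def cat_trimer():
    return parse_composition_name("Cat-Cat-Cat")


def test_neutral_loss_masses():
    expected = {
        "phloroglucinol(HRF)": 126.0317,
        "rda_catechol": 152.0473,
        "rda_pyrogallol": 168.0423,
        "water": 18.0106,
        "gallate": 152.0110,
    }
    for label, mass in expected.items():
        assert monoisotopic_mass(NEUTRAL_LOSSES[label]) == pytest.approx(mass, abs=5e-5)


def test_qm_single_unit_ions(dimer_gallate):
    frags = qm_fragments(dimer_gallate)
    for role, mz in [("terminal", 289.0718), ("extension", 287.0561), ("terminal", 441.0827)]:
        assert contains_mz([f for f in frags if f.role == role], mz)


def test_qm_gallocatechin_terminal_ion():
    comp = parse_composition_name("Cat-GalCat")
    assert contains_mz(qm_fragments(comp), 305.0667)


def test_qm_requires_a_bond():
    with pytest.raises(FragmentError):
        qm_fragments(parse_composition_name("Cat"))


def test_qm_complementarity(default_db):
    """The terminal ion of a sub-multiset S and the extension ion of its
    complement sum, element-wise, to the precursor formula (the split
    transfers 2 H from the extension side): poly(S) + (poly(S̄) − H2) =
    precursor.  Checked for every dimer and trimer."""
    for comp in default_db:
        if comp.dp > 3:
            continue
        frags = qm_fragments(comp)
        terminals = [f for f in frags if "terminal" in f.pathway[0]]
        extensions = [f for f in frags if "extension" in f.pathway[0]]
        for term in terminals:
            assert any(
                term.formula + ext.formula == comp.formula for ext in extensions
            ), f"no complementary QM pair reconstitutes {comp.name}"


def test_loss_fragments_gallate_chain(dimer_gallate):
    precursor = Fragment(
        formula=dimer_gallate.formula, charge=1,
        mz=mz_for_ion(dimer_gallate.neutral_mass, DEPROTONATED_1),
        pathway=(), structure="precursor", role="none",
    )
    frags = loss_fragments(precursor, dimer_gallate, 2)
    assert contains_mz(frags, 577.1352)  # - gallate (structure VI)
    assert contains_mz(frags, 451.1035)  # - phloroglucinol - gallate (structure I)
    assert contains_mz(frags, 559.1246)  # - gallate - water


def test_gallate_loss_invalid_without_gallate(cat_trimer):
    precursor = Fragment(
        formula=cat_trimer.formula, charge=1,
        mz=mz_for_ion(cat_trimer.neutral_mass, DEPROTONATED_1),
        pathway=(), structure="precursor", role="none",
    )
    with pytest.raises(FragmentError):
        apply_loss(precursor, "gallate", cat_trimer)


def test_trimer_hrf_loss(cat_trimer):
    frags = generate_fragments(cat_trimer)
    assert contains_mz(frags, 865.1985)  # precursor
    assert contains_mz(frags, 739.1668)  # - phloroglucinol


def test_generate_fragments_dimer_gallate(dimer_gallate):
    frags = generate_fragments(dimer_gallate)
    for want in (729.1461, 577.1352, 559.1246, 451.1035, 289.0718, 287.0561):
        assert contains_mz(frags, want)
    # the gallocatechin diagnostic must be absent (within 20 ppm)
    assert not any(abs(f.mz - 305.0667) / 305.0667 * 1e6 <= 20 for f in frags)


def test_fragment_conservation(default_db):
    """Every fragment has non-negative element counts, positive m/z, and
    m/z strictly below the precursor at equal charge."""
    for name in ("Cat-Cat", "Cat-Cat:Gal", "GalCat-GalCat", "Cat-Cat-GalCat"):
        comp = parse_composition_name(name)
        frags = generate_fragments(comp)
        precursor_mz = mz_for_ion(comp.neutral_mass, DEPROTONATED_1)
        for f in frags:
            assert all(n >= 0 for n in f.formula.values())
            assert 0 < f.mz <= precursor_mz + 1e-9
            if f.pathway:
                assert f.mz < precursor_mz


def test_fragment_dedup_and_order(dimer_gallate):
    frags = generate_fragments(dimer_gallate)
    keys = [(f.formula, f.charge) for f in frags]
    assert len(keys) == len(set(keys))
    assert [f.mz for f in frags] == sorted((f.mz for f in frags), reverse=True)


def test_annotate_dimer_gallate_spectrum(dimer_gallate):
    annotated, evidence = annotate_spectrum(DIMER_GALLATE_PEAKS, dimer_gallate)
    assert all(p.fragment is not None for p in annotated)
    assert all(p.ppm <= 20 for p in annotated)
    labels = {round(p.mz, 4): p.fragment.structure for p in annotated}
    assert labels[577.1350] == "VI"
    assert labels[451.1044] == "I"
    assert labels[433.0946] == "II"
    assert labels[407.0770] == "V"
    assert labels[289.0717] == "III"
    assert evidence["Cat"] == {"terminal": True, "extension": True}


def test_annotate_noise_peak_unmatched(dimer_gallate):
    annotated, _ = annotate_spectrum([(500.0, 10.0)], dimer_gallate)
    assert annotated[0].fragment is None


def test_gallocatechin_absence_diagnostic(dimer_gallate):
    """A spectrum lacking the 305.0667 ion gives no gallocatechin
    extension evidence; for a dimer that actually contains gallocatechin
    the ion would be expected, so its absence rules the unit out."""
    annotated, _ = annotate_spectrum(DIMER_GALLATE_PEAKS, dimer_gallate)
    galcat_dimer = parse_composition_name("Cat-GalCat")
    annotated2, evidence2 = annotate_spectrum(DIMER_GALLATE_PEAKS, galcat_dimer)
    assert evidence2["GalCat"]["terminal"] is False
    assert evidence2["GalCat"]["extension"] is False


def test_annotation_table_columns(dimer_gallate):
    annotated, _ = annotate_spectrum(DIMER_GALLATE_PEAKS[:3], dimer_gallate)
    table = annotation_table(annotated)
    assert list(table.columns) == [
        "observed_mz", "intensity", "fragment_formula", "theoretical_mz",
        "ppm_error", "pathway", "structure_label",
    ]
    assert len(table) == 3
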