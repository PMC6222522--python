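"""Combinatorial database enumeration, naming, and formula indexing."""

import itertools

import pytest

from pacmass import (
    DEFAULT_MONOMERS,
    build_default_database,
    enumerate_compositions,
    monoisotopic_mass,
    parse_composition_name,
    parse_formula,
    sequence_isomer_count,
)
from pacmass.database import (
    DatabaseConfigError,
    MONOMERS_BY_CODE,
    PolymerComposition,
    multiset_count,
)
from pacmass.reference import reference_table


def brute_force_multisets(n_types: int, dp_min: int, dp_max: int) -> set:
    """Oracle: ordered tuples over the subunit alphabet, collapsed to multisets."""
    out = set()
    for dp in range(dp_min, dp_max + 1):
        for seq in itertools.product(range(n_types), repeat=dp):
            out.add(tuple(sorted(seq)))
    return out


def test_default_database_count(default_db):
    assert len(default_db) == 996


@pytest.mark.parametrize("dp_max", [2, 3, 4, 5, 6])
def test_enumeration_matches_brute_force(dp_max):
    db = enumerate_compositions(2, dp_max)
    oracle = brute_force_multisets(4, 2, dp_max)
    assert len(db) == len(oracle) == multiset_count(4, 2, dp_max)
    got = {
        tuple(
            sorted(
                i
                for i, m in enumerate(DEFAULT_MONOMERS)
                for _ in range(comp.count(m.code))
            )
        )
        for comp in db
    }
    assert got == oracle


def test_single_subunit_range():
    db = enumerate_compositions(2, 10, [DEFAULT_MONOMERS[0]])
    assert len(db) == 9  # one entry per DP


def test_invalid_configuration():
    with pytest.raises(DatabaseConfigError):
        enumerate_compositions(3, 2)
    with pytest.raises(DatabaseConfigError):
        enumerate_compositions(2, 4, [])


@pytest.mark.parametrize(
    "name,formula",
    [
        ("Cat-Cat", "C30H26O12"),
        ("Cat-Cat:Gal", "C37H30O16"),
        ("Cat", "C15H14O6"),  # DP 1: zero bonds, monomer formula unchanged
        ("Cat-GalCat-GalCat", "C45H38O20"),
    ],
)
def test_composition_formula(name, formula):
    assert parse_composition_name(name).formula == parse_formula(formula)


def test_composition_element_count_rule():
    """H = 14·dp + 4·g − 2(dp−1); O = 6·n_cat + 7·n_galcat + 10·n_catgal + 11·n_galcatgal."""
    for comp in enumerate_compositions(2, 5):
        f = comp.formula
        g = comp.count("Cat:Gal") + comp.count("GalCat:Gal")
        assert f["H"] == 14 * comp.dp + 4 * g - 2 * (comp.dp - 1)
        assert f["O"] == (
            6 * comp.count("Cat")
            + 7 * comp.count("GalCat")
            + 10 * comp.count("Cat:Gal")
            + 11 * comp.count("GalCat:Gal")
        )


def test_canonical_names():
    comp = PolymerComposition.from_counts(
        {MONOMERS_BY_CODE["GalCat"]: 1, MONOMERS_BY_CODE["Cat"]: 2}
    )
    assert comp.name == "Cat-Cat-GalCat"
    assert parse_composition_name("Cat-Cat-Cat-GalCat:Gal").name == "Cat-Cat-Cat-GalCat:Gal"
    assert parse_composition_name("GalCat").name == "GalCat"


def test_mass_telescoping():
    """neutral_mass(Cat_n) = n × mass(C15H12O6) + mass(H2)."""
    base = monoisotopic_mass("C15H12O6")
    h2 = monoisotopic_mass("H2")
    for n in range(1, 11):
        comp = parse_composition_name("-".join(["Cat"] * n))
        assert comp.neutral_mass == pytest.approx(n * base + h2, abs=1e-9)


@pytest.mark.parametrize(
    "types,dp,expected", [(2, 4, 16), (2, 3, 8), (1, 7, 1), (4, 2, 16)]
)
def test_sequence_isomer_count(types, dp, expected):
    assert sequence_isomer_count(types, dp) == expected


def test_formula_ambiguity_structure(default_db):
    """Formula collisions: 501 distinct formulas among the 996 entries
    (brute-force oracle), and the C67H54O29 tie resolves to the canonical
    gallate-ester-maximizing representative."""
    brute = {comp.formula.hill() for comp in default_db}
    assert len(brute) == len(default_db.formulas) == 501
    cands = default_db.candidates_for_formula("C67H54O29")
    assert len(cands) == 2
    assert cands[0].name == "Cat-Cat-Cat-GalCat:Gal"
    assert default_db.candidates_for_formula("C6H12O6") == []


def test_reference_formulas_all_in_database(default_db):
    """Every reference-table formula is in the default database and its
    composition is among the formula's candidates."""
    for row in reference_table():
        cands = default_db.candidates_for_formula(row.formula)
        assert cands, row.formula
        assert row.polymer in {c.name for c in cands}


def test_export_deterministic(default_db, tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    default_db.export_csv(a)
    default_db.export_csv(b)
    assert a.read_bytes() == b.read_bytes()
    lines = a.read_text().splitlines()
    assert lines[0] == "name,dp,n_cat,n_galcat,n_catgal,n_galcatgal,formula,neutral_mass,knm,kmd"
    assert len(lines) == 997  # header + 996 rows


def test_query_mass_tolerance_boundary(default_db):
    theo = monoisotopic_mass("C30H26O12")
    inside = theo * (1 + 20e-6)
    outside = theo * (1 + 20.000001e-6)
    assert any(f == "C30H26O12" for f, _ in default_db.query_mass(inside, 20.0))
    assert not any(f == "C30H26O12" for f, _ in default_db.query_mass(outside, 20.0))
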