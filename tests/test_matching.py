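"""Feature filtering, database matching, isomer grouping, and report I/O."""

import numpy as np
import pytest

from pacmass import (
    Adduct,
    Feature,
    IonSpecies,
    MatchConfig,
    filter_features,
    group_matches,
    match_features,
    monoisotopic_mass,
    mz_for_ion,
    neutral_mass_from_ion,
    read_features_csv,
    report_table,
    write_features_csv,
)
from pacmass.matching import FeatureTableError


def feat(mz, charge=1, rt=5.0, abundance=1e4, adduct=None, sample="S", rep="r1"):
    return Feature(sample_id=sample, replicate=rep, rt=rt, mz=mz, charge=charge,
                   abundance=abundance, adduct=adduct)


def test_filter_abundance_boundary_and_charge():
    fs = [feat(577.1, abundance=749), feat(577.1, abundance=750), feat(577.1, charge=2)]
    kept = filter_features(fs)
    assert [f.abundance for f in kept] == [750, 1e4]
    assert filter_features([]) == []


def test_filter_rejects_disallowed_charge():
    f3 = Feature("S", "r1", 5.0, 400.0, 1, 1e4)
    fs = [f3, Feature("S", "r1", 5.0, 400.0, 2, 1e4)]
    config = MatchConfig(allowed_charges=frozenset({1}))
    assert [f.charge for f in filter_features(fs, config)] == [1]


def test_match_printed_dimer_and_trimer(default_db):
    matches, rejects = match_features(
        [feat(577.1351), feat(865.1985)], default_db, MatchConfig()
    )
    assert not rejects
    assert matches[0].formula == "C30H26O12"
    assert matches[0].composition.name == "Cat-Cat"
    assert matches[1].formula == "C45H38O18"


def test_out_of_tolerance_is_rejected(default_db):
    mz = 577.1351 * (1 + 25e-6)
    matches, rejects = match_features([feat(mz)], default_db, MatchConfig())
    assert not matches and len(rejects) == 1


def test_formate_adduct_interpretation(default_db):
    neutral = monoisotopic_mass("C30H26O12")
    mz = mz_for_ion(neutral, IonSpecies(Adduct.FORMATE, 1))
    matches, _ = match_features([feat(mz, adduct=Adduct.FORMATE)], default_db)
    assert matches[0].formula == "C30H26O12"
    assert matches[0].ion.adduct is Adduct.FORMATE
    # unknown adduct: deprotonated interpretation of the same m/z misses,
    # the formate interpretation wins
    matches, _ = match_features([feat(mz)], default_db)
    assert matches[0].formula == "C30H26O12"


def test_charge_consistent_neutral_mass(default_db):
    neutral = monoisotopic_mass("C60H50O24")
    f1 = feat(mz_for_ion(neutral, IonSpecies(charge=1)), charge=1)
    f2 = feat(mz_for_ion(neutral, IonSpecies(charge=2)), charge=2)
    m1 = neutral_mass_from_ion(f1.mz, IonSpecies(charge=1))
    m2 = neutral_mass_from_ion(f2.mz, IonSpecies(charge=2))
    assert abs(m1 - m2) < 1e-6
    matches, _ = match_features([f1, f2], default_db)
    assert {m.formula for m in matches} == {"C60H50O24"}


def brute_force_match(feature, db, config):
    """Oracle: scan every composition x adduct x charge with no index."""
    best = None
    ions = []
    if feature.adduct is not None:
        ions = [IonSpecies(feature.adduct, feature.charge)]
    else:
        ions = [IonSpecies(Adduct.DEPROTONATED, feature.charge)]
        if feature.charge == 1:
            ions.append(IonSpecies(Adduct.FORMATE, 1))
    for ion in ions:
        exp = neutral_mass_from_ion(feature.mz, ion)
        for comp in db:
            theo = comp.neutral_mass
            ppm = abs(theo - exp) / theo * 1e6
            if ppm <= config.ppm_tolerance + 1e-9:
                key = (ppm, 0 if ion.adduct is Adduct.DEPROTONATED else 1, comp.dp)
                if best is None or key < best[0]:
                    best = (key, comp.formula.hill())
    return None if best is None else best[1]


def test_matcher_agrees_with_brute_force(default_db):
    rng = np.random.default_rng(7)
    comps = list(default_db)
    features = []
    for i in rng.choice(len(comps), size=40, replace=False):
        comp = comps[int(i)]
        charge = 2 if comp.dp >= 4 and i % 2 else 1
        mz = mz_for_ion(comp.neutral_mass, IonSpecies(charge=charge))
        mz *= 1 + rng.normal(0, 8e-6)  # 8 ppm: some in, some near the edge
        features.append(feat(mz, charge=charge, rt=float(rng.uniform(4, 16))))
    for _ in range(10):  # random off-database m/z
        features.append(feat(float(rng.uniform(100, 3000))))
    config = MatchConfig()
    matches, rejects = match_features(features, default_db, config)
    got = {id(f): None for f in features}
    for m in matches:
        got[id(m.feature)] = m.formula
    for f in features:
        assert got[id(f)] == brute_force_match(f, default_db, config)


def test_isomer_clustering_tolerance(default_db):
    mz = mz_for_ion(monoisotopic_mass("C30H26O12"), IonSpecies(charge=1))
    fs = [feat(mz, rt=5.000), feat(mz, rt=5.05)]
    matches, _ = match_features(fs, default_db)
    wide = group_matches(matches, MatchConfig(rt_group_tolerance=0.10))
    narrow = group_matches(matches, MatchConfig(rt_group_tolerance=0.01))
    assert wide[0].isomer_count == 1
    assert narrow[0].isomer_count == 2
    assert narrow[0].rt_list == sorted(narrow[0].rt_list)


def test_single_match_single_group(default_db):
    matches, _ = match_features([feat(577.1351)], default_db)
    groups = group_matches(matches)
    assert len(groups) == 1 and groups[0].isomer_count == 1
    assert groups[0].name == "Cat-Cat"


def test_report_table_layout(default_db):
    mz2 = mz_for_ion(monoisotopic_mass("C60H50O24"), IonSpecies(charge=2))
    matches, _ = match_features(
        [feat(577.1351), feat(mz2, charge=2, rt=9.5)], default_db
    )
    table = report_table(group_matches(matches))
    assert list(table.columns) == [
        "rt_list", "mean_rt", "formula", "polymer",
        "mean_experimental_mass", "mean_ppm_error", "charge_note",
    ]
    assert table.iloc[0]["formula"] == "C30H26O12"  # sorted by formula mass
    assert table.iloc[1]["charge_note"] == "z=2"
    empty = report_table([])
    assert len(empty) == 0 and list(empty.columns) == list(table.columns)


def test_feature_csv_round_trip(tmp_path, default_db):
    path = tmp_path / "features.csv"
    fs = [feat(577.1351, adduct=Adduct.DEPROTONATED), feat(623.1406, adduct=Adduct.FORMATE),
          feat(865.1985)]
    write_features_csv(fs, path)
    back = read_features_csv(path)
    assert [f.mz for f in back] == [f.mz for f in fs]
    assert [f.adduct for f in back] == [Adduct.DEPROTONATED, Adduct.FORMATE, None]


def test_feature_csv_errors(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("sample_id,replicate,rt,mz\nS,r1,5.0,577.1\n")
    with pytest.raises(FeatureTableError, match="missing column"):
        read_features_csv(bad)
    bad2 = tmp_path / "bad2.csv"
    bad2.write_text(
        "sample_id,replicate,rt,mz,charge,adduct,abundance\nS,r1,5.0,577.1,1,protonated,100\n"
    )
    with pytest.raises(FeatureTableError, match="row 2"):
        read_features_csv(bad2)
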