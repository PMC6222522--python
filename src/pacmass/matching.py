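"""Feature filtering, formula matching, and isomer grouping.

Re-implements the targeted extraction stage of the workflow: deisotoped
negative-mode LC-MS features (m/z, charge, retention time, abundance) are
abundance-filtered, converted to candidate neutral masses under every
allowed adduct interpretation (deprotonated z = 1/2, formate z = 1), and
queried against the theoretical compound database at a ±ppm tolerance
(default ±20 ppm, inclusive).  Matches sharing a formula are clustered on
retention time into isomer peaks and summarized into a report table of
(rt list, formula, composition, mean experimental mass, mean ppm error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .database import CompoundDatabase, PolymerComposition
from .ions import Adduct, IonSpecies, neutral_mass_from_ion, ppm_error

__all__ = [
    "Feature",
    "MatchConfig",
    "MatchResult",
    "CompoundGroup",
    "FeatureTableError",
    "filter_features",
    "match_features",
    "group_matches",
    "report_table",
    "read_features_csv",
    "write_features_csv",
]

FEATURE_COLUMNS = ["sample_id", "replicate", "rt", "mz", "charge", "adduct", "abundance"]


class FeatureTableError(ValueError):
    """Malformed feature table input."""


@dataclass(frozen=True)
class Feature:
    """One deisotoped negative-mode LC-MS feature."""

    sample_id: str
    replicate: str
    rt: float
    mz: float
    charge: int
    abundance: float
    adduct: Optional[Adduct] = None  # None = unknown, try all allowed

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise FeatureTableError(f"feature m/z must be positive, got {self.mz}")
        if self.rt < 0 or self.abundance < 0:
            raise FeatureTableError("feature rt and abundance must be non-negative")


@dataclass(frozen=True)
class MatchConfig:
    """Extraction and matching settings (defaults mirror the workflow)."""

    ppm_tolerance: float = 20.0
    min_abundance: float = 750.0
    allowed_charges: frozenset[int] = frozenset({1, 2})
    allowed_adducts: frozenset[Adduct] = frozenset({Adduct.DEPROTONATED, Adduct.FORMATE})
    rt_group_tolerance: float = 0.10  # minutes, single-linkage isomer clustering

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise FeatureTableError("ppm_tolerance must be positive")
        if self.min_abundance < 0:
            raise FeatureTableError("min_abundance must be non-negative")


@dataclass(frozen=True)
class MatchResult:
    """A feature assigned to a database formula."""

    feature: Feature
    formula: str
    candidates: tuple[PolymerComposition, ...]  # canonical representative first
    ion: IonSpecies
    neutral_mass: float  # experimental, reconstructed from m/z under `ion`
    ppm_signed: float
    ppm_unsigned: float

    @property
    def composition(self) -> PolymerComposition:
        return self.candidates[0]


@dataclass
class CompoundGroup:
    """All matches of one formula, resolved into isomer peaks on rt."""

    formula: str
    name: str  # canonical composition name
    rt_list: list[float]  # one mean rt per isomer peak, ascending
    mean_rt: float
    mean_experimental_mass: float
    mean_ppm_error: float
    sample_abundance: dict[str, float]
    charges: frozenset[int]
    members: list[MatchResult] = field(repr=False, default_factory=list)

    @property
    def isomer_count(self) -> int:
        return len(self.rt_list)


def filter_features(features: Iterable[Feature], config: MatchConfig = MatchConfig()) -> list[Feature]:
    """Abundance/charge pre-filter: keep counts ≥ threshold ("smaller than"
    the threshold is excluded, so the boundary is inclusive) and allowed
    charge states.  Order is preserved."""
    return [
        f
        for f in features
        if f.abundance >= config.min_abundance and f.charge in config.allowed_charges
    ]


def _ion_interpretations(feature: Feature, config: MatchConfig) -> list[IonSpecies]:
    if feature.adduct is not None:
        if feature.adduct not in config.allowed_adducts:
            return []
        if feature.adduct is Adduct.FORMATE and feature.charge != 1:
            return []
        return [IonSpecies(feature.adduct, feature.charge)]
    ions = []
    for adduct in (Adduct.DEPROTONATED, Adduct.FORMATE):
        if adduct not in config.allowed_adducts:
            continue
        if adduct is Adduct.FORMATE and feature.charge != 1:
            continue
        ions.append(IonSpecies(adduct, feature.charge))
    return ions


def match_features(
    features: Iterable[Feature],
    db: CompoundDatabase,
    config: MatchConfig = MatchConfig(),
) -> tuple[list[MatchResult], list[Feature]]:
    """Assign each feature to the database formula minimizing |ppm error|.

    Every allowed adduct interpretation of the feature is tried; among all
    (formula, ion) pairs within the tolerance the lowest |ppm| wins, with
    ties broken toward the deprotonated interpretation and then the lower
    DP.  Returns (matches, rejects); unmatched features are rejects, never
    errors.
    """
    matches: list[MatchResult] = []
    rejects: list[Feature] = []
    for feature in features:
        best = None
        for ion in _ion_interpretations(feature, config):
            exp_mass = neutral_mass_from_ion(feature.mz, ion)
            for formula, ppm in db.query_mass(exp_mass, config.ppm_tolerance):
                cands = db.candidates_for_formula(formula)
                key = (ppm, 0 if ion.adduct is Adduct.DEPROTONATED else 1, cands[0].dp)
                if best is None or key < best[0]:
                    theo = cands[0].neutral_mass
                    best = (
                        key,
                        MatchResult(
                            feature=feature,
                            formula=formula,
                            candidates=tuple(cands),
                            ion=ion,
                            neutral_mass=exp_mass,
                            ppm_signed=ppm_error(theo, exp_mass, signed=True),
                            ppm_unsigned=ppm,
                        ),
                    )
        if best is None:
            rejects.append(feature)
        else:
            matches.append(best[1])
    return matches, rejects


def _single_linkage_1d(values: Sequence[float], tolerance: float) -> list[list[float]]:
    """Cluster sorted scalars, chaining neighbours within ``tolerance``."""
    ordered = sorted(values)
    clusters: list[list[float]] = [[ordered[0]]]
    for v in ordered[1:]:
        if v - clusters[-1][-1] <= tolerance:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters


def group_matches(
    matches: Iterable[MatchResult],
    config: MatchConfig = MatchConfig(),
) -> list[CompoundGroup]:
    """Collapse matches into one group per formula with rt-resolved isomers.

    Matches sharing a formula are single-linkage clustered on rt at
    ``rt_group_tolerance``; each cluster is one chromatographically
    resolved isomer peak and contributes its mean rt to the group's rt
    list.  Group-level masses and ppm errors are means over member
    features; abundances are summed per sample.  Groups are ordered by
    theoretical formula mass, ties by mean rt.
    """
    by_formula: dict[str, list[MatchResult]] = {}
    for m in matches:
        by_formula.setdefault(m.formula, []).append(m)

    groups: list[CompoundGroup] = []
    for formula, members in by_formula.items():
        clusters = _single_linkage_1d([m.feature.rt for m in members], config.rt_group_tolerance)
        rt_list = sorted(sum(c) / len(c) for c in clusters)
        sample_abundance: dict[str, float] = {}
        for m in members:
            sample_abundance[m.feature.sample_id] = (
                sample_abundance.get(m.feature.sample_id, 0.0) + m.feature.abundance
            )
        groups.append(
            CompoundGroup(
                formula=formula,
                name=members[0].candidates[0].name,
                rt_list=rt_list,
                mean_rt=sum(m.feature.rt for m in members) / len(members),
                mean_experimental_mass=sum(m.neutral_mass for m in members) / len(members),
                mean_ppm_error=sum(m.ppm_unsigned for m in members) / len(members),
                sample_abundance=sample_abundance,
                charges=frozenset(m.feature.charge for m in members),
                members=list(members),
            )
        )
    groups.sort(key=lambda g: (g.members[0].candidates[0].neutral_mass, g.mean_rt))
    return groups


def report_table(groups: Iterable[CompoundGroup]) -> pd.DataFrame:
    """Identification report: one row per compound group.

    Columns ``rt_list, mean_rt, formula, polymer, mean_experimental_mass,
    mean_ppm_error, charge_note`` with masses at 4 dp, rt at 2 dp, ppm at
    1 dp; rt values joined with ``"; "``.  A ``z=2`` charge note marks
    groups observed as doubly charged species.
    """
    rows = []
    for g in groups:
        note = "z=2" if 2 in g.charges else ""
        rows.append(
            {
                "rt_list": "; ".join(f"{rt:.2f}" for rt in g.rt_list),
                "mean_rt": round(g.mean_rt, 2),
                "formula": g.formula,
                "polymer": g.name,
                "mean_experimental_mass": round(g.mean_experimental_mass, 4),
                "mean_ppm_error": round(g.mean_ppm_error, 1),
                "charge_note": note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rt_list",
            "mean_rt",
            "formula",
            "polymer",
            "mean_experimental_mass",
            "mean_ppm_error",
            "charge_note",
        ],
    )


_ADDUCT_NAMES = {a.value: a for a in Adduct}


def read_features_csv(path) -> list[Feature]:
    """Read the feature-table dialect (header ``sample_id,replicate,rt,mz,
    charge,adduct,abundance``; empty adduct = unknown).  Errors name the
    offending row."""
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate": str, "adduct": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureTableError(f"feature table missing column(s): {', '.join(missing)}")
    features = []
    for i, row in df.iterrows():
        adduct_raw = row["adduct"]
        if pd.isna(adduct_raw) or str(adduct_raw).strip() == "":
            adduct = None
        else:
            try:
                adduct = _ADDUCT_NAMES[str(adduct_raw).strip()]
            except KeyError:
                raise FeatureTableError(f"row {i + 2}: unknown adduct {adduct_raw!r}")
        try:
            features.append(
                Feature(
                    sample_id=str(row["sample_id"]),
                    replicate=str(row["replicate"]),
                    rt=float(row["rt"]),
                    mz=float(row["mz"]),
                    charge=int(row["charge"]),
                    abundance=float(row["abundance"]),
                    adduct=adduct,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FeatureTableError(f"row {i + 2}: {exc}") from exc
    return features


def write_features_csv(features: Iterable[Feature], path) -> None:
    rows = [
        {
            "sample_id": f.sample_id,
            "replicate": f.replicate,
            "rt": f.rt,
            "mz": f.mz,
            "charge": f.charge,
            "adduct": "" if f.adduct is None else f.adduct.value,
            "abundance": f.abundance,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)
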