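"""Replay the bundled 89-compound reference table through the matcher.

Each (retention time, formula) isomer peak of the reference table becomes
one synthetic feature at the reported experimental mass; the pipeline
filters, matches at ±20 ppm against the theoretical database, groups
isomers on retention time, and reprints the identification report.
"""

from pacmass import build_default_database, filter_features, group_matches, match_features, report_table, replay_as_features
from pacmass.reference import REPLAY_CONFIG

db = build_default_database()
features = replay_as_features()
print(f"replayed features: {len(features)}")

kept = filter_features(features, REPLAY_CONFIG)
matches, rejects = match_features(kept, db, REPLAY_CONFIG)
groups = group_matches(matches, REPLAY_CONFIG)
print(f"matched: {len(matches)}, rejected: {len(rejects)}")
print(f"compound groups (formulas): {len(groups)}; isomer peaks: {sum(g.isomer_count for g in groups)}")

table = report_table(groups)
print("\nlightest five groups (mass error in ppm vs theoretical mass):")
print(table.head(5).to_string(index=False))
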