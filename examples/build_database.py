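"""Build the theoretical proanthocyanidin database and look up a formula.

Enumerates every multiset of the four grape flavan-3-ol subunits for
DP 2-10 (B-type linkages, −2H per bond) and prints the entry count, a few
rows, and the compositions behind one ambiguous formula.
"""

from pacmass import build_default_database

db = build_default_database()
print(f"database entries (DP 2-10, 4 subunits): {len(db)}")
print(f"distinct molecular formulas:            {len(db.formulas)}")

df = db.to_dataframe()
print("\nfirst dimers:")
print(df.head(4)[["name", "formula", "neutral_mass", "knm", "kmd"]].to_string(index=False))

# One formula, several isomeric compositions: MS1 cannot tell them apart,
# so the database keeps all candidates with a canonical representative first.
cands = db.candidates_for_formula("C67H54O29")
print(f"\ncompositions sharing C67H54O29: {[c.name for c in cands]}")
print("(the first entry is the canonical representative used in reports)")
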