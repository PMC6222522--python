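"""Modified Kendrick mass-defect analysis of the trimer series.

With the catechin extension unit C15H12O6 rescaled to nominal mass 288,
every pure-(epi)catechin polymer shares the defect −0.0152; substituting
a gallocatechin (+O) moves the defect by +0.0086 and adding a gallate
ester (+C7H4O4) by +0.0225, so composition reads off the (KNM, KMD) plane.
"""

from pacmass import kendrick_transform, kmd_shift, parse_composition_name

print("composition                KNM     KMD")
for name in [
    "Cat-Cat-Cat",
    "Cat-Cat-GalCat",
    "Cat-GalCat-GalCat",
    "Cat-Cat-Cat:Gal",
    "Cat-Cat:Gal-Cat:Gal",
]:
    comp = parse_composition_name(name)
    point = kendrick_transform(comp.neutral_mass)
    print(f"{name:25s} {point.knm:5d}  {point.kmd:+.4f}")

for delta, label in [("O", "+O (gallocatechin for catechin)"), ("C7H4O4", "+gallate ester")]:
    knm, kmd = kmd_shift(delta)
    print(f"shift {label}: KNM {knm:+d}, KMD {kmd:+.4f}")

knm, kmd = kmd_shift("C15H12O6")
print(f"shift +1 extension unit: KNM {knm:+d}, KMD {kmd:+.4f} (homologues share a defect)")
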