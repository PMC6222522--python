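"""Predict diagnostic fragments and annotate a tandem spectrum.

For the (epi)catechin-(epi)catechin-gallate dimer the observed peak list
(precursor 729.15) annotates fully: gallate/water losses (structures VI),
heterocyclic ring fission (I, II), retro-Diels-Alder (IV, V), and the two
quinone-methide single-unit ions (III).  The absence of any ion near
305.0667 rules out a gallocatechin extension unit.
"""

from pacmass import annotate_spectrum, annotation_table, parse_composition_name

PEAKS = [
    (729.1488, 120.0), (577.1350, 900.0), (559.1221, 300.0),
    (451.1044, 200.0), (433.0946, 150.0), (425.0854, 100.0),
    (407.0770, 1000.0), (289.0717, 400.0), (287.0559, 350.0),
    (500.0000, 10.0),  # a noise peak: should stay unannotated
]

comp = parse_composition_name("Cat-Cat:Gal")
annotated, evidence = annotate_spectrum(PEAKS, comp, tolerance_ppm=20.0)

print(annotation_table(annotated).to_string(index=False))
print("\nsubunit evidence from single-unit quinone-methide ions:")
for code, roles in evidence.items():
    for role, seen in roles.items():
        print(f"  {code:10s} {role:10s} {'observed' if seen else 'absent'}")
print("\n(no peak near m/z 305.0667: gallocatechin is not part of this dimer)")
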