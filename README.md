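# pacmass

Toolkit for characterizing proanthocyanidins (condensed tannins) in
LC-MS data: combinatorial theoretical-mass databases of flavan-3-ol
oligomers, ppm-tolerance molecular-formula matching of negative-mode
features, modified Kendrick mass-defect analysis, and rule-based MS/MS
fragment prediction and annotation.

## The problem

Proanthocyanidins are polymers of flavan-3-ol monomers — (epi)catechin
(`Cat`, C15H14O6), (epi)gallocatechin (`GalCat`, C15H14O7) and their
3-*O*-gallate esters (`Cat:Gal` C22H18O10, `GalCat:Gal` C22H18O11) —
joined by B-type interflavan bonds, each bond removing two hydrogens:

    formula(polymer) = Σ nᵢ·monomerᵢ − (DP − 1)·H₂

They drive astringency in wine and other foods, but the combinatorics are
brutal: the number of sequence isomers grows as *types*^DP, while MS1 can
only see the molecular formula. `pacmass` works at the level MS1 can
resolve: it enumerates all subunit *multisets* for DP 2–10 over the four
grape monomers (996 compounds, 501 distinct formulas), matches deisotoped
negative-mode features ([M−H]⁻, [M−2H]²⁻, [M+HCOO]⁻) against that
database at ±20 ppm, resolves isomers chromatographically, and confirms
compositions from diagnostic MS/MS ions.

## Kendrick analysis

Compositions are visualized with a modified Kendrick transform whose
repeat unit is the catechin extension unit C15H12O6 (288.063388 Da):

    KM  = M × 288 / m(C15H12O6)
    KNM = round(KM)          KMD = KNM − KM

All pure-(epi)catechin polymers share KMD −0.0152 regardless of DP;
adding an oxygen (gallocatechin-for-catechin) shifts (KNM, KMD) by
(+16, +0.0086) and a gallate ester (C7H4O4) by (+152, +0.0225), so a
compound's composition can be read directly off a KMD-vs-KNM plot.

## MS/MS fragmentation rules

Three pathways generate the diagnostic ions: quinone-methide fission of
the interflavan bond (QM; intact terminal-unit ion vs 2-Da-lighter
extension-unit ion, e.g. catechin 289.0718/287.0561, gallocatechin
305.0667), heterocyclic ring fission (HRF; −C6H6O3 phloroglucinol), and
retro-Diels-Alder cleavage (RDA; −C8H8O3 or −C8H8O4), chained with water
and gallate losses. Annotation is compositional — presence *and absence*
of single-unit ions constrain which subunits occupy extension positions.

## Worked example

```
$ python examples/kendrick_analysis.py
composition                KNM     KMD
Cat-Cat-Cat                 866  -0.0152
Cat-Cat-GalCat              882  -0.0066
Cat-GalCat-GalCat           898  +0.0020
Cat-Cat-Cat:Gal            1018  +0.0073
Cat-Cat:Gal-Cat:Gal        1170  +0.0298
shift +O (gallocatechin for catechin): KNM +16, KMD +0.0086
shift +gallate ester: KNM +152, KMD +0.0225
shift +1 extension unit: KNM +288, KMD +0.0000 (homologues share a defect)
```

The trimer series shows the lattice structure of the Kendrick plane: the
catechin trimer sits at (866, −0.0152); each gallocatechin substitution
moves it (+16, +0.0086); each gallate ester (+152, +0.0225); adding a
whole extension unit changes KNM by exactly 288 and leaves KMD untouched.

Other examples (`examples/*.py`) build the 996-entry database, replay the
bundled 89-compound wine reference table through the matcher (21 formula
groups, 89 isomer peaks, mean mass errors reproducing the reported ppm
column), annotate a galloylated-dimer tandem spectrum (all nine peaks at
≤ 20 ppm, noise peak left unassigned), and recover planted compounds from
synthetic data (99.9 % correct at 5 ppm mass error).

A thin CLI mirrors the workflow:

```
pacmass build --out db.csv
pacmass simulate --seed 1 --out features.csv --truth truth.csv
pacmass match --features features.csv --out report.csv
pacmass kendrick --report report.csv --out kmd.csv --figure kmd.svg
pacmass fragment "Cat-Cat:Gal" --out fragments.csv
```

## Layout

- `src/pacmass/formula.py`, `ions.py` — formula arithmetic, monoisotopic
  masses, negative-mode adduct m/z math
- `src/pacmass/database.py` — monomer registry, polymer compositions,
  combinatorial database with mass/formula indexes
- `src/pacmass/kendrick.py`, `plotting.py` — Kendrick transform, shift
  rules, scatter/bubble plot tables and figures
- `src/pacmass/matching.py` — feature filtering, ±ppm matching, isomer
  grouping, report tables
- `src/pacmass/fragments.py`, `spectra.py` — fragment generation,
  spectrum annotation, MGF/peak-list I/O
- `src/pacmass/simulate.py`, `reference.py` — synthetic-data generator
  and the bundled 89-compound reference table
- `src/pacmass/cli.py` — `pacmass` command-line entry point

See `docs/methods.md` for the model, parameter defaults, and limitations.
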