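# Methods

## Chemical model

Proanthocyanidin oligomers are modeled as multisets of four flavan-3-ol
subunits — (epi)catechin (C15H14O6), (epi)gallocatechin (C15H14O7), and
their 3-*O*-gallate esters (C22H18O10, C22H18O11) — joined exclusively by
B-type interflavan bonds. Each bond removes H₂, so a composition with
counts {nᵢ} and DP = Σnᵢ has formula Σnᵢ·monomerᵢ − (DP−1)·H₂. Two
consequences drive the whole design:

* **Compositional, not sequential.** Epimers, sequence permutations and
  bond regiochemistry (4→8 vs 4→6) all share one molecular formula, which
  is all MS1 can measure. The database therefore stores one entry per
  *multiset*; enumerating DP 2–10 over four subunits gives
  Σ C(dp+3, 3) = 996 entries. Sequence-isomer counts (types^DP) are
  provided separately for interpreting chromatographic multiplicity.
* **Formula degeneracy.** A formula is determined by (DP, gallate count
  g, extra-oxygen count x), feasible whenever max(g, x) ≤ DP, so the 996
  compositions collapse to Σ_{dp=2..10}(dp+1)² = 501 distinct formulas.
  Candidates for an ambiguous formula are ordered by a fixed canonical
  rule — maximize the doubly substituted subunit (GalCat:Gal), then
  catechin count, then name — which is total, deterministic, and
  reproduces the conventional representative for e.g. C67H54O29.

Monoisotopic masses use CODATA/IUPAC atomic values (C = 12 exactly,
H = 1.00782503207, O = 15.9949146196); proton 1.007276467, electron
0.000548580. A-type (doubly linked) proanthocyanidins, anthocyanin
adducts and subunits beyond the four grape monomers are out of scope
(the monomer registry is extensible by construction).

## Ion arithmetic

Negative-mode interpretations are deprotonation ([M−zH]^z−, z ∈ {1, 2};
m/z = (M − z·1.007276)/z) and the formate adduct ([M+HCOO]⁻, singly
charged only; shift +44.998203 including the electron). Mass errors are
reported unsigned in ppm relative to the theoretical mass, to 1 decimal;
a signed variant ((theo − exp)/theo) is available for diagnostics.
Whether measured masses carry an electron-mass correction is immaterial
at the 4–16 ppm errors this workflow tolerates.

## Kendrick transform

Kendrick quantities use the catechin extension unit C15H12O6 as repeat:
KM = M·288/m(C15H12O6), KNM = round(KM) (half away from zero — no
database entry falls within 0.2 of a half-integer, so the tie rule is
inert but fixed), KMD = KNM − KM, reported at 4 decimals. The divisor is
the full-precision 288.063388 by default, keeping the base-unit series
*exactly* invariant; a `divisor` argument accepts the printed 4-dp
constant 288.0634, and both reproduce every published 4-dp value (tested).
Kendrick quantities are always computed from the neutral monoisotopic
mass, never from ion m/z — the trimer lane sits at KNM 866, not 865.

## Feature matching

Features (sample, replicate, rt, m/z, charge, abundance, optional
adduct) are filtered at ≥ 750 counts (the "smaller than" threshold is
exclusive, so 750 itself survives) and charge ∈ {1, 2}. Each allowed
adduct interpretation yields a candidate neutral mass; the formula
minimizing |ppm| within the ±20 ppm (inclusive) tolerance wins, ties
broken toward deprotonation and lower DP. A binary-search mass index
accelerates the query; a test pins its equivalence to a brute-force scan
over all entries × adducts. Unmatched features become a rejects list.

Isomer resolution clusters matches sharing a formula by single-linkage
on rt. The default tolerance (0.10 min) reflects raw replicate features;
the bundled reference table stores already-merged peak apexes (closest
pair 0.04 min), so its replay uses 0.01 min. Group statistics are means
over member features (rt, experimental neutral mass, unsigned ppm) and
per-sample abundance sums.

**Known limitation — near-degenerate formulas.** The substitution
(DP, g, x) → (DP−1, g+2, x−1) changes mass by only 36.4 mDa (one
extension unit vs two gallates minus an oxygen). Above ~1450 Da that is
< 25 ppm, inside the matching tolerance: a feature with an unluckily
large (≳ 12 ppm) mass error can land closer to the degenerate neighbor
than to its true formula. At 5 ppm error this affects ≈ 0.1 % of heavy
features (observed ~1 per 1000 in seeded runs, always to the 36-mDa
neighbor); it also explains why the reference compound C75H62O33, whose
reported mass is 15.8 ppm from theory, is formally closer to C74H58O34.
This is an intrinsic ambiguity of formula-level matching, surfaced
rather than patched.

## Fragment prediction and annotation

Fragments are generated compositionally over sub-multisets — the union
over all sequence isomers — because annotation argues from the presence
or absence of ions, not from a known sequence:

* **QM** (interflavan cleavage): for every proper sub-multiset S,
  a terminal-side ion [poly(S)−H]⁻ and an extension-side ion 2 Da
  lighter. Single-unit ions carry the terminal/extension role evidence.
* **Neutral losses**: water (always), gallate (capped by the gallate
  count), HRF phloroglucinol C6H6O3 and RDA C8H8O3/C8H8O4 (each
  destroying one C-ring, so HRF+RDA applications are capped by the unit
  count; RDA at most once, variant gated on the B-ring type present).
  Loss chains are enumerated up to `max_losses` (default 2) from the
  precursor and from each QM terminal fragment.
* **Named structures**: the canonical diagnostic chain — I (HRF), II
  (I − H₂O), IV (RDA), V (IV − H₂O), VI (− gallate), VI − H₂O — is
  always emitted explicitly. For galloylated precursors, I/II/IV/V
  include loss of the gallate ester(s): the observed 451.10/433.09/
  425.09/407.08 series of the galloylated dimer corresponds to those
  gallate-shed forms, which sit at loss depth 3 and would otherwise be
  cut off by the default depth. Structure labels are derived from the
  loss trace (QM → III; gallate-only → VI).

Product ions are singly charged even for doubly charged precursors (as
observed in practice). Deduplication keeps the shortest pathway per
(formula, charge). Annotation assigns each observed peak the
lowest-|ppm| fragment within tolerance; the default 20 ppm is
deliberately loose because printed flavonoid fragment values routinely
deviate 5–20 ppm from exact arithmetic. The per-subunit evidence summary
reports terminal/extension QM ions seen or absent — the absence of the
gallocatechin ion at 305.0667 is itself diagnostic. A handful of
published composite ions (e.g. trimer 695.13, hexamer 863.17) are not
reachable by any single loss combination and are not special-cased.

## Synthetic data

The generator plants compounds (default: the canonical compositions of
the 21 bundled reference formulas) into two contrasted samples with
multipliers 1× and 3× (emulating short vs extended maceration), three
replicates, and:

* mass error: multiplicative, ε ~ N(0, σ), σ = 5 ppm by default;
* retention: rt = 5.1 + 2.2·(DP−2) + 0.9·x + 0.25·g + N(0, 0.05) min —
  a linear HILIC surrogate whose coefficients land near the reference
  table's mean rts and reproduce the qualitative trends (retention grows
  with DP, hydroxylation, and more weakly galloylation); it is a test
  harness, not a retention model;
* abundance: log-normal (μ_log 11.5, σ_log 1.0 — comfortably above the
  750-count floor), drawn once per compound × replicate and scaled by
  the sample multiplier so between-sample ratios are exact;
* charge: DP ≥ 4 features are doubly charged with probability 0.9
  (12 of the 13 heavy reference rows were observed doubly charged);
* noise: 50 features per sample, uniform over m/z 100–3200 but
  rejection-sampled ≥ 30 ppm from every database ion, so any noise match
  is a genuine false positive (none occur by construction).

MS/MS simulation subsamples the predicted fragment set with ppm jitter
plus uniform noise peaks. All randomness flows from one integer seed;
identical (seed, config) gives identical output.

What passing synthetic tests does **not** show: real chromatographic
peak shapes, isotope envelopes, ion suppression, co-elution, or
between-run rt drift are all unmodeled, and the biological comparison of
differently macerated wines is not reproducible without the original raw
data — the synthetic recovery and oracle-equivalence properties stand in
for it.

## Numerical choices

Problem sizes were chosen to keep every check fast at desk scale: the
brute-force enumeration oracle runs to DP 6 (4^6 tuples), QM
complementarity is verified for all dimers and trimers, and the recovery
test plants 21 compounds × 24 replicates × 2 samples (1008 features).
The ppm tolerance comparison is inclusive with a 10⁻⁹-ppm slack
absorbing float round-off at the boundary. CSV exports print masses at
6 dp and KMD at 4 dp and are byte-deterministic for a fixed database.
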