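# Methods

This note documents the modelling choices in `ersar`: what each stage
assumes, the parameters that matter, and what the synthetic benchmark does
and does not establish.

## Structure standardization

SMILES are parsed with RDKit and reduced to a single parent structure:
largest organic fragment (most heavy atoms; ties by molecular weight, then
lexicographically smallest canonical SMILES — salt/solvent stripping),
functional-group cleanup, charge neutralization, and canonical-tautomer
selection with RDKit's MolStandardize default rule set.  The rule-set
identifier is written into every model artifact so that prediction-time
featurization provably uses the same chemistry as training.  Standardization
is idempotent (tested).  Stereochemistry is preserved in the canonical
SMILES but ignored by fingerprint matching: the shipped dictionaries are
constitution-only.  Which tautomer canon a different toolkit would pick is
not modelled; numeric parity with other preprocessors is not claimed.

## Curation

pIC50 = −log₁₀(IC50 in molar); recognized units are nM, µM, M.  Class
labels use strict thresholds: active iff pIC50 > 6 (IC50 < 1 µM), inactive
iff pIC50 < 5 (IC50 > 10 µM); the band between, including the boundary
values exactly, is "intermediate" and excluded, keeping the two classes
separated by an order of magnitude in potency.  Compound identity is the
standardized canonical SMILES, so salt forms and drawing variants merge.
Replicates merge by **median** pIC50 (robust to a single discordant assay);
replicate sets whose individual labels span both the active and inactive
regions are dropped outright, because any average of contradictory
measurements would fabricate a confident label.  All drops are counted and
reported.

## Fingerprints

A dictionary is an ordered list of bits; each bit is a SMARTS pattern
(`smarts_presence`, or `smarts_count_at_least` with a threshold) or a named
whole-molecule count (`feature_count_at_least`: element tallies, ring
census, hydrogen count, fragment count).  Count-mode vectors report the
symmetry-deduplicated embedding count (unique atom sets), so `C-C` on octane
counts 7, and a positive count always coincides with the presence bit —
count ≥ presence element-wise is a tested invariant.  Aromaticity is RDKit's
default perception, applied uniformly to molecules and patterns.

Shipped families and their provenance:

* **maccs (166)** — genuine, built at runtime from RDKit's public MACCS key
  table; the three keys RDKit leaves without SMARTS (isotope, >1 aromatic
  ring, >1 fragment) are expressed as feature-count rules.
* **pubchem (881), substructure (307), klekota_roth (4,860)** — synthetic
  stand-ins generated programmatically with the families' canonical
  cardinalities and rule-kind structure (element-census and ring-census
  count rules plus SMARTS sections for the PubChem-style family; a curated
  head of ~80 genuine functional-group SMARTS — amides, amines, phenols,
  sulfonyls, N-heterocycles — for the substructure family).  The authentic
  bit lists are not redistributable here; per-bit parity with other
  fingerprint software is explicitly not claimed.  Every pattern is
  compile-validated at build time.  User dictionaries in the same TSV format
  (index, rule_kind, pattern, threshold, description) can replace any family.

## Filtering and splitting

Near-constant bits carry no class information and inflate the mtry search
space, so bits with sample standard deviation (ddof = 1) below 0.1 are
removed before splitting.  The filter is fitted on the full data set before
the split — deliberately mirroring the conventional workflow order — and the
filter record flags this as a known information-flow choice.

The Kennard–Stone split is the deterministic maximin rule in Euclidean space
on the filtered fingerprint block (for binary bits this is √Hamming; the
metric is recorded in the split result): seed with the globally farthest
pair, then repeatedly add the candidate whose minimum distance to the
selected set is largest, until ⌈0.8·n⌉ compounds are selected as the
internal set.  All ties break to the lowest row index, making the split a
pure function of the ordered matrix; an exhaustive oracle equivalence test
covers 200 random instances.  Because maximin selection claims the hull
first, the external set lies inside the internal set's occupied region —
which is also why the applicability domain covers essentially all external
compounds (see below).

## Random-forest modelling

Grid: ntree ∈ {100, 200, …, 1000}, mtry ∈ {5, 10, …, 30} (library
defaults).  Each pair is scored by the mean per-fold MCC over seeded
stratified 5-fold cross-validation; ties go to the smaller ntree, then
smaller mtry.  MCC is preferred to accuracy as the tuning objective because
the curated classes need not be balanced.  Grid points with mtry above the
retained feature count are skipped with a warning.  The winner is refit on
the whole internal set; reports cover resubstitution (plus the forest's
out-of-bag accuracy, the bagging-native training estimate — both are
emitted, labelled, since they answer different questions), pooled 5-fold CV
(pooled confusion = sum of fold confusions) and the external test set.
Metrics follow the closed forms in the README, with the conventions: zero
Sn/Sp denominator → 0, zero factor under the MCC root → MCC 0, "active" is
the positive class, class assignment by majority vote (0.5 threshold,
untuned).  Feature interpretation uses the forest's mean decrease of Gini
impurity, ranked with stable ties; the reporting default is the top 20.

## Applicability domain

Mean-centered, unscaled PCA (binary bits share a scale, so unit-variance
scaling would only amplify rare bits) with 2 components by default —
enough for a scores-plot view and deliberately conservative; configurable.
The closed per-component [min, max] intervals of the internal scores define
the box; no tolerance padding.  By construction 100% of internal compounds
are in-domain; on the benchmark the Kennard–Stone external set is ≥ 95%
in-domain (tested), for the hull reason above.  Out-of-domain queries still
receive predictions, flagged, since refusing to predict helps nobody in a
screening setting.

## Synthetic benchmark

The generator emulates a curated single-endpoint IC50 table: 150 actives
carrying a planted para-alkyl-phenol motif (`[OX2H]c1ccc(cc1)[#6;A]`, a
classic ER pharmacophore element, also a curated bit of the substructure
family) with pIC50 ~ N(7.0, 0.4) truncated above 6, and 150 inactives on
motif-free scaffolds (no aromatic hydroxyls anywhere, so the motif bit
cannot fire) with pIC50 ~ N(4.0, 0.4) truncated below 5.  Class means sit a
full log unit clear of the 6/5 thresholds so labels are unambiguous at zero
noise.  `label_noise` swaps the structural class of a compound (motif ↔
no-motif) with the given probability while keeping its potency label,
degrading the learnable signal monotonically (tested over noise 0/0.1/0.2).
Structures come from a small scaffold grammar (aromatic/saturated cores,
alkyl/amine/halide decorations), are validated through the standardizer at
generation time, and are unique after canonicalization.  A companion
injector adds replicates (unit swaps, salt forms, jittered values,
deliberate conflicts) with known ground truth to exercise curation.

What passing these tests shows: the pipeline's plumbing — curation
arithmetic, featurization identity, split determinism, tuning, domain
geometry — is correct, and a clean substructure signal is recovered.  What
it does not show: performance on real assay data, where signals are
distributed over many correlated bits, classes are imbalanced, and assay
noise is not unit-normal; the benchmark makes no attempt to emulate the real
ER SAR landscape or ChEMBL's assay heterogeneity.

## Problem sizes and seeds

Benchmark-scale runs (tests and the acceptance script) use n = 150+150 per
target and a reduced tuning grid of ntree ∈ {100, 200} × mtry ∈ {5, 10} —
on a perfectly separable benchmark the tuning surface is flat, so the wider
default grid adds computation without information; the full grid remains
the library default for real data.  Every stochastic component (generator,
fold shuffling, forest) is seeded; the Kennard–Stone split and the PCA box
have no random state at all, which is what makes byte-identical prediction
CSVs a testable guarantee.

## Known limitations

Single endpoint (IC50) only; no assay-confidence weighting.  The synthetic
PubChem/Klekota–Roth stand-ins preserve cardinality and structure, not
per-bit semantics, so Gini ranks on those families name synthetic bits.
The 2-component bounding box is a coarse, axis-aligned domain — it can admit
compounds far from the training data along discarded components.  No
probability calibration, y-randomization or scaffold-based splitting.
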