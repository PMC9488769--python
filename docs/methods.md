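# Methods

## Scope and data flow

`ecforge` implements a two-stage reconstruction pipeline. Stage one ingests
tabular EC predictions from up to five upstream annotation tools (the tools
themselves are never executed here), trains one small classifier per EC
number, and emits scored annotations. Stage two maps high-confidence
annotations to reactions in a KEGG-like or BiGG-like database, assembles a
draft stoichiometric model, gap-fills it by mixed-integer linear
programming, simulates it by flux balance analysis, and serializes it.

## Ensemble classification

**Training sets.** For EC *x*: positives are proteins carrying *x* in the
gold labels; negatives are proteins predicted *x* by at least one tool but
lacking it in gold. This makes the negative class exactly the set of
candidate false positives the classifier must reject. ECs with fewer than
10 gold proteins are excluded from training (too little signal) and remain
reachable only through the pass-through rule.

**Naive Bayes (default).** Features are binary high-confidence indicators,
one per tool able to predict the EC. Parameters use add-α smoothing with
α = 1: prior = (n₊+α)/(n+2α), p(Fᵢ=1|y=c) = (countᵢ,c+α)/(n_c+2α). The
smoothing is required, not cosmetic: it keeps every probability strictly
inside (0, 1) so that a feature never observed in one class cannot zero out
the posterior. The posterior is evaluated in log space with exact two-class
normalization; the test suite verifies agreement with the direct
product-form evaluation to 1e-12 over a thousand random parameter draws.

**Alternatives.** Logistic regression consumes one-hot confidence-level
encodings, random forests ordinal levels; both come from scikit-learn with
library-default hyperparameters and an explicit seed (stochastic fits
require one; 42 is recorded in the serialized model). Majority rule assigns
an EC when strictly more than half of the tools *able* to predict it call
it at high confidence — the denominator is the able-tool count, not the
total tool count, which keeps the rule meaningful for ECs only one or two
tools cover. The best-tool rule assigns when a tool with maximal training
F1 for the EC calls it; ties are resolved permissively (any tied-best tool
suffices), and ECs missing from the performance table fall back to
majority voting with a warning.

**Selection rules.** A score strictly greater than 0.5 is high-confidence.
The auto-assign rule covers ECs inside every tool's predictive range on
which no tool produced a false positive; the rule is parameterized on the
training data only, since it is part of the trained model, and fires on any
prediction of the EC. The pass-through rule promotes the designated
wide-range tool's high-confidence calls for ECs outside the trained model's
range. The multifunctional filter (keep the top-scoring EC plus ECs
frequently co-occurring with it in training: co-annotated in ≥ 10 proteins
and in ≥ 50% of the proteins carrying the top EC, both configurable) is
implemented but off by default: it buys precision on monofunctional
proteins at the cost of recall on genuinely multifunctional ones.

**Metrics.** Macro metrics average per-EC precision/recall/F1 with equal
class weight; ECs with no predictions have undefined precision and are
excluded from the precision mean only (the exclusion count is reported).
Macro F1 is the mean of per-class F1; the harmonic mean of macro P and R is
reported alongside because both conventions circulate. Micro metrics pool
(protein, EC) decisions. Specificity on non-enzymes is the fraction
receiving zero high-confidence calls. The k-fold splitter assigns proteins
(multifunctional ones first, hardest to balance) greedily to the fold where
their ECs are least represented, then audits that every EC retains training
examples in every fold; an EC with fewer than k proteins is rejected. This
greedy EC-coverage-preserving assignment approximates published
multifunctional-split protocols without reproducing any one of them.

## Reconstruction

**Draft assembly.** Every database reaction linked to a high-confidence EC
enters the draft (indiscriminate inclusion — a known source of pathway
redundancy, accepted deliberately), with supporting proteins attached as
flat OR gene associations; spontaneous reactions are added if requested;
exactly one user reaction must be flagged as the objective (biomass).
Sequence-similarity support for non-EC reactions (BLAST hits at E ≤ 1e-20,
boundary inclusive) is honored only for BiGG-like databases. Everything
lives in one compartment; no transport prediction is attempted. Reversible
reactions default to bounds (−1000, 1000), irreversible to (0, 1000).

**Dead ends.** A metabolite is a dead end if no reaction can produce it or
none can consume it under current bounds (reversibility counts both ways).
Synthesized exchanges are drains by default; metabolites nothing can
produce get a reversible exchange so a supply route exists. Dead ends are
detected on the pooled base-plus-candidate network, so only metabolites
orphaned even after all candidates are considered receive exchanges.

**Penalties.** Candidate scores sᵢ in (0.0001, 0.5] are scaled to median 1
(midpoint interpolation for even counts) and converted to pᵢ = 1/(1+s′ᵢ);
scores at or below the 0.0001 floor are treated as unscored (default
penalty 1), as are candidates without any score. The dead-end exchange
penalty defaults to 1; raising it (e.g. to 10) pushes solutions toward the
declared media instead of inventing nutrient imports.

**MILP.** Solved with scipy's HiGHS backend; integrality tolerance 1e-6,
default feasibility tolerances. Variables are the flux vector over the
combined network plus one binary indicator per candidate, coupled by
yᵢv_{L,i} ≤ vᵢ ≤ yᵢv_{U,i}. Equal-penalty optima are solver-arbitrary; a
`deterministic_tie_break` flag adds a 1e-9-scale lexicographic perturbation
for reproducible tests (the reported objective is always the exact penalty
sum of the returned set). Infeasibility (no candidate subset reaches β)
raises an error listing objective precursors that remain unproducible.
Augmentation re-verifies the repaired model with one independent LP solve.

**Simulation.** FBA is a single HiGHS LP; optima below 1e-9 are reported
as 0. Knockouts zero all reactions associated with exactly one gene —
with flat OR associations, genes appearing only in multi-gene reactions
are untestable rather than guessed at. Growth calls use a 1e-4 h⁻¹
threshold, inclusive, for both knockouts and phenotype arrays (the
knockout threshold is a package choice; the array threshold and the
10 mmol/gDW/h alternate-source bound follow standard phenotype-array
practice). Yield analyses fix substrate uptake at 1 mmol/gDW/h, zero
oxygen uptake when anaerobic, and always run a zero-substrate control: a
nonzero control objective is the signature of an energy-generating cycle
(typically a wrong reversibility) and is flagged.

**Serialization.** SBML Level 3 Version 1 with fbc v2 (strict): SBO:0000247
on species, SBO:0000375 on reactions, SBO:0000243 on gene products; EC
links as identifiers.org `ec-code` CV terms; provenance and gap-fill
penalties in element notes. Identifiers are sanitized (non-alphanumerics to
underscores, `R_`/`M_`/`G_` prefixes) and the mapping returned. The reader
inverts all of this, so write-read round-trips preserve the stoichiometric
matrix, bounds, gene sets and objective exactly. JSON model serialization
covers naive Bayes parameter blocks, the rule tables and logistic
regression coefficients; random forests should be persisted with joblib.

## Synthetic data

The generators emulate the pipeline's inputs at desk scale. Prediction
tables: each protein carries one gold EC (plus a second at the
multifunctional rate, default 0.1); each tool emits true ECs with its
(optionally per-EC) sensitivity and false ECs with its false-positive rate;
true-call scores are uniform on the high bin (0.5, 1], false-call scores
uniform on (0, 1], the simplest model in which true predictions skew high.
Networks: linear chains (FBA optimum equals the uptake bound), parallel
paths (redundancy for knockout tests), gapped chains (1–3 withheld
reactions whose low-confidence scores are drawn from (0.05, 0.5], plus
decoy reactions among disconnected metabolites, so the withheld set is the
unique minimum-penalty repair — verified by enumeration, not assumed), and
energy-cycle networks (an irreversible two-reaction loop producing the
biomass precursor from nothing). All generators are pure functions of
their parameters and seed.

What the synthetic data does not capture: realistic EC class-size
distributions, sequence-similarity structure between training and test
proteins, correlated tool errors, genome-scale network sizes, and
biologically calibrated biomass compositions. Passing tests therefore
demonstrate correctness of the algorithms and formulas, not expected
performance on real proteomes.

## Problem sizes and numerical choices

Tests run networks of 2–7 reactions with candidate pools of at most 12 (so
exhaustive subset enumeration stays an exact oracle), prediction benchmarks
of 120–400 proteins over 4–8 EC classes, and 1000-draw randomized checks of
the posterior formula. The MILP/LP tolerance constants live in
`gapfill.py`/`simulate.py`; comparisons against enumeration use 1e-9. The
cross-validated ensemble comparison fixes seed 11 and two tools with
complementary per-EC sensitivity (0.95/0.4 at 3% false-positive rate),
chosen once as a realistic complementary-coverage scenario.

## Known limitations

No compartments or transport prediction; flat OR gene associations only
(no complexes, hence conservative "untestable" knockout calls); no
thermodynamic constraints or reversibility inference; single-optimum gap
filling (no enumeration of alternative solutions); KEGG/BiGG vendor-format
parsing is out of scope — the database schema is the package's own JSON/TSV
with converters expected upstream.
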