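# Methods

## The problem

In tandem MS, protonated analytes isolated in an ion trap can react with a
neutral reagent gas.  With 2-methoxypropene (MOP), some protonated analytes
form a stable adduct (the *diagnostic product*, DP) whose appearance
identifies functional groups — famously separating a sulfoxide drug
metabolite from its keto isomer where collision-activated dissociation
cannot.  Others transfer a proton to MOP or do not react at all.  The
measured quantity per analyte is the *branching ratio*: the abundance of the
DP divided by the abundance of all product ions, in percent, constant over
reaction time.

`mopflow` predicts, from structure alone, whether a protonated analyte will
form the diagnostic adduct, and renders the trained model as a *chemical
reactivity flowchart* — an ordered list of Boolean substructure checks a
chemist can read and argue with.

## Featurization

Analytes are represented as binary Morgan (ECFP-like) circular fingerprints
(RDKit), default radius 1 and width 2048 bits.  Radius 1 keeps each bit close
to a nameable functional group and minimizes bit collisions; radii 2 and 3
are supported for comparison scans.  Bits are presence/absence, not counts:
the downstream decisions are Boolean feature checks.

Full reaction-SMILES input (`protonated analyte + MOP >> adduct`) is
accepted, but fingerprinting is applied to the *neutral analyte* only.  The
MOP reactant and the adduct product are constant across records, so their
bits carry no information gain, and the interpretable features of a
reactivity flowchart are analyte substructures.  Deprotonation removes one
hydrogen from the first positively charged H-bearing atom; zwitterionic
groups (nitro, N-oxide) are left intact.  Protonation site is not encoded.

Every set bit is mapped back to the atom environment(s) that generated it
(canonical fragment SMILES + SMARTS + an example atom), and columns reached
by more than one distinct environment are flagged as collisions.  This map
is what makes the final flowchart readable.

## Labels and the cutoff

The classifier is binary: *reactive* (forms the DP) vs *unreactive* (proton
transfer and no reaction, pooled).  Branching ratios are binarized at a
cutoff θ with a `>=` comparison.  The default θ = 70% sits inside the
largest empty interval of the training ratio distribution (65–83%): no
training analyte falls inside it, so the labeling is insensitive to
measurement error (reproducibility is about ±10%).  θ = 40%, at the
second-largest gap, is the natural alternative and is retained in the
default comparison grid {10, 20, 30, 40, 50, 60, 70, 90}; 80% is omitted
because it labels the training set identically to 70%.  `gap_analysis`
exposes the gap structure so the cutoff choice is auditable.

## Trees and ensembles

Trees are grown from scratch by greedy maximization of information gain

    H(S) = -Σ_c p(c) log2 p(c),     IG(S, A) = H(S) - Σ_t (|t|/|S|) H(t),

with Boolean bit-presence splits only, a minimum leaf size of 2 (one analyte
must never define a leaf), and no depth limit by default.  Stopping: pure
node, no candidate split with IG above float tolerance (1e-12), or no split
leaving both children at the minimum leaf size.  Ties on IG go to the lowest
column index — deterministic and seed-free.  Leaf ties on class counts go to
*unreactive*, the majority class of the data and the conservative call.

Two sources of bootstrap randomness are implemented and on by default:

* row resampling with replacement at full size, and
* per-node candidate-feature subsetting of ⌈√(number of ever-set bits)⌉
  columns drawn without replacement.

The ensemble (default B = 10 000 trees) aggregates per-analyte reactivity
probability as the fraction of trees voting reactive (so probabilities are
multiples of 1/B), thresholded at 0.5 with `>=`.  Feature usage is tallied
per tree (anywhere / at the root / per shallowest depth).  Seeding: one
master `SeedSequence` spawns one substream per tree, so tree *i* is the same
whether B is 100 or 10 000, and changing B never perturbs earlier trees.

The √-rule subset size and the "both sources on" default are this package's
resolution of an ambiguity: bootstrapped tree models of this kind can
randomize rows, features, or both, and the published description names
bootstrapping while attributing variation to random input features.  Both
are configurable (`row_resampling`, `feature_subset_size="all"`).

## Flowchart distillation

The flowchart is built by greedy conditional-frequency distillation — the
construction is this package's design; the published account specifies the
inputs (feature frequencies over 10 000 trees) and the output (the chart)
but not the assembly procedure.

State = a partial assignment of fingerprint bits (the answers given so far).
Each tree is consulted under that assignment: following known bits it either
reaches a leaf (a decided vote) or stops at a node testing an unknown bit —
its *next question*.  The next check is the bit most trees ask next, with
two refinements:

* bits that do not separate the training rows consistent with the current
  answers are not askable;
* bits inducing the *same partition* of those rows are pooled as one check
  (they are different fingerprint environments of the same substructure,
  e.g. the S atom and the C–S environment of a sulfoxide) under the lowest
  column index.  This is what keeps charts comparable after retraining.

A branch terminates in a class when the consistent training rows are at
least `purity` (default 0.9) one class, when no tree asks anything further,
or at `max_depth` (default 8).  The terminal label is the majority over
consistent rows; with no consistent rows it falls back to the tree votes
(undecided trees voting their node's training majority).  A node's `support`
is the fraction of trees still undecided when the check is made; it shrinks
monotonically along every path.

Exact reproduction of any particular published check sequence is not claimed
— the chart is a faithful distillation of *this* ensemble, validated by the
requirement that chart and thresholded ensemble agree on ≥ 90% of training
rows on planted-rule data.

## Evaluation

With 8 reactive vs 28 unreactive training analytes, accuracy is misleading,
so models are compared by Cohen's kappa:

    Po = (TP+TN)/N,
    Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N²,
    κ  = (Po − Pe) / (1 − Pe),

with κ undefined (flagged, NaN) when Pe = 1.  κ is reported to 2 d.p.

**Proton-affinity baseline.**  An analyte whose PA exceeds the reagent's
*may* form the adduct; below it, proton transfer dominates.  The standalone
rule is `reactive ⟺ PA > 214.42 kcal/mol` (the DFT-calculated MOP value).
The comparison is strict: a tie scores unreactive, because adduct formation
above the threshold is only possible, not assured, and PA orderings within
0.1 kcal/mol carry no real significance.  The standalone baseline's κ is
deliberately not treated as a reproducible constant — two blind-test PAs sit
within 0.06 kcal/mol of the reagent value, inside that stated noise.

**Hybrid verification filter.**  Ensemble predictions are overridden by the
PA rule *only* for analytes carrying fingerprint bits never set in the
training matrix (novel functional groups, where the ensemble extrapolates).
Applying the PA rule everywhere would break analytes the ensemble already
gets right; restricting it to novel chemistry repairs the nitro-compound
errors without collateral damage.

## Synthetic data

`generate_library` emits molecules from a scaffold × decoration grammar
(alkyl/branched/cyclic scaffolds; sulfoxide decorations for the
pattern-present half; sulfone, nitro, alcohol, amine, ketone, ether,
nitrile, aryl for the rest).  A planted SMARTS rule (default
`[CX4][SX3](=O)[#6]`, aliphatic sulfoxide) fixes each molecule's
branching-ratio regime: mean 90% when present, 5% when absent, Gaussian
noise of 5 percentage points, and a 5% probability of drawing from the wrong
regime (label noise).  These defaults emulate the observed reactivity
landscape: a strongly bimodal ratio distribution with a dominant sulfoxide
motif and occasional exceptions.

What the generator does *not* emulate: real measurement correlation between
similar analytes, N-oxide chemistry as a second reactive motif, ring-fused
and polyfunctional structures, and any relationship between PA and
structure.  Passing the recovery tests therefore shows the pipeline can
re-derive a substructure rule from data of this size and noise level — not
that any particular real functional group ranks where it does.

Two bundled fixtures complement the generator:

* `blind_test_table()` — the 13-analyte prospective test set (experimental
  outcomes, vote fractions for cutoffs 20–70% at radius 1, DFT proton
  affinities, a novel-nitro flag marking the two nitro compounds that are
  the hybrid filter's scope).  Transcribed published values.
* `synthetic_training_table()` — a clearly-labelled SYNTHETIC stand-in for
  the 36-analyte training table, whose full listing is not redistributed
  here.  It is constructed to satisfy every published distributional fact
  (n = 36; largest gap 65–83; second-largest just below 40; 8 analytes ≥ 70%
  with identical labels at 80%; 13 ≥ 40%; the four named 40–70% compounds in
  that band; tetrahydrothiophene 1-oxide the one sulfoxide below 40%;
  sulfones/alcohols/amines all unreactive).  Individual ratios and most
  structures are invented; anything computed from it tests the *operations*,
  not the original measurements.

## Problem sizes in the test and acceptance runs

Recovery experiments use 40-molecule libraries, B = 500 trees, and 20
replicate seeds; unit tests use B = 60–300.  These sizes put Monte-Carlo
noise well below the asserted margins (vote fractions are multiples of
1/500; root-recovery is asserted at ≥ 19/20) while keeping the whole suite
interactive.  The held-out-kappa acceptance bound (mean ≥ 0.8 over seeds) is
set by the generator's own label noise: a single 40-row test set has a ≈6%
chance of ≥5 flipped labels, which caps that seed's κ below 0.8 even for a
perfect classifier, so the per-seed statistic would test the noise draw, not
the method.

## Known limitations

* Binary bits mean count information (two sulfoxides vs one) is invisible.
* Bit collisions are flagged but not resolved; at radius 1 and 2048 bits
  they are rare on small molecules.
* The flowchart is a distillation, not an exact compilation: agreement with
  the ensemble is high but not guaranteed to be total.
* Proton affinities are consumed as inputs (e.g. from DFT); the package
  never computes them.
* The stand-in training profile supports demonstration and operation-level
  tests only; retraining it does not reproduce the original study's model.
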