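# Methods

## Overview

`kgi` models a binary clinical phenotype from gene expression by way of
*knowledge-based* features: instead of feeding thousands of individual genes
to a classifier, expression is first aggregated over curated gene sets
(pathways, ontology terms, protein families), and a grammatical-evolution
neural network (GENN) then searches for small arithmetic networks over those
aggregate features.  A final integration stage pools the best-model
variables of several knowledge sources and reruns the search, looking for
models that cross sources (e.g. a pathway interacting with a protein
family).

The pipeline is: transformation → per-source cross-validated search →
best-model selection → integration.

## Transformation

For each gene set *S* with measured member genes *g ∈ S* (those present in
the expression matrix), the feature value for sample *i* is

    x_i(S) = (1/|S_measured|) · Σ_{g ∈ S_measured} e_ig

i.e. the sum of member expression divided by the member count — the mean.
Dividing by the member count removes the bias a raw sum carries toward
large sets.  The denominator counts *measured* members only: normalizing by
a set's nominal curated size would shrink features of poorly-measured sets
toward zero for no biological reason.

Sets are kept only when strictly more than `min_measured` (default 10)
member genes are measured; aggregates of very small sets are dominated by
single-gene noise.  "More than 10" is read as ≥ 11; the threshold is a
parameter, so the ≥ 10 reading is one flag away.  Genes may belong to many
sets — real collections overlap heavily and no disjointness is enforced.

Feature identifiers are `<source>:<set-id>` with characters that are
structural in model text (whitespace, parentheses, commas, `*`) replaced by
underscores, so features can appear verbatim inside serialized models.

## The model class and its grammar

An evolved classifier is an expression tree.  Internal nodes take 2 or 3
weighted inputs and apply one of four activations: PADD (sum), PSUB
(left-to-right subtraction), PMULT (product), PDIV (left-to-right protected
division).  Leaves are knowledge features; weights are constants drawn from
the grammar (`1.0`, `-1.0`, or a signed single-decimal `d.d`).  The
canonical grammar is:

    <net>  ::= <node>
    <node> ::= <func> ( <in> , <in> ) | <func> ( <in> , <in> , <in> )
    <func> ::= PADD | PSUB | PMULT | PDIV
    <in>   ::= <w> * <var> | <w> * <node>
    <w>    ::= 1.0 | -1.0 | <d>.<d> | -<d>.<d>
    <d>    ::= 0 | 1 | … | 9
    <var>  ::= F_1 | … | F_p

Although the grammar has no additive constant, a model can synthesize one:
`PDIV(1.0*F, 1.0*F)` evaluates to 1 whenever `F ≠ 0`, so
`PSUB(w1*F, w2*PDIV(1.0*F, 1.0*F))` realizes the thresholded single-feature
classifier `w1·F − w2`.  This matters under class imbalance, where the
optimal decision boundary is far from zero.

### Genotype→phenotype mapping

Genomes are variable-length strings of integer codons (length 20–400,
values below 2^16; a classical bit-string genome is readable through
`genome_from_bits`).  Mapping is the standard grammatical-evolution rule: a
leftmost derivation in which each expansion of a nonterminal with k > 1
alternatives consumes one codon and selects alternative `codon mod k`;
single-alternative rules consume nothing.  The codon pointer wraps at the
genome end at most `wrap_limit` (default 2) times; an incomplete derivation
after that is a mapping *failure*, which is reported as a value (fitness 0)
rather than raised, keeping the evolutionary loop total.  Unread codons are
neutral: appending them never changes the phenotype.

### Numerical choices

- The root value is squashed through the logistic function, giving a score
  in (0, 1); classification is `score ≥ 0.5` with the tie assigned to the
  positive class.  A bounded score makes ROC AUC well defined.  Raw-output
  thresholding at 0 is equivalent at the default threshold since
  `logistic(0) = 0.5`.
- Protected division: a denominator with |d| < 1e-8 makes that division
  step yield 1.0.  This is conventional genetic-programming protection and
  shapes fitness (a division node can silently become a constant).
- Every weighted term and node output is clamped to ±1e100, so no finite
  input can overflow to infinity or cancel to NaN; evaluation is total on
  finite inputs and scores stay strictly inside (0, 1).

## Evolution

Fitness is the balanced accuracy — (sensitivity + specificity)/2 — of the
model's predictions on the training fold.  With 39 cases against 454
controls, raw accuracy would reward the majority-class predictor with 0.92;
balanced accuracy gives it exactly 0.5.

The island model splits the population into demes.  Within a deme each
generation applies: elitism (top `elitism` genomes copied unchanged),
tournament selection (size 2), aligned single-point codon crossover
(probability 0.9; offspring take each other's tails, so lengths stay within
the parents' range), and per-codon uniform reset mutation (probability 0.01
per codon).  Every `migration_interval` generations the best genome of each
deme replaces the worst genome of the next deme around a ring; all bests
are taken from the pre-migration state, so the global best never decreases
across a migration, and with elitism ≥ 1 each deme's best fitness is
monotone non-decreasing in generations.  These operators and rates are
conventional grammatical-evolution defaults; all are exposed in
`EvolutionConfig`.

Generation 0 is initialized to be *all functional*: a random derivation is
grown (symbol-depth budget 11, about five node levels; choices restricted
to alternatives that can still terminate within budget), its choices are
reverse-encoded as codons congruent to the choice index, and the genome is
padded with random codons to a random length in [20, 400].  Uniformly
random codon strings map successfully only about half the time, so grown
initialization buys a meaningful head start without constraining what
variation can later produce.

Reproducibility: one master seed; each deme owns a child random stream
spawned deterministically from it, and all cross-deme bookkeeping is
serial, so results are bit-identical regardless of worker count
(`n_jobs`).  Repeated phenotypes are cached (genome-digest → model text →
fitness), which substantially accelerates converged populations without
changing any result.

### Scale

Two profiles ship.  The desk profile — 150 individuals × 3 demes × 40
generations, migration every 10 — is what the test battery, the analysis
scripts and the acceptance script use; it is sized so that a full 5-fold
run takes seconds to tens of seconds on one CPU while still recovering the
planted effects in the synthetic scenarios.  The full-scale profile
(25,000 × 20 × 300, migration every 15) matches the scale of full production runs
of this method on real cohorts; it is shipped as a named preset and not
exercised by tests.

## Cross-validation and best-model selection

Folds are stratified by default (equal-size folds preserving the case
fraction); with 39 cases in 493 samples an unstratified split can produce
folds with no cases, making balanced accuracy undefined.  A literal
equal-random split is available behind a flag.  Each fold evolves on the
other four fifths with a fold-specific seed derived from the master seed,
and the fold's best-ever solution is scored on the held-out fifth: balanced
accuracy of its thresholded predictions, and Mann–Whitney AUC of its
continuous scores.

Two notions of consistency are computed:

- **best_model_support** — model identity taken as the *set of input
  feature names* (weights and topology ignored); the best model is the
  feature set identified in the most folds, ties broken by highest mean
  held-out balanced accuracy, then fewest features, then lexicographic
  names.  The chosen set is represented by its best held-out fold's tree.
- **feature_support(f)** — the number of folds whose best model uses
  feature *f* (per-variable consistency, the "4/5"-style number).  Under
  genetic-programming bloat, whole feature sets rarely coincide across
  folds while genuinely informative single variables recur in nearly all of
  them, so per-variable support is the more meaningful recovery statistic
  and is what the signal-recovery checks use.

The headline metric of a run is the *best* per-fold held-out balanced
accuracy; the mean ± sd across folds is reported alongside as the less
optimistic summary.

## Integration

Each source's best-model features (columns keep their source-prefixed
names) are pooled into one combined matrix and the cross-validated search
is rerun on it.  If the per-source searches each happened to retain a
variable that only matters jointly, integration can discover the joint
model even though neither single-source run could see it.

## Synthetic data

The generator emulates the shape of the real inputs: continuous
(already-normalized) expression, several named gene-set collections, an
imbalanced binary phenotype.  Background expression is i.i.d. N(0, σ²) —
the pipeline consumes normalized values, and Gaussianity puts the Bayes
accuracy of every planted effect in closed form.  Gene sets are drawn
disjoint so planted effects cannot leak between features (real collections
overlap; the transformation handles that, the generator simply avoids it).
Labels are assigned by exact count (`round(ratio·n)` cases at random
positions), so the 39/454 cohort shape is reproduced exactly.

Effects are planted at the gene level but specified on the aggregate scale
(the aggregate of m i.i.d. genes has sd σ/√m):

- **shift**: every member gene of the planted set gains
  `magnitude · σ/√m` in case samples, so the aggregate separates the
  classes by `magnitude` of its own sd; the Bayes balanced accuracy on
  that one feature is Φ(magnitude/2).
- **interaction**: labels are drawn Bernoulli with probability p₊ or p₋
  depending on the *sign product* of two planted aggregates, with
  p₊ − p₋ = magnitude and (p₊ + p₋)/2 = the class ratio.  Each aggregate
  alone is exactly null marginally; the product of the two features is a
  near-perfect discriminator.  Recovering this effect certifies that the
  search finds non-additive structure.

Preset scenarios: **S1** (200 samples, 25 % cases, 50 disjoint 20-gene
pathway sets, one set shifted by 3 aggregate-sd → Bayes BA Φ(1.5) ≈ 0.933);
**S2** (600 balanced samples, two sources of 12 sets × 15 genes, one XOR
interaction across sources with a 0.90 probability gap); **S3** (493
samples, exactly 39 cases, 30 sets, nothing planted).  S2's sample size is
chosen so that the sampling noise of a null feature's AUC (se ≈ 0.024) stays
well below the 0.55 marginal-null bound checked in tests.

What passing on this generator does *not* show: robustness to non-Gaussian
expression distributions, batch effects, missingness, overlapping or
mis-annotated gene sets, or correlated background genes.  Those belong to
upstream normalization and curation, which the pipeline deliberately
consumes as given.

## Known limitations

- The search is single-objective; there is no parsimony pressure, so best
  models carry hitchhiking features (bloat).  Per-variable support is the
  recommended recovery readout.
- Balanced accuracy on small held-out folds is coarse (steps of 1/positives
  per fold), so per-fold test metrics are noisy at desk scale.
- Model equality ignores weights and topology; two structurally different
  models over the same features count as one.
- The grammar fixes the activation inventory to the four arithmetic nodes;
  there are no trainable hidden-layer weights — all constants evolve
  through the grammar.
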