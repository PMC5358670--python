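# Methods

This note documents the statistical model, the algorithms, the defaults and
the design decisions behind `brl`, at the level of detail a maintainer or a
methods-minded user needs. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Given an *m* × *n* matrix of continuous measurements (expression
intensities) and a categorical class per sample, learn a set of IF-THEN
rules over discretized features that predicts the class and reads as a
compact summary of the data. The intended regime is *n* ≫ *m* with only a
few informative features — the biomarker-discovery setting in which model
parsimony (few rules, few variables) matters as much as accuracy.

## Supervised discretization (EBD)

Each feature is discretized independently against the class on the
*training* data only. For one feature, sort the (value, label) pairs and
group equal values into runs; candidate cut-points are midpoints between
adjacent runs unless both runs are pure in the same class (a cut there can
never help, and equal values can never be separated). With *B* candidates,
a cut-point set *C* (|*C*| = *c*) is scored in log space as

```
log P(C) + Σ_intervals log DirMult(interval class counts)
log P(C) = log p + c·log(1−p) − log C(B, c),   p = 1/(1+λ)
```

where `DirMult` is the multinomial-Dirichlet marginal likelihood with a
uniform Dirichlet(1) prior — the same leaf evidence as the K2 score below —
and the prior is geometric in the count *c* (so that E[*c*] = λ) and
uniform over the `C(B, c)` placements of *c* cuts among the *B* candidates.

The placement term is a multiplicity correction: the score is *maximized*
over cut positions, and without it the maximum over the 2^B placements
capitalizes on chance — at *m* ≈ 90 a class-independent Gaussian feature
would typically receive several spurious cut-points, and downstream models
inherit the noise. With the correction, class-independent features almost
always come out with zero cut-points (arity 1) and are excluded from the
structure search, while a feature separated by a single threshold reliably
gets exactly one cut. The exact prior formula is recorded in every scheme
file, and the dynamic program is checked against brute-force enumeration of
all cut subsets in the tests.

The optimum is found by an O(B²) dynamic program over candidate boundaries
(exact, since the score is additive over intervals given *c*), with the
interval count capped at `max_intervals` = 16 as a guard — generous
relative to the 2–4 intervals typical of informative expression markers.

Defaults: λ = 0.5. Intervals are right-closed (`value ≤ cut`), applied
unchanged to held-out data; out-of-range values fall into the open outer
intervals, and a variable with *k* cut-points keeps arity *k* + 1 even when
an interval is empty in a particular fold.

Missing feature values are rejected with an error rather than imputed.

## K2 scoring

A model is a decision tree over parent-variable value partitions whose
leaves carry class-count vectors. Leaf *j* with counts *N<sub>jk</sub>*
contributes `log[(r_t−1)!/(N_j+r_t−1)! · Π_k N_jk!]`, computed via
log-gamma (finite up to and beyond 10⁶ instances per leaf); the model
score is the sum over leaves and empty leaves contribute log 1 = 0. This is
the K2 metric with leaves playing the role of parent configurations; the
structure prior is uniform, so models are compared by marginal likelihood
alone. Ties between equal-scoring models are broken toward fewer used
variables, then fewer leaves, then earlier insertion — a deterministic
preference for parsimony.

## Structure search

Both searches are target-centric (predictors are only ever parents of the
class), deterministic, and share a score-ordered, capacity-bounded beam
(`beamWidth` = 1000) with structural de-duplication, and a cap
(`maxConj` = 8) on distinct variables per model. Variables whose
discretization produced arity 1 are excluded — they admit no split.

**Global (GSS).** The state is a parent set; its tree is the fully
expanded CPT, one leaf per joint parent assignment (`Π r_i` leaves — two
parents of arity 3 and 4 give 12 rules; ten binary parents give 1024).
Search is best-first: the beam is seeded with every single-parent model;
popping a model scores all of its one-parent extensions (each parent set is
scored at most once, in a cache shared by the entire beam) and queues the
single best extension for further growth. Chains grow strictly in set
size, so the search ends at `maxConj` depth; the best model ever scored is
returned. We deliberately queue the best extension even when it does not
improve the popped model's score: an optimum is sometimes reachable only
through a score-neutral or score-decreasing intermediate, and with this
rule the search provably explores every parent set when *n* is small
(exhaustive-equivalence is asserted in the tests). Scoring a parent set
counts only occupied cells, so sparse joint spaces cost O(*m*) rather than
O(`Π r_i`).

**Local (LSS).** The state is the tree itself. The beam is seeded with
singleton models — one complete split of each variable at the root. A
popped model undergoes one *specialization sweep*: for every variable and
every leaf whose path does not already condition on it, every binary split
(all 2-block partitions of the value set, `2^(r−1)−1` of them) plus the
complete split (one branch per value) is evaluated, rescoring only the
affected leaf. The single best specialization of the sweep re-enters the
beam if and only if it strictly improves the popped model's score; the
best model ever seen is returned. Scores rise strictly along every queue
chain, so the search terminates; one sweep costs O(*n* · leaves · *m* ·
*r*) via a per-(leaf, variable) value-by-class count table from which all
splits are scored with one matrix product — instances are repartitioned
only for the winning split.

Queueing one candidate per sweep, rather than one per (variable, leaf)
pair, is what keeps total work near quadratic in *n* at fixed model
capacity (asserted in the tests by counting split evaluations while
doubling *n*); queueing every improving candidate floods the beam with
near-duplicates and inflates work by orders of magnitude without changing
the returned models in our experiments.

Because a leaf is only split when the score strictly improves, contexts
with indistinguishable class distributions are never separated: with two
binary genes where the class distribution under `GeneA = DOWN` is the same
for both values of `GeneB`, the local tree keeps the merged `GeneA = DOWN`
leaf and yields 3 rules against the global tree's 4. All 2-block
partitions are enumerated for binary splits; for three-valued variables
this is the 3 combinations one expects, and at arity ≥ 4 the count is
`2^(r−1)−1` (value *pairs* would not define a partition of the value set).

## Rules and prediction

One rule per leaf — including leaves with no training evidence, which the
ME&E property makes unavoidable. The antecedent is the conjunction of
(variable, value-set) constraints on the path; the consequent is the class
with the largest leaf count. Ties go to the training majority class (a
zero-evidence leaf therefore predicts the majority class with smoothed
probability 0.5). With smoothing α = 1 (configurable):

* class distribution: `(N_jk + α) / (N_j + α·r_t)`;
* TP = count of the predicted class, FP = sum of the others (the
  "against all other classes" framing covers the multi-class case);
* posterior probability `(TP+α)/((TP+α)+(FP+α))`, posterior odds
  `(TP+α)/(FP+α)`.

Rules are printed in descending posterior-odds order for readability; since
exactly one rule fires per instance, order carries no semantics. The
machine-format bundle (JSON) stores rules, leaf counts, the discretization
scheme, the model score and the run configuration, so prediction on raw
continuous data is self-contained and the text/machine round trip is
loss-less.

## Evaluation

Stratified k-fold cross-validation (default k = 10): within each class,
indices are shuffled under the run seed and dealt round-robin, so per-fold
class counts deviate from proportionality by at most one instance. Per
fold, the discretization scheme is refit on the training split alone and
applied to the held-out split (no information leak — asserted in the
tests); metrics are AUC, accuracy (percent correct), number of rules and
number of distinct antecedent variables, summarized as mean ± SEM (sample
standard deviation / √k). AUC is the rank-based Mann–Whitney statistic on
the predicted positive-class probability with half-credit for ties; with
more than two classes it is the one-vs-rest macro average (an extension —
the motivating datasets are binary). Folds whose training split is
single-class are skipped with a warning.

## Synthetic data

The generator emulates the shape of expression studies: *m* samples ×
*n* features of standard Gaussian noise, a Bernoulli(class balance) class,
and a planted subset of informative features. At depth 1 each informative
feature has its case-class mean shifted by `shift × sd` (effects in sd
units, scale-free). At depth 2 two features carry an XOR-style
interaction — each is marginally flat and only their joint value is
informative — which marginal methods (including per-feature EBD) cannot
see; it exists to exercise interaction-capable search. A separate
generator draws discrete two-predictor datasets from explicit per-cell
class distributions, used to study leaf merging under context-specific
independence. All randomness flows through one seeded generator; identical
seeds give identical data.

What the generator does *not* emulate: probe/batch effects, heavy-tailed
or count-based noise, correlated co-expression modules, normalization
artifacts. Passing tests therefore demonstrate correctness of the
machinery and recoverability of clean planted signal, not performance on
real microarray or RNA-Seq data.

## Problem sizes and defaults

Library defaults are `maxConj` = 8, `beamWidth` = 1000, λ = 0.5, α = 1,
k = 10 folds. The test suite and acceptance script exercise the pipeline
at m ≈ 60–100 samples and n ≈ 5–51 features (one planted marker among 50
noise genes for the recovery study; 10⁴ draws for distributional checks) —
sizes at which every oracle comparison (exact rational K2, exhaustive
parent sets, exhaustive cut-point subsets, all-pairs AUC) is feasible
exactly.

## Known limitations

* LSS explores a richer space than GSS but is still greedy per sweep; a
  specialization that only pays off two splits later can be missed.
* The EBD placement prior makes discretization conservative at small *m*;
  weak markers (≲ 1 sd shift at m ≲ 50) may receive no cut-points and
  hence never enter the search.
* Multi-class AUC and the TP/FP framing are documented extensions beyond
  the binary setting the method was designed around.
* No handling of missing values, batch effects or feature correlation;
  normalization is expected upstream.
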