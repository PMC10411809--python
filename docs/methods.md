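# Methods

## The annotation problem

Many classification problems in functional genomics — the motivating one
being conditional gene essentiality, where a gene is lethal to knock out
only under a specific condition such as embryonic development or immune
challenge — come with very few labelled examples and a large pool of
unlabelled ones, because labels require experiments. Pool-based active
learning addresses this by iterating: train a classifier on the labelled
set, pick informative unlabelled samples, label them, repeat. The
classical strategies (uncertainty sampling, random sampling) hand each
queried batch to a human oracle. This package implements the alternative
in which the oracle is replaced by a *certainty* heuristic: the samples
the classifier is most confident about are pseudo-labelled by the
classifier itself and appended to the training set, so no human is in
the loop.

## The certainty heuristic

Let `X` be the current labelled set and `U` the unlabelled pool. Each
iteration the classifier scores every pool sample with a positive-class
probability `p ∈ [0, 1]`. The scored pool is split at the classification
boundary `b` (default 0.6) into a positive side `P+ = {p ≥ b}` and a
negative side `P− = {p < b}`. The boundary sits above the conventional
0.5 to suppress false positives when scores skew high.

Quartiles of each side are computed with the order-statistic rule

    Q_i = the (i/4)(n+1)-th smallest value,  i = 1..4

with linear interpolation at fractional positions and clamping of
positions outside `[1, n]` (so `Q4` of any sample is its maximum, and a
singleton's every quartile is its value). Membership of the extreme
quartiles is inclusive: the fourth quartile of `P+` is `{p ≥ Q3}`, the
first quartile of `P−` is `{p ≤ Q1}`.

Two dynamic cut-offs follow:

* **sup** (positive side): the minimum of the fourth-quartile members if
  that minimum exceeds the user threshold `t` (default 0.9), otherwise
  `t` itself. Samples with `p ≥ sup` are pseudo-labelled positive. Since
  `sup ≥ t` always, every pseudo-positive carries confidence at least
  `t`.
* **inf** (negative side): the maximum of the first-quartile members.
  Samples with `p ≤ inf` are pseudo-labelled negative. Deliberately, no
  user threshold applies on this side — the asymmetry is part of the
  method (the negative class is assumed to be the bulk, so its extreme
  quartile is already safe).

The batch (possibly empty) moves from `U` to `X` with provenance tag
`pseudo`, and the loop repeats until the labelled fraction of the full
dataset reaches `stop_fraction` (default 0.90), the batch comes back
empty (status `stalled`), or `max_iterations` is hit. An optional
`stall_fallback="top1"` adds the single most extreme sample per side
instead of stalling; the default is to stop, because silently looping
without progress is worse than an explicit stall.

## Benchmark strategies and the simulated oracle

For comparison the loop also runs with *uncertainty* sampling (the
`batch_size = 20` samples closest to the boundary) and *random* sampling
(a uniform batch of 20), each followed by a simulated oracle that
replaces every pre-label with the held-back ground truth (provenance
`oracle`). The benchmark protocol on a fully labelled dataset: a
stratified 20% seeds the labelled set, the remaining 80% becomes the
pool with labels hidden, the loop runs to the stop criterion, and two
evaluations are reported separately because they answer different
questions:

* **annotation metrics** — all labels assigned during the run against
  the held-back truth (for oracle strategies this is 1.0 by
  construction; for the certainty strategy it measures pseudo-label
  quality);
* **residual metrics** — a final classifier, retrained on the
  accumulated labelled set, evaluated at the boundary on the samples
  still unlabelled at stop.

A caveat worth stating explicitly: the two strategies' residual pools
are not comparable sets. The random strategy's residual is an unbiased
10% of the data, while the certainty strategy's residual is precisely
the subset its own confidence rule declined to label all run — its
hardest samples. Residual accuracy therefore systematically understates
the certainty strategy relative to an oracle-backed baseline, and
head-to-head residual comparisons between the two should be read with
that selection bias in mind. Annotation metrics with the oracle
strategies' *pre-correction* labels would be the symmetric comparison,
but pre-correction labels are transient by design.

## Classifier and per-iteration pipeline

The classifier is LightGBM (binary objective). The default
hyperparameters are the settings published for the gene-essentiality
application: `n_estimators=600, learning_rate=0.05, num_leaves=32,
colsample_bytree=0.2, reg_alpha=3, reg_lambda=1, min_split_gain=0.01,
min_child_weight=40`. Note `min_child_weight` is a minimum
sum-of-hessians per leaf; with log-loss hessians capped at 0.25 a leaf
needs ~160 samples, so these defaults assume training sets of several
hundred rows upward. For simulation-scale data
`small_data_classifier_params()` keeps the same settings but relaxes the
two leaf-size floors (`min_child_weight=1e-3, min_child_samples=5`);
without this the booster cannot split at all on a few dozen rows and
degenerates to a constant score. The per-tree feature subsampling
(`colsample_bytree=0.2`) is kept deliberately: it forces the ensemble to
spread over features, which matters under self-training — an ensemble
allowed to lock onto a single separating feature gets confidently wrong
on samples where that one feature is contrarian, and pseudo-labelling
then reinforces the error.

Each iteration, from the current labelled set:

1. **SMOTE balancing.** Synthetic minority samples are convex
   combinations `x + u (x_nn − x)`, `u ~ U(0,1)`, of a minority sample
   and one of its `k = 5` (capped at minority size − 1) nearest minority
   neighbours, until class counts are equal. Synthetics are regenerated
   each iteration from real labelled rows only and never enter the
   persistent labelled set — this prevents synthetic points compounding
   across iterations.
2. **Embedded feature selection.** Features are ranked by
   Breiman-style out-of-bag permutation importance: a 100-tree bagged
   forest of decision trees (`max_features=sqrt`), each tree's OOB
   accuracy compared with its accuracy after shuffling one feature
   column, drops averaged over trees. The top `k = 400` (capped at the
   number of features) are kept. The forest is built from individual
   sklearn decision trees with package-owned bootstrap indices so the
   OOB masks are exact.
3. **Training and scoring.** The classifier is fit on the balanced,
   feature-selected set; 5-fold stratified CV scores
   (accuracy/precision/ROC-AUC) are computed on the same set for
   reporting only (the deployed model is the full-set refit; folds are
   capped by the smaller class count). The pool is scored and the
   configured strategy selects the batch.

Global preprocessing — z-scoring (sample sd, constant columns to zero)
and the pairwise Pearson redundancy filter (drop one of each pair with
|r| > 0.70, keeping the member more correlated with the class label;
pairs visited in descending |r|; ties keep the earlier column;
zero-variance features have correlation defined as 0 and are never
dropped on their own) — is fit once on the union of labelled and pool
rows before the loop, not per iteration. Labels enter only the
keep-choice. Per-iteration recomputation applies to SMOTE and feature
selection only.

Per-iteration randomness is derived deterministically from
`(config.seed, iteration)` via `numpy.random.SeedSequence`, so runs are
bit-reproducible while iterations draw independent streams.

## Gene-set features

Curated gene-set collections are de-redundified before feature
construction. Pairwise overlap is Jaccard `J(A,B) = |A∩B| / |A∪B|`;
pairs with `J > τ` (default 0.3, strictly) become edges of an undirected
graph over the sets. Each set carries weight `w = 1 − log10(p)/100`
from its significance p-value (`w ∈ [1, 2]` for `p ∈ [1e−100, 1]`; the
additive 1 makes the optimiser prefer keeping more sets, the log term
breaks ties toward significance). The retained collection is the
maximum-weight independent set of that graph — the binary program
`maximize Σ w_i x_i` subject to `x_i + x_j ≤ 1` on every edge — solved
exactly by branch-and-bound: isolated vertices are taken greedily,
connected components solved independently, and within a component the
search branches on a maximum-degree vertex (exclude it, or include it
and delete its closed neighbourhood), memoised on the surviving vertex
set. Exactness is what matters at curated-collection scale; the solver
is cross-checked against exhaustive subset enumeration in the tests.

Each kept set then contributes one feature per query gene: the
neighbourhood of the gene in a protein-association network is tested for
over-representation in the set by a one-sided Fisher's exact test (the
hypergeometric tail `P(X ≥ overlap)` over the universe, which defaults
to the union of network genes and set members), and the feature is
`−log10(p)`. An empty neighbourhood gives p = 1, feature 0. One-sided
over-representation is used because enrichment features are
one-directional by construction.

## Synthetic data

`make_binary_dataset` draws two Gaussian classes: each informative
dimension's class means differ by `class_sep` noise-sd units (so the
overall Mahalanobis separation is `class_sep·√n_informative`; at the
default 5 informative dimensions, `class_sep = 3` is near-separable and
`0.5` heavily overlapping). Noise dimensions are standard normal;
redundant dimensions are `ρ·z + √(1−ρ²)·ε` copies of informative ones,
giving Pearson correlation ≈ ρ. Defaults (`n = 200, d = 10,
n_informative = 5, pos_fraction = 0.35`) mirror the size and imbalance
of the small public benchmark tables the method was validated on.
`make_geneset_fixture` generates set collections with engineered
redundancy (a planted triple with pairwise `J > 0.3`), log-uniform
p-values on `[1e−10, 1]`, and an Erdős–Rényi association network with
one planted gene whose neighbourhood equals a set exactly.

What the generator deliberately does not emulate: heterogeneous feature
types (the real application mixes sequence, domain, topology and
localisation features), heavy-tailed or discrete feature distributions,
label noise, and feature dimensionality in the tens of thousands.
Passing tests therefore demonstrate the algorithmic contracts and the
qualitative behaviour of the loop, not performance claims about any
real organism's data.

## Problem sizes and numerical choices

Simulations in the tests and the acceptance script use n = 200 samples
(20% seed split), three seeds per condition for the separation ladder
{3, 2, 1, 0.5}, 20 paired seeds for the strategy comparison, 1000 random
pools (≤ 200 scores) for the heuristic-equivalence check, 200 random
graphs (≤ 18 vertices) for the solver check, and all hypergeometric
tables with universe ≤ 30 for the enrichment check — sizes chosen so
each property is exercised well past its edge cases while a full run
stays interactive on one core.

Tie-breaking is by ascending sample ID wherever an order is needed;
quartile positions are clamped rather than special-cased for small
partitions; probabilities at exactly the boundary belong to the positive
side, and at exactly `sup`/`inf` are selected (inclusive comparisons
throughout). Fisher p-values are floored at the smallest positive double
before the log. Precision is reported as absent (not 0) when nothing is
predicted positive, and ROC-AUC as absent when the truth is
single-class.

## Known limitations

* Self-training confirmation bias: a wrong early pseudo-label is never
  revisited; on hard data errors can compound. The threshold mitigates
  but does not eliminate this.
* The certainty strategy's batch size is cut-off-driven and can be
  large in early iterations on easy data (a quarter of the negative
  side per pass), which makes the first batch dominate the training
  set's provenance mix.
* Residual-pool metrics are biased against the certainty strategy (see
  above).
* Only binary classification is supported.
* The correlation filter is pairwise; higher-order multicollinearity is
  out of scope.
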