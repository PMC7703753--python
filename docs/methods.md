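# Methods

## Pipeline model

A pipeline is an expression tree. Leaves are copies of the full dataset;
internal nodes apply one operator each (fit on the training data flowing
through them, then applied to any data); combine nodes concatenate the
columns of two or more branches without de-duplication; the root is the
single classifier. Complexity counts operator nodes including the
classifier — a bare classifier is complexity 1, and a pipeline with four
pre-processors prints complexity 5 — while combine nodes and dataset
leaves are free. Trees serialize to a stable text form
(`clf(...)<-op(...)<-...<-DATA`, `COMBINE[...;...]` for branches) and to
JSON; serialization round-trips bit-for-bit.

Fitness is the mean stratified 10-fold CV balanced accuracy paired with
complexity. Folds are derived from the sample-id-sorted order, so fitness
is invariant to row permutation. Any operator failure inside a fold —
empty selected feature set, non-convergence, invalid input such as
negative values reaching a multinomial naive Bayes — is caught and marks
the whole record invalid with a −∞ sentinel rather than raising: the
evolutionary loop must keep selecting over populations that contain
failures.

## Operator catalog

The full configuration has 11 classifiers (logistic regression, decision
tree, random forest, extra trees, Bernoulli NB, multinomial NB,
k-nearest neighbours, Gaussian NB, gradient boosting, linear SVC,
multilayer perceptron), 14 transformers/constructors (standard, min-max
and max-abs scalers; binarizer; normalizer; polynomial features; PCA;
FastICA; Nystroem; RBF sampler; zero counts; stacking estimator; few-level
one-hot encoder; feature agglomeration) and 5 selectors (variance
threshold, select percentile, select FWE, RFE, select-from-model). A
reduced configuration keeps all pre-processors but a single classifier.
Hyperparameter domains are finite lists (mutation samples from them) and
are exportable/importable as YAML so custom configurations need no code
changes.

Notable conventions:

* The binarizer and the Bernoulli-NB internal binarization use strict
  "greater than threshold"; the default threshold is 0. Consequently
  (a) multiplying any feature by a positive constant leaves threshold-0
  Bernoulli-NB predictions unchanged, and (b) standard scaling followed by
  threshold-0 Bernoulli NB is exactly mean-binarization of each feature.
  Both identities are asserted in the test suite.
* RFE and select-from-model rank features with an internal extra-trees
  classifier. The internal forest uses 20 trees: it only produces an
  importance ranking, never the final model, and the ranking is stable
  well below the 100 trees used for ensemble classifiers.
* The stacking estimator appends the internal classifier's predicted
  class and both class probabilities (3 columns for a binary problem); the
  internal classifier runs at its default hyperparameters, so the GP
  explores *which* model to stack, not its tuning.
* Ensemble classifiers use 100 trees; zero-variance columns under
  standard scaling get scale 1 instead of a division by zero; feature
  agglomeration clips its cluster count to the available column count, and
  ward linkage forces the Euclidean metric.
* Generated feature names carry the operator name plus a walk counter so
  that an operator occurring twice in one chain (legal, and observed in
  evolved pipelines) cannot collide.

## Search

Defaults mirror the study protocol: population 1000, up to 1000
generations or a 24 h wall-clock budget (checked between generations; a
timed-out run returns its archive), 10-fold CV fitness, 50-seed
representative-model selection. Crossover rate 0.1 and mutation rate 0.9
follow the public tool's documented defaults. Each generation: the single
best pipeline is copied into round(10%) of the slots and protected from
variation (this makes the elitism testable — with fixed folds the
best-so-far fitness is provably non-decreasing, and the suite asserts
it); the remaining slots are filled by 3-way/2-way-parsimony tournament
winners; crossover and mutation are then applied to the configured
fractions of the non-elite slots. Fitness ties at the tournament's
removal step discard the more complex candidate (parsimony-consistent);
a surviving complexity tie prefers the higher fitness; a full tie is
uniform random.

Open design points resolved here: CV folds are fixed for the whole run
(per-generation redraw is available but off — determinism and the
monotonicity property were judged more valuable than the variance
reduction); elitist replacement copies the single best pipeline, not the
Pareto front; tournaments compare raw mean CV balanced accuracy with
parsimony as described, not Pareto rank. Identical trees within a run are
evaluated once (pure caching; results are identical to re-evaluation
because fitness is deterministic given the fixed folds).

## Data handling

CSV/TSV tables load with per-column kind inference (≤2 distinct numeric
values in {0,1} → binary; any non-numeric value → categorical, label-
encoded to integer codes with the level set retained; else continuous),
overridable per column. Labels map to {0,1} by sorted order (logged);
samples with missing labels are dropped (logged). KNN imputation (default
k = 5, exposed in config since the source protocol names the strategy but
not k) replaces each missing entry by the mean over the k nearest
samples, with nan-Euclidean distance — squared differences over mutually
observed features, rescaled by the fraction usable — and donors restricted
to samples observing the target feature; the test suite checks it against
a brute-force exhaustive-distance oracle. The 75/25 split is stratified
(the source protocol does not say; we stratify and say so), with
validation counts rounded half-away-from-zero per class and the total
adjusted to round(0.25·n) — 925 samples give 231/694.

## Evaluation

ROC-AUC is the Mann-Whitney rank statistic (ties count ½), checked
against an exhaustive pair-counting oracle; PR-AUC is step-wise average
precision (no trapezoidal interpolation, which is optimistic).
Single-threshold metrics use hard predictions (probability 0.5 for
probabilistic classifiers). Grid search enumerates the Cartesian grid in
deterministic order, scores every point by 10-fold CV balanced accuracy
on the training split, refits the winner (ties → first) on the full
training split and reports both splits; an optional fixed pre-processor
chain (e.g. standard scaler + RFE) is prepended to every evaluated
pipeline, so a composed baseline prints complexity chain-length + 1.

Head ablation removes operators one at a time from the input (leaf) end —
the deepest node first — refitting after each removal down to the bare
classifier, giving the complexity column k, k−1, …, 1.

Permutation feature importance permutes one column at a time with a seed
derived from (seed, feature, repeat), re-scores the *already fitted*
pipeline and reports the mean decrease in balanced accuracy over repeats
(default 100). Constant columns and columns the model never consults
score exactly 0. The split to permute is configurable
(`pfi_split ∈ {validation, train, all}`); the default is the full
dataset.

The ordered-arrangement count used for the pre-processor search-space
estimate is Σₖ p!/(p−k)! (each pre-processor at most once, order matters,
empty chain included); for p = 10 this is 9 864 101, i.e. ~9.86×10¹¹
combinations on top of a 10⁵-point grid. We note that a headline figure
sometimes quoted for this construction is ~10× larger; the package
reports the number the stated construction actually yields, verified by
exhaustive enumeration up to p = 6 and the recurrence a(p) = p·a(p−1)+1.

## Synthetic cohort generator

The generator emulates the *shape* of an angiography cohort with NMR
metabolomics: 925 samples; 73 continuous "metabolic" features in
correlated blocks (within-block ρ = 0.6, block size 5), half of them
exponentiated to a positive right-skewed scale; 27 mixed binary/continuous
"clinical" features; a 3-level latent severity (none / non-obstructive /
obstructive) with default proportions (0.20, 0.20, 0.60) — the cohort is
disease-majority, consistent with the high precision at moderate recall
reported for such referral populations — binarized as P1 (any disease vs
none) and P2 (obstructive vs rest); 5% MCAR missingness on the metabolic
block only. Informative metabolic features carry a mean shift of
effect_size·severity; informative clinical features are Bernoulli with a
severity-dependent rate (linear in the logit). An optional XOR pair adds
w·(xor−½) (default w = 8) to the severity logits — centred so the
marginal class balance stays near the configured proportions; with the
XOR weight active the realized class counts necessarily deviate from the
proportions, so the exact-count invariant applies with the pair off.

What the generator does **not** emulate: real NMR covariance structure,
units, feature names, non-random missingness, or label noise beyond the
severity model. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal, not clinical performance
on any real cohort.

A deliberate observation the XOR benchmark exploits: a greedy decision
tree cannot find a pure XOR in the presence of noise features (neither
XOR column has marginal impurity gain), and univariate selectors actively
discard the pair. Only a feature *constructor* — polynomial expansion,
kernel approximation, stacking — makes the signal accessible, which is
precisely the argument for searching over pipeline structure rather than
classifiers alone. With no noise columns a shallow tree does solve XOR,
and the generator test asserts that contrast (logistic regression ≤ 0.55,
depth-≥2 tree ≥ 0.9 on the bare pair at n = 1000).

## Problem sizes for the bundled experiments

The bundled benchmarks are scaled to minutes on one CPU while preserving
every qualitative condition:

* XOR search effectiveness: n = 400 (2 binary XOR features + 8 Gaussian
  noise), reduced decision-tree configuration, population 20, 6
  generations, max 5 operators, 10-fold CV, 20 seeds; a seed is a win when
  the evolved pipeline beats the grid-searched logistic-regression
  baseline's CV balanced accuracy by ≥ 0.2. The reduced configuration is
  used because the full configuration's 100-tree ensembles and MLP
  dominate runtime without changing the claim under test; the observed
  margin (median ≈ 0.5) is far above the threshold.
* GP invariant runs: population 16, 20 generations, 5-fold CV on a
  100-sample dataset; the Pareto archive is compared against a brute-force
  non-domination filter over every evaluated pipeline.
* PFI recovery: default-shaped cohort (925 × 100), effect size 1.0,
  standard-scaled logistic regression on the training split, 30 permutation
  repeats, 10 seeds; recovery = fraction of planted informative features in
  the PFI top-10.
* Protocol-shape experiment: 160-sample cohort (12 metabolic + 6 clinical
  features), full 7-model roster per profile, population 10, 2 generations,
  1 seed, 5-fold CV.

## Known limitations

* The stacking estimator does not tune its internal classifier's
  hyperparameters.
* Combine nodes concatenate without de-duplicating columns.
* No caching of partial pipeline results across different trees; only
  identical whole trees share an evaluation within a run.
* Multi-class labels, regression targets and in-pipeline imputation are
  out of scope (imputation happens once, before the search).
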