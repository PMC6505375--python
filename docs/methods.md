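# Methods

## Problem setting and data model

The unit of observation is a (child, rater) pair: a rater answers 31
multiple-choice behavioral questions about one child's video. Answers are
encoded as ordinal integers in the order the vocabulary lists the choices
(choices are severity-ordered), with a per-question sentinel code
(`max code + 1`) for "unratable/missing". The sentinel is kept as its own
category rather than imputed: tree models can route on it, and an
"unratable" judgment is itself informative. Each child carries a clinical
diagnosis in {TD, SLC, ASD} and optionally a site tag.

Cross-validation folds partition *children* (never rows) and are stratified
on the three-way diagnosis: children are shuffled within class and dealt
round-robin into folds with a pointer that carries across classes, so total
fold sizes differ by at most one and each fold's class mix is within one
child of proportional. Plain random splitting would satisfy the method, but
at cohort sizes near 150 the per-fold class mix is unstable without
stratification.

## Rater-adaptive ensemble

One random forest per rater (default 500 trees, unlimited depth, fixed
seed; an optional seeded random search over depth/leaf-size/feature-rate is
available behind `tune=True`). The accuracy delta z_j is measured on a
rater-specific stratified held-out split (25% of that rater's children,
fixed seed). The baseline is the plurality over all rater models' predicted
labels on that same split, with ties broken by training-label prevalence and
then fixed class order; a constant majority-class baseline is available via
`baseline="majority_class"`. When all raters cover all children the
validation split is shared, so z_j orders raters by model accuracy. After
z is measured, each rater model is refit on all of that rater's children so
the final predictors use the full training fold.

Weights are softmax(z) at temperature 1, with z in accuracy-fraction units
(a 0–1 scale); temperature is exposed for sensitivity analysis. Because
accuracy deltas are small numbers, weights are intentionally mild —
the scheme reorders raters rather than silencing them. A child not covered
by some rater is predicted by renormalizing the weights over the covering
raters; a child covered by no weighted rater is an error.

## Stacked screening

Layer 1: TD (0) vs atypical = {ASD, SLC} (1). Layer 2: ASD (1) vs other (0).
The default decision threshold is 0.5 on the ensemble probability and is
configurable. At evaluation time layer 2 trains on the truly atypical
training children but is scored on the *predicted*-atypical test children;
gated TD false positives count as layer-2 negatives. This mirrors deployment
(layer 2 never sees ground truth at test time) and inflates the variance of
layer-2 specificity on small gated sets, which is reported honestly: a fold
whose gated set is single-class yields undefined (NaN) layer-2 metrics,
excluded from the mean with a warning rather than imputed.

Metrics per fold: sensitivity TP/(TP+FN), specificity TN/(TN+FP), UAR their
mean, accuracy, and AUC via the rank statistic with tie correction. Reported
SD is the sample SD (ddof=1) over retained folds.

## Shapley attribution

Attribution is interventional: for sample x and background row z the
coalition value is v(S) = f(x_S, z_{S̄}), averaged over a reference set. For
a decision tree each leaf's indicator factorizes over the features on its
path, so per (x, z) pair the leaf contributes a unanimity-style game — v(S)
is the leaf value iff S contains every path feature satisfied only by x and
none satisfied only by z (and the leaf is dead for the pair if any feature
is violated by both). That game has the closed-form Shapley solution
(u−1)! d!/(u+d)! per "x-only" feature and −u!(d−1)!/(u+d)! per "z-only"
feature. Summing over leaves, trees, and the reference set gives *exact*
interventional Shapley values in time polynomial in the number of leaves;
the brute-force 2^p subset-enumeration oracle is retained for testing
(p ≤ 12) and a seeded permutation-sampling fallback covers non-tree models.

The base value is the mean predicted target-class probability over the
reference set; by construction base + Σ_k Φ_k equals the prediction exactly
(residuals observed ~1e−16). The reference set defaults to the model's
training matrix (avoiding test leakage) and can be subsampled (seeded) to
bound runtime. Ensemble attributions are the rater-weight combination of
per-model attributions, which preserves local accuracy by linearity. Global
importance is the sum over videos of |Φ_k|, ties broken by feature order.

## Cross-site elastic net

Per-child features for this analysis are consensus answer vectors: plurality
over raters per question, ties to the lowest code, sentinel only if all
raters marked the question unratable. The model minimizes

    mean weighted log-loss + α·(ρ‖β‖₁ + (1−ρ)·½‖β‖₂²),

intercept unpenalized, with balanced class weights n/(2·n_c) (per-class
weight sums are equal). The fit is delegated to scikit-learn's saga solver
with C = 1/(W·α), W the total sample weight; α = 0 uses an unpenalized
lbfgs fit. Because saga's step size shrinks with the penalty strength, the
unpenalized intercept can stall at extreme α, so after every fit the
intercept is polished by an exact 1-D Newton solve at fixed β — a strict
(weak) improvement of the objective that recovers the closed-form weighted
log-odds in the total-shrinkage limit. Non-convergence raises a warning with
the iteration count, never an error.

Grid search defaults: α ∈ {1, 0.1, 0.01, 0.001}, ρ ∈ {0.1, 0.3, 0.5, 0.7,
0.9}, selected by mean 3-fold CV AUC with ties toward larger α then larger
ρ (prefer the more regularized, sparser model among equals). Selection
frequency counts folds with |β_k| > 1e−8, the numerical-zero threshold under
the solver tolerance. Transfer evaluation: stratified 80/20 split of the
train site, grid search on the 80%, refit, then score the 20% held-out and
the full other site.

## Synthetic-data generator

The generator emulates the statistical structure the method assumes, not
any real cohort. Each child draws a latent "true" answer per question from
a class-conditional archetype distribution; each rater reports the latent
answer with per-question reliability r, otherwise a uniformly random wrong
code, and emits the missing sentinel with a per-question missingness
probability. Rater expertise is therefore feature-specific by construction —
the premise the weighting scheme exploits.

Default study conditions:

- Cohort mix 55/50/54 ASD/SLC/TD (rescaled proportionally for other sizes).
- Archetypes over 4 severity codes, p(code) ∝ exp(−|code − μ|/0.7), with
  class mean severities: TD 0.4 everywhere; ASD 2.3 on ten core
  social-communication/repetitive items and 1.5 on six language items;
  SLC 2.3 on language and 0.9 on core items; all classes 0.5 on the
  remaining 15 items (class-uninformative by design, which makes the
  signal-destroying site-shift limit exact).
- Three raters: R1 r = 0.95 everywhere; R2 complementary — r = 0.35 on the
  core items, 0.75 elsewhere; R3 r = 0.40 everywhere; missingness 0.02.
- Site shifts blend archetypes toward uniform on a chosen question subset;
  magnitude 1 removes all class signal on those questions at site B.

What the generator does **not** emulate: rater bias toward specific wrong
codes (errors are uniform), correlation between questions given class
(answers are conditionally independent), rater drift over time, missingness
correlated with severity, and demographic structure. Passing tests therefore
demonstrate the algebraic and statistical properties of the method — weight
recovery, gating behavior, attribution exactness, penalty limits — under the
assumed noise model, not clinical performance on real videos.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte-Carlo tolerances
meaningful while keeping the suite quick: weight recovery uses 300 children
x 30 seeds with 200-tree forests; the zero-signal stacked check 300 children
x 10 seeds at 100 trees; transfer checks ~400 children per site x 10 seeds
with a 2x2 hyperparameter subgrid (the full 4x5 default grid is unnecessary
for exchangeability/null limits). The acceptance script reports stacked CV
metrics at the 159-child default cohort with 200-tree forests.

Tolerances: probability vectors validated to 1e−9; softmax normalization
1e−9; ensemble linearity and weighted-sum identities 1e−12; Shapley local
accuracy 1e−6 (observed ~1e−16); elastic-net α = 0 equivalence 1e−4 against
an independently converged unpenalized fit; objective recomputation 1e−10.
Ties: majority vote → prevalence then fixed class order; consensus answers →
lowest code; importance ranking → feature order; grid selection → larger α
then larger ρ.

## Known limitations

- The exact tree attribution is O(leaves × samples × reference × path
  width); for large forests use `max_reference` subsampling (the estimate
  remains exact for the subsampled background distribution).
- Weight separation is mild because softmax on accuracy fractions is nearly
  linear around 0; with many raters of similar skill the ensemble approaches
  a uniform average. The temperature parameter sharpens this if desired.
- `RaterEnsembleClassifier` consumes grouped annotation tables, not flat
  matrices, so it does not compose with sklearn pipelines;
  `ElasticNetLogistic` does.
- With very small cohorts the rater-specific 25% validation split can be too
  small to rank raters reliably; z estimates are then noisy and weights
  drift toward uniform (a conservative failure mode).
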