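# Methods

## Data model

A dataset is a samples × features table with a per-feature kind tag — RNA and
CNV (continuous), MUT and FP (binary 0/1) — plus a strictly positive response
vector (IC50). Missingness is an explicit boolean mask; on disk it is an empty
cell or `NA`, internally the value is NaN wherever the mask is set and never a
magic number. Feature kinds are assigned from id prefixes
(`rna_`/`cnv_`/`mut_`/`fp_`), overridable with a prefix→kind map, because
heterogeneous sources rarely share a schema. Sample alignment between a table
and a response is an inner join on sample id, insensitive to row order.

Label transforms: `none` (the per-drug path), `log`, and `log1p` (default for
the combined multi-drug path). `log(IC50)` is ≤ 0 whenever IC50 ≤ 1, which
violates the gamma family's support; `log1p` keeps the stacked labels positive
while still compressing the right tail, so it is the default wherever a
transformed response feeds the gamma head. Raw `log` remains available for the
point-only ANN head.

## Layer 1 — autoencoder contribution screen

One single-hidden-layer autoencoder per continuous kind (RNA and CNV are
screened independently; MUT and FP bypass the layer). Columns are standardized
to zero mean / unit variance, the hidden layer uses tanh, the output layer is
linear, and training is full-batch Adam (lr 0.01, 200 epochs) on mean squared
reconstruction error, seeded. Hidden width defaults to `min(64, G//4)`, at
least 1 and strictly less than G so the code rejects non-compressive settings.

Importance is read off the weights by propagating normalized absolute
connection weights (the Gedeon scheme): input→hidden shares
`P_ik = |W_ik|/Σ_i|W_ik|`, hidden→output shares analogously, input→output
contributions `Q = P_in P_out`, and total contribution
`q_i = Σ_j Q_ij/Σ_{i*}Q_{i*j}`. Absolute values are used because signed
weights make the shares non-monotone in influence and can zero a denominator;
a hidden unit with all-zero incoming weights contributes nothing and its
column is left zero rather than renormalized (warning logged). Two identities
are asserted: every share column sums to 1, and `Σ_i q_i = G` to 1e−8.

The ranking cut keeps `ceil(0.5·G)` features from the **top** of the
descending-q ranking (fraction and direction configurable; a screen should
retain influential inputs), ties broken by original column order. Among the
survivors, features with |Pearson r| > 0.8 (strict) are grouped into connected
components and each component keeps its highest-q member (ties → lowest
column index). Constant features have undefined correlations and survive as
singletons with a warning.

A property worth knowing: because contribution credit is split among
near-duplicates, features inside large exchangeable correlated blocks score
*lower* than isolated ones. The screen enriches for features that carry
signal in small correlated groups against a background of isolated noise —
the co-expression-module structure the test suite constructs — and should not
be expected to rank the members of one homogeneous block.

## Layer 2 — mutual information and mRMR

Eq.-level choice: the mutual-information integral is realized as plug-in
discrete MI over **equal-frequency bins** (default 10, reduced to 5 when
n < 100; binary variables keep their two levels), in nats. The estimator is
deterministic and exactly reproducible, which is what makes the greedy-oracle
tests possible; kernel/k-NN estimators are deliberately out of scope.

Greedy mRMR: the first pick maximizes relevance `I(Y, X_i)` (the redundancy
term is defined as 0 while the selected set is empty, since the score divides
by |S|); every later step maximizes relevance minus mean redundancy against
the selected set. Each pairwise MI is computed once and cached as a running
redundancy sum, ties break to the lowest original column index, and the
selection order is recorded. Missing data are handled pairwise-complete: each
MI uses the rows where both variables are observed (bins are computed
marginally per feature).

## Layer 3 — second-order boosted trees with native missing handling

Written from scratch (no boosting library in the core path) so split
decisions are auditable against brute-force enumeration. Loss is squared
error, so gradients are `g_i = F(x_i) − y_i` and hessians 1; each round grows
one tree depth-first (default depth 4) by exact greedy search over all
features and thresholds (midpoints between consecutive distinct present
values). For every candidate split the missing-value samples are assigned to
the left and to the right in turn and the better side is stored as the node's
default direction (ties go left) — merged feature blocks route their
missingness through the trees without imputation. Split gain is the
regularized objective reduction with optimal leaf weights `ω* = −G/(H+λ)`;
splits are accepted only when gain > 0. Defaults: 50 rounds, λ = 1, γ = 0,
shrinkage 0.3 — ordinary boosted-tree practice at desk scale; the training
loss sequence is asserted non-increasing.

Feature importance is the total recorded split gain; the selection rule keeps
positive-gain features, at most 40 (the cap operationalizes "below 40"
without a stated rule). Tie-breaks everywhere: lowest feature index, then
lowest threshold, then missing-left.

On the raw response scale the gamma distribution's heavy right tail dominates
squared error, and *no* squared-loss booster (verified against xgboost under
matched settings) reliably ranks all weak informative features above noise;
recovery tests therefore run on the log response, which is also the combined
path's label scale.

## GLM head

Families: exponential, gamma, inverse Gaussian — the three positive-support
exponential families; link log by default (guarantees μ > 0), canonical
inverse available. Coefficients come from IRLS (statsmodels performs the
weighted least-squares iterations) warm-started at the least-squares fit of
the link-transformed response. Near-saturated designs (the per-drug path can
fit ~40 features to ~50 cell lines) can drive plain Fisher scoring into a
period-2 limit cycle or an infeasible step; a damped IRLS fallback with step
halving on the deviance restores monotone convergence, and non-convergence is
flagged on the fit, never silent. Convergence is judged on relative deviance
change (tol 1e−8; the pipeline allows up to 2000 iterations because the
saturated fits genuinely need several hundred).

Gamma shape k is estimated by profile maximum likelihood given μ̂ — the score
`n(ln k + 1 − ψ(k)) + Σ(ln y_i − ln μ_i − y_i/μ_i)` is strictly decreasing in
k and is bracketed and solved exactly — rather than by moment/Pearson
methods, so log-likelihoods and AICs are coherent across families: the
exponential family is the gamma family with k fixed at 1 and shares the same
β̂ (the shape factors out of the IRLS estimating equations), and the AIC
parameter count includes the shape only where it is estimated. The inverse
Gaussian dispersion is its closed-form MLE.

Prediction intervals are **plug-in central quantile intervals** of the fitted
response distribution at the predicted mean (gamma: `Q(α/2; k̂, μ̂/k̂)` to
`Q(1−α/2; k̂, μ̂/k̂)`). Parameter-estimation uncertainty is not propagated;
this is the documented contract, and the coverage simulations quantify what
it costs (nothing detectable at n = 500 under a correctly specified model).
Missing feature values at this stage are median-imputed per column — a GLM
cannot route missingness the way the trees do — and the medians are stored in
the fit for reuse at predict time.

## ANN head

A plain numpy feed-forward regressor matching the architecture contract:
four hidden layers (1000/800/500/100 default; tests use scaled widths), tanh
activation with inverted dropout on hidden layers during training, RMSE as
the reported loss. Training is seeded mini-batch gradient descent with
momentum (0.9); the gradient step uses the MSE gradient, a monotone transform
of RMSE with the same minimizer. Inputs and targets are standardized
internally. Dropout is disabled at inference, so prediction is deterministic.
This head emits point predictions only — intervals are the GLM's contract.
Dropout rate (0.1), epochs (200), batch size (32) and learning rate (0.01)
are package choices; no external deep-learning runtime is used.

## Evaluation and recommendation

Ten-fold cross-validation partitions samples into seeded near-equal folds and
computes RMSE, R² = 1 − SS_res/SS_tot and PICP on the **pooled** out-of-fold
predictions (not the mean of per-fold metrics). By default every selection
layer is refit inside each training fold, so selection never sees held-out
samples; a global-selection switch (select once, cross-validate the head)
exists for comparability with select-then-validate workflows and logs a
leakage warning. On pure-noise data the leakage-free mode keeps pooled R²
near zero — the guard the tests assert.

Variance homogeneity between two response samples uses Levene with median
centering (Brown–Forsythe; robust to the skewed IC50 scale) by default,
Bartlett optionally; a gamma-variant compares two fitted predictive
distributions (Var = μ²/k) via seeded Monte-Carlo draws followed by Levene.

The recommendation rule encodes interval-aware potency: rank candidate drugs
by point prediction ascending (lower predicted IC50 = more potent); when the
leading candidates' points are within a 20% relative margin — the
configurable operationalization of "comparable" — prefer the shortest
interval; attach pairwise variance tests when predictive parameters are
available; and flag any candidate whose lower *and* upper bounds exceed every
competitor's as the aggressive/high-risk option. The output is a ranked
hypothesis with statistics attached, not clinical advice.

## Synthetic data

The generator emulates the statistical shape of the real inputs, not their
marginals: RNA/CNV are standard-normal features with pairwise correlation
`block_rho` inside consecutive blocks (default size 5), MUT/FP are Bernoulli
bits (rates 0.15 / 0.3), and the response is
`y_i ~ Gamma(k, μ_i/k)` with `μ_i = exp(β₀ + Σ β_j x_ij)` over a small
informative set drawn from the continuous columns. Effect sizes default to
|β| ∈ [0.3, 1.0] with random signs — detectable but not trivial at the tens
of cell lines per drug the method targets, recoverable at larger n — and an
explicit coefficient map can override the draw. `inject_missing` masks a
seeded Bernoulli subset of cells restricted to named kinds, mimicking
block-merge missingness. All randomness flows from one integer seed through a
named generator; no global state.

What passing tests on this generator do **not** show: behavior under real
CCLE/GDSC marginal distributions, batch effects, non-log-linear
dose–response, or real drug chemistry. Headline real-data figures from
pharmacogenomic studies are out of reach without those datasets; the
synthetic criteria check calibration and mechanics, not biology.

## Problem sizes and numerical choices

The default test/benchmark sizes are desk-scale by design: interval
calibration at n_train = n_test = 500 (shape 5, five ±0.5 coefficients,
intercept 1); the first-layer cut on a 100 × 200 block; mRMR to 500 features
from 60 × 2000; the full per-drug run on 50 × 2000 with 10 informative
features. A default per-drug run at that size completes in well under a
minute on one CPU.

Degenerate inputs and tie rules are all pinned: empty selected set → zero
redundancy; fewer distinct values than bins → bin count reduced with a
warning; constant features → dedup singletons / dropped before model fitting
(zero variance); all-missing feature at a node → skipped; both-zero-variance
variance test → statistic 0, p = 1 with warning; rank-deficient GLM design →
error, not silent pseudo-inverse.

## Known limitations

- Interval coverage is plug-in: at very small n the intervals are mildly
  anti-conservative because β̂ and k̂ uncertainty is ignored.
- The contribution screen is a reconstruction-based filter; it is blind to
  the response and can discard weakly expressed but predictive features.
- mRMR's histogram MI loses power for very small samples (bins collapse).
- The boosted selection on raw heavy-tailed responses favors features that
  explain the tail; transform the labels when ranking fidelity matters.
- The combined path's pre-selection feature space (union of per-drug
  selections plus fingerprint bits) is one defensible construction of a
  merged multi-drug design, configurable but not canonical.
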