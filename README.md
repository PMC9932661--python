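# drpred

Drug-response prediction for cancer cell lines: a three-layer feature-selection
cascade feeding a **gamma-distribution GLM** that produces point predictions
*and* prediction intervals for IC50, plus an ANN alternative head, ten-fold
cross-validated evaluation (R², RMSE, PICP) and an interval-based
drug-recommendation rule.

## The problem and the method

Pharmacogenomic screens (CCLE/GDSC-style) pair tens of thousands of genomic
features — continuous expression (RNA) and copy-number (CNV) values, binary
mutation indicators (MUT), optionally 256-bit Morgan fingerprint blocks (FP)
for the drug — with a strictly positive response, the half-maximal inhibitory
concentration IC50, for a few dozen cell lines per drug. Point regression alone
hides how *uncertain* each prediction is; modeling the full response
distribution yields intervals whose length can rank treatment options.

The cascade reduces ~10⁴ features to a GLM-sized design in three stages:

1. **Contribution screen.** One single-hidden-layer tanh autoencoder per
   continuous kind; Gedeon connection-weight contributions
   `q_i = Σ_j Q_ij / Σ_{i*} Q_{i*j}` with `Q = P_in · P_out`,
   `P_ik = |W_ik| / Σ_{i*} |W_{i*k}|`; keep the top 50% by `q`, collapse
   features with |Pearson r| > 0.8 to one representative, merge MUT back
   untouched.
2. **mRMR.** Greedy minimum-redundancy–maximum-relevance on plug-in mutual
   information over equal-frequency bins:
   `f_mRMR(X_i) = I(Y, X_i) − (1/|S|) Σ_{X_s∈S} I(X_s, X_i)`; stops at
   m = 500 features.
3. **Boosted-tree selection.** From-scratch second-order gradient boosting:
   split gain `½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)] − γ`
   with learned default directions for missing values; keep features with
   positive total gain, capped at 40.

The head is a GLM with `η = Xβ`, log link `μ = exp(η)`, and the response
family chosen by AIC among exponential, gamma `f(y) = y^{k−1}e^{−y/θ}/(Γ(k)θ^k)`
and inverse Gaussian. Gamma shape `k` is estimated by profile maximum
likelihood. Prediction intervals are plug-in central gamma quantile intervals
`[Q(α/2; k̂, μ̂/k̂), Q(1−α/2; k̂, μ̂/k̂)]`, whose quality is scored by PICP
(fraction of held-out responses inside their intervals).

## Worked example

```python
from drpred import PipelineConfig, simulate_dataset
from drpred.pipeline import run_per_drug

beta = {"rna_g0": 0.8, "rna_g10": -0.7, "rna_g20": 0.6,
        "cnv_g0": 0.7, "cnv_g10": -0.6}
table, y, truth = simulate_dataset(
    200, n_rna=200, n_cnv=100, n_mut=20, shape_k=10.0, seed=0, beta=beta
)
config = PipelineConfig(mrmr_m=100, layer3_cap=20, cv_folds=10, seed=0)
run = run_per_drug(table, y, config, cross_validate=True)
print("dimension chain:", " -> ".join(map(str, run.dimension_chain())))
print("selected family:", run.model.glm_fit.family)
print("informative recovered:",
      sorted(set(run.model.feature_ids) & set(truth.informative_ids)))
cv = run.cv
print(f"10-fold CV: R2={cv.r2:.3f}  RMSE={cv.rmse:.3f}  PICP={cv.picp:.3f}")
```

prints

```
dimension chain: 320 -> 170 -> 100 -> 20
selected family: gamma
informative recovered: ['cnv_g0', 'cnv_g10', 'rna_g0', 'rna_g10']
10-fold CV: R2=0.511  RMSE=15.867  PICP=0.935
```

Reading the numbers: the cascade shrinks 320 features to 20 (50% contribution
cut on each continuous block, then mRMR to 100, then the boosted-tree cap),
recovers four of the five truly informative features, AIC picks the gamma
family, and the pooled out-of-fold 95% intervals cover 93.5% of the held-out
IC50 values — close to nominal despite every selection layer being refit
inside each fold. R² on the raw IC50 scale is dominated by the distribution's
heavy right tail; the interval coverage, not R², is the calibration check.

A CLI mirrors the library (`drpred simulate | screen | select-mrmr |
select-boost | fit-glm | fit-ann | predict | evaluate | recommend |
run-per-drug | run-combined`); every run writes a JSON manifest with the
config, seed and per-stage dimensions.

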