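# pbsis

Two-stage feature screening and variable selection for high-dimensional
generalized linear models with a **binary response**, built around the
point-biserial correlation (PB-SIS).

## The problem

In case/control studies with far more predictors than samples (gene
expression panels, biomarker screens; p in the hundreds to tens of
thousands, n ~ 100-1000), fitting a penalized model to all predictors at
once is slow and unstable. The two-stage strategy first **screens**:
rank every predictor by a cheap marginal association with the outcome and
keep only the top `d`. If the screen has the *sure independence* property,
the true predictors survive this cut with probability approaching one. A
**penalized logistic regression** (lasso, SCAD or MCP) then selects the
final sparse model from the `d` survivors.

For a binary outcome Y in {0, 1} and a continuous predictor X, the natural
marginal utility is the point-biserial correlation — the Pearson
correlation of X with the 0/1 coding,

    r_pb = sum_i (x_i - x̄)(y_i - ȳ) / sqrt( sum_i (x_i - x̄)² · sum_i (y_i - ȳ)² ),

whose population value under the two-class normal mixture
(X | Y=k ~ N(μ_k, σ²), P(Y=1) = p₁) is

    ρ = Δ sqrt(p₁p₀) / sqrt(1 + p₁p₀Δ²),    Δ = (μ₁ − μ₀)/σ.

Stage 1 keeps the `d = ⌊n / ln n⌋` predictors with the largest |r_pb|
(M̂_d). Stage 2 fits a penalized logistic regression on M̂_d by
IRLS + coordinate descent along a decreasing λ path, with λ tuned by
stratified 10-fold cross-validation (deviance loss, one-standard-error
rule) or by AIC / BIC / EBIC.

The package also implements the two standard comparator screens — MMLE
(magnitude of the one-predictor logistic slope) and the Kolmogorov filter
(two-sample KS statistic between class-conditional ECDFs) — plus the full
Monte-Carlo study machinery (six benchmark generating models, AR(1)
designs, P1/P2/MMMS/RSD metrics) so the method's operating characteristics
can be reproduced end to end.

## Worked example

```python
import numpy as np
from pbsis import ModelSpec, generate_dataset, two_stage_pbsis, default_threshold

# benchmark model 1: logit, beta0=1, beta=(2,3) on x1 and x3, AR(1) rho=0
spec = ModelSpec.table_model(1, n=100, p=200, rho=0.0)
data, _ = generate_dataset(spec, seed_key=(42, 0))

d = default_threshold(data.n)          # floor(100 / ln 100) = 21
screen, fit, support = two_stage_pbsis(
    data, d, penalty_family="lasso", criterion="cv", folds=10, seed=42,
)
print("screened top-5:", [data.feature_names[j] for j in screen.selected[:5]])
print("final support :", [data.feature_names[j] for j in support])
print(f"lambda = {fit.penalty.lam:.4f}, deviance = {fit.deviance:.1f}, df = {fit.df}")
```

Output:

```
screened top-5: ['x3', 'x1', 'x50', 'x18', 'x5']
final support : ['x1', 'x3', 'x18', 'x40', 'x50']
lambda = 0.0709, deviance = 72.9, df = 5
```

Both true predictors (x1, x3) head the screening ranking and survive into
the final support; the CV-tuned lasso keeps a handful of spurious
predictors, which is its documented behavior (the MCP penalty yields
sparser finals at a small cost in containment probability).

The same workflow is available from the shell:

```bash
pbsis screen --input cohort.csv --response status --d 21 --out ranks.csv
pbsis fit --input cohort.csv --response status --penalty scad --tune ebic --out fit.json
pbsis simulate --config study.yaml --out results.csv
```

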