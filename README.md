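# sigcombine

Combine the predictive strength of multiple gene-set prognostic signatures
for survival prediction.

Published gene signatures for cancer outcome are built on partly different
genes, yet their risk predictions tend to agree — each captures part of the
same underlying biology. `sigcombine` implements a framework that exploits
this: instead of reusing each signature's original coefficients, it refits a
survival model per *gene set* on a common training cohort, predicts a risk
score per patient per set on an independent test cohort, and integrates the
resulting score matrix into a single, stronger dichotomous risk predictor.
It is aimed at biostatisticians and computational biologists comparing or
pooling expression-based risk signatures across cohorts and platforms.

## The model

For gene set *j* and patient covariates *x* (standardized log-expression),
a Cox proportional-hazards model

> h(t | x) = h₀(t) · exp(β_j′ x_{G_j})

is fitted by maximizing the L2-penalized partial log-likelihood
l(β) − (λ/2)‖β‖², with the penalty weight λ chosen per gene set by
maximizing the cross-validated partial likelihood
CV(λ) = Σ_f [ l(β̂₍₋f₎) − l₍₋f₎(β̂₍₋f₎) ] (leave-one-out or k-fold). A gene
set whose CV profile has no interior maximum is assigned the **null model**
(β = 0). Each fitted set assigns test patient *i* a **prognostic index**
PI_ij = β̂_j′ x_i — a log relative hazard. The R×n PI matrix is then
integrated by principal components analysis (covariance or correlation
basis); the first component's scores, dichotomized at their median, form
the **combined-PI risk predictor**. An evaluation suite (Kaplan-Meier,
logrank, uni/multivariate Cox with stratification, deviance, PVE, Harrell's
C, hazard ratios, Fisher's exact odds ratio, AIC stepwise selection,
Schoenfeld-residual proportional-hazards diagnostics) compares it against
the individual signatures and clinical covariates.

Everything is testable offline: the `simulate` module generates two-cohort
studies with planted gene-set signal, configurable censoring and
missingness, and a ground-truth record.

## Worked example

Simulate a 123-patient training / 81-patient test study with three signal
and two noise gene sets, then run the full pipeline with 10-fold CV:

```
sigcombine simulate --seed 7 --out-dir demo/data --n-train 123 --n-test 81
sigcombine run-all \
    --train-expression demo/data/train_expression.tsv \
    --train-clinical   demo/data/train_clinical.tsv \
    --test-expression  demo/data/test_expression.tsv \
    --test-clinical    demo/data/test_clinical.tsv \
    --gene-sets        demo/data/gene_sets.gmt \
    --seed 7 --cv kfold:10 --out-dir demo/run
```

`demo/run/signature_report.tsv` summarizes each gene set's transfer to the
test cohort — change in deviance ΔD (negative = predictive gain), PI
standard deviation, and the logrank p of the PI > 0 dichotomization:

```
         delta_deviance   pi_sd  logrank_p
sig16          -13.0106  0.8838     0.0478
sig26          -50.4635  1.2351     0.0000
sig54          -40.2282  1.5481     0.0001
noise70          0.2276  0.0517     0.9846
noise76          3.2094  0.1914     0.7560
```

The three signal sets transfer (ΔD strongly negative); the noise sets do
not (ΔD ≥ 0, wide logrank p). `demo/run/evaluation.tsv` compares the
PCA-combined predictor with each individual signature in univariate Cox
models:

```
   covariate                       term       p     PVE  Deviance       C      HR
 combined_pi           (overall effect)  0.0000  0.3357   33.1316  0.7337     NaN
 combined_pi  combined_pi:high (vs low)  0.0000     NaN       NaN     NaN  6.3941
 sig16                (overall effect)   0.0492  0.0466    3.8693  0.5921     NaN
```

The combined predictor dominates every single signature here: likelihood-
ratio p ≈ 9e-09, concordance C = 0.73, and a hazard ratio of 6.4 for its
high-risk group, versus p = 0.049 and C = 0.59 for the best-behaved small
signature alone. `combined_pi.tsv` carries each patient's PC1/PC2 scores
and risk call; `pi_heatmap.tsv` the 1%-quantile-trimmed PI matrix for
plotting; `manifest.json` the deterministic record of all outputs.

Each stage is also independently invokable (`map`, `impute`, `fit`,
`predict`, `combine`, `evaluate`) on the previous stage's files, and
`--swap-cohorts` reruns the analysis with training and test roles
exchanged.

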