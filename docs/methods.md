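# Methods

`sigcombine` implements a three-module framework for survival prediction
from multiple gene-set signatures: (1) per-gene-set prognostic model
construction by penalized Cox regression, (2) integration of the resulting
per-patient risk scores by dimension reduction, and (3) dichotomous risk
prediction and statistical comparison against clinical predictors. This
note records the model, its assumptions, the tunable parameters, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## Per-set model: Cox proportional hazards with an L2 penalty

For gene set *j* with genes *G_j* the hazard of patient *i* is modeled as

    h(t | x_i) = h0(t) · exp( Σ_{k ∈ G_j} β_k x_ik )

with standardized log-expression covariates x. The relative hazard between
two patients is constant over time (the proportional-hazards assumption);
the baseline hazard h0 cancels from the partial likelihood and is never
estimated — absolute survival curves are always reported via Kaplan-Meier.
Ties are handled with the Breslow approximation: tied event times share
one risk set. This is the simplest consistent convention and the synthetic
cohorts use continuous times, so ties are rare.

Because |G_j| is comparable to (or exceeds) the number of patients, β is
estimated by maximizing the penalized partial log-likelihood

    l_pen(β) = l(β) − (λ/2) ‖β‖²₂

by Newton-Raphson with step halving, converged when the penalized gradient
max-norm is ≤ 1e-6 (iteration cap 200, singular-system errors surfaced,
never silenced). As λ→0 the fit approaches ordinary Cox regression; as
λ→∞ it approaches the constant (null) estimator. Note that the absolute
value of λ under the (λ/2)Σβ² convention depends on the penalty convention
and the data scale; λ values are not comparable across conventions or
datasets, only the selected model is.

## Penalty selection: cross-validated partial likelihood

λ is chosen on a log-spaced grid (default 40 points on [1, 1e5], spanning
the order of magnitude where optima land for standardized expression data)
by maximizing the Verweij-van Houwelingen criterion

    CV(λ) = Σ_f [ l(β̂₍₋f₎) − l₍₋f₎(β̂₍₋f₎) ]

where l is the full-data partial log-likelihood and l₍₋f₎ omits fold f.
Folds are leave-one-out by default; k-fold (seeded permutation split) is
available for speed and for the swap-cohort robustness variant. A fold
whose removal leaves zero events is skipped with a warning.

**Null-model boundary rule.** If the CV argmax sits on the largest grid
λ, or the profile is monotone non-decreasing, the cross-validation
function has no maximum in the search range: the gene set is assigned the
null model (β = 0, λ = +∞ sentinel, prognostic index identically 0, ΔD =
0, PI sd = 0). An argmax at the *lower* grid end is accepted as λ_opt —
it indicates the grid should be extended downward, not that the data
support no effect; the grid is configurable precisely for this case.
Null-model rows are excluded from clustering and PCA downstream.

## Preprocessing

* **KNN imputation** (k = 10 by default): a missing cell is filled with
  the inverse-distance-weighted mean of the k nearest *genes* that are
  observed in that column. Distances are Euclidean over pairwise-complete
  columns (columns observed in both rows); whether to use all columns or
  pairwise-complete ones is genuinely open in this design — pairwise-
  complete was chosen so that a heavily missing gene still has usable
  neighbors, and the choice is isolated in one helper. Plain unweighted
  neighbor means are available behind a flag. When no neighbor is
  observed in the target column the gene's own observed mean is used
  (logged). Observed cells are never modified.
* **Standardization**: each gene row is centered and scaled to sd 1
  (n−1 denominator, documented so tests can be exact), independently
  within each cohort — training and test each use their own means/sds,
  never pooled. This is why predicted PIs on the test cohort come out
  roughly centered around zero, which the PI > 0 dichotomization rule
  implicitly relies on. Zero-variance genes are dropped and logged.

## Gene mapping

Foreign-platform identifiers are matched against the platform annotation
with a total, deterministic linker priority: platform-native clone/probe
id > UniGene > symbol > alias. Only matches from the single
highest-priority linker with ≥ 1 hit are kept. Symbol/alias matching is
case-insensitive (vendor files disagree on case); unigene/clone matching
is exact. Probes matched to the same gene are collapsed by their mean over
observed values (probe-level missingness must not poison the collapsed
row; imputation happens later). Within-set duplicate identifiers are
dropped with a log line. Post-mapping gene identity — used for the
between-set overlap table — is the set of matched probe ids.

## Prediction and per-set evaluation

The prognostic index of test patient *i* is PI_i = Σ_k β̂_k x_ik over the
model's genes present in the test matrix (log relative hazard up to a
constant). Model genes missing from the test platform are excluded with a
warning rather than zero-imputed; if fewer than 50% of the model's genes
are present, prediction is refused as meaningless. Predictive transfer is
summarized by the change in deviance ΔD = −2[l(β̂; test) − l(0; test)],
computed by plugging the training-derived β̂ into the test-cohort partial
likelihood with no refitting and no recalibration scalar — it is a pure
prediction metric, negative when the model transfers usefully. Clinical
calls dichotomize the PI at 0: strictly positive = high risk.

## Integration

* **Clustering view**: patients are clustered on 1 − Spearman correlation
  of their PI profiles across gene sets, average linkage, tree cut into
  two groups; the group with the higher observed event fraction is labeled
  high risk. A constant profile (rank correlation undefined) gets
  dissimilarity 1 to everyone, logged. Heatmap exports clamp values
  outside the [1%, 99%] quantiles.
* **PCA view**: eigendecomposition of the R×R covariance matrix of the
  non-null PI rows over patients (explicit row centering — near-zero row
  means are not relied upon). Covariance is the default basis because
  higher-variance PIs are assumed to carry more information; when a
  high-variance row correlates little with the rest it dominates
  covariance-basis PC1, and the correlation basis is the appropriate
  replacement (both are exposed; the acceptance suite reproduces this
  dominance/rescue behavior on a planted construction). Eigenvectors are
  sign-ambiguous, so PC1 is oriented to correlate non-negatively with the
  across-set mean PI (high PC1 = high predicted risk); lower components
  get a largest-entry-positive sign for determinism. PC1 scores are
  dichotomized at their median (strictly above = high risk); the median
  is stored so the cut can be reapplied to new patients.

## Evaluation suite

Unpenalized (optionally stratified) Cox fits reuse the penalized core at
λ = 0. Stratified fits sum per-stratum partial likelihoods sharing one β;
strata without events are dropped with a warning. Reported measures:

* likelihood-ratio p for the overall effect; deviance 2[l(β̂) − l(0)];
* PVE as the likelihood-ratio R², 1 − exp(−2(l1−l0)/n) with n = number of
  subjects — an R²-like proportion-of-variation measure on (0,1), chosen
  as the standard likelihood-based form; deviance and PVE rank predictors
  identically at fixed n;
* Harrell's C over usable pairs (earlier time is an observed event, times
  differ; tied predictions score 0.5) — 0.5 is no discrimination, 1 is
  perfect separation;
* hazard ratios exp(β̂) with Wald 95% CIs per contrast (two-level risk
  predictors report high-vs-low by defaulting the reference level to
  "low");
* Fisher's exact test: conditional-MLE odds ratio under the noncentral
  hypergeometric model, exact CI by test inversion, two-sided p by the
  point-probability rule (scipy's implementations, cross-checked against
  direct hypergeometric enumeration in the tests);
* proportional-hazards diagnostic: Grambsch-Therneau correlation of
  scaled Schoenfeld residuals with Kaplan-Meier-transformed time,
  per-covariate and global χ² (the field-default residual test);
* hybrid stepwise AIC: at each step every single addition and deletion is
  scored by AIC = −2l + 2·(#coefficients) and the best strictly improving
  move taken, ties broken by covariate name order, full trace retained;
  analysis-of-deviance p available between nested fits.

Monotone likelihood (perfect separation) is flagged — by a diverging
Newton step or by a fitted linear-predictor spread exceeding sd 10 — and
returns a non-converged result with NaN estimates rather than a silent
number.

## Synthetic cohorts

The generator emulates a two-cohort early-stage breast-cancer expression
study. Defaults: 123 training / 81 test patients; 250 genes; five gene
sets (three signal, two noise) with sizes echoing small published
signatures; 5% missing cells; within-set latent-factor correlation 0.3;
baseline hazard h0 = 0.01 events/month with uniform censoring on [0, 120]
months, which yields ≈ 42% observed events, typical of such cohorts.
Signal sets' latent factors load with correlation 0.5 on a single shared
risk axis, so each set partially captures one true signal — the analogue
of published signatures tracking overlapping tumor biology, and the
regime in which pooling their predictions can help. True coefficients sit
on one third of each signal set's genes at a common magnitude (0.25 per
standardized-expression unit). Event times are exponential given the
hazard, so proportional hazards holds exactly by construction and the PH
diagnostic's rejection rate calibrates at α. The truth record carries the
per-patient linear predictor and the analytic expected event fraction
conditional on the drawn expression (closed form under uniform
censoring), which the tests compare with realized rates.

Not emulated: array-specific artifacts (dye bias, print-tip effects,
spot-quality issues), non-proportional hazards, informative censoring,
non-Gaussian expression marginals, and annotation errors. Passing tests
therefore demonstrate correctness of the statistical machinery and the
integration property under the model's own assumptions, not robustness to
real-array pathology.

## Problem sizes and determinism

Simulation-based tests and the acceptance script use desk-scale problems
(cohorts of 60–123 patients, gene sets of 12–76 genes, 8–15 point λ
grids, 5–10-fold CV, 40–100 replicates) — large enough for the asserted
rates to be stable at the stated tolerances. All randomness flows through
`numpy.random.default_rng` seeds carried in the specs and configs; the
same seed reproduces every output bitwise, including the pipeline
manifest (wall-clock timestamps are opt-in and off by default, keeping
the manifest deterministic).

## Known limitations

* The Breslow tie convention differs from Efron's; with heavily tied
  times coefficient estimates would differ from Efron-based software.
* The λ grid must bracket the CV optimum; an argmax at the lower grid
  edge silently accepts the edge value (extend the grid when profiles
  look truncated).
* Exact conditional odds-ratio CIs are conservative for small tables.
* The stepwise search is greedy; with strongly collinear candidates the
  selected model depends on the name-order tie-break.
* Cross-platform mapping operates only on the supplied annotation
  snapshot; outdated or suppressed transcript records are not resolved.
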