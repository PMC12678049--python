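# Methods

This note documents the statistical procedures implemented in
`metaboaging`, the design of the synthetic-cohort generator, the defaults
and why they are set where they are, and the limits of what the bundled
experiments demonstrate.

## 1. Preprocessing

* **Metabolites** (raw concentrations ≥ 0): per-biomarker mean imputation
  on the raw scale, then `ln(x + 1)`, then z-scoring. Imputation precedes
  the transform so the imputed value stays interpretable as a
  concentration; the transform order is otherwise immaterial for the mean
  rank structure. All z-scores in the package use the sample SD
  (divisor n − 1).
* **Proteins** (normalized-expression scale): columns with a missing
  fraction *strictly greater* than 0.30 are dropped (a column missing
  exactly 30% is kept); survivors are mean-imputed and z-scored.
* **Frailty index**: the proportion of accumulated deficits among the
  *observed* items of a 49-item battery — the standard
  deficit-accumulation denominator; a fixed-49 denominator is available
  via `denominator="fixed"`. Participants missing ≥ 10 items are excluded
  (flagged, FI unset).
* **Telomere length**: natural log of the (assumed technically
  pre-adjusted) T/S ratio, then z-score.
* **Covariates**: fields with ≤ 5% missing are median- (continuous) or
  mode- (categorical) filled; above 5%, categorical fields gain an
  explicit `"missing"` level and continuous fields a binary missingness
  indicator plus median fill. Every decision is recorded in an audit.
* **Landmark filter** (sensitivity analysis): participants whose *event*
  occurred within the first year of follow-up are removed; early
  censorings are retained, since the exclusion targets incident cases.

## 2. Survival engine

`fit_cox` is a Newton–Raphson maximiser of the Cox partial likelihood with
Efron tie handling by default (Breslow available); convergence at relative
log-likelihood change < 1e-9 or gradient norm < 1e-8; runaway coefficients
(|log-HR| > 15 with a plateauing likelihood) raise a monotone-likelihood
error. Risk-set sums use suffix cumulative sums, so one iteration costs
O(n p²).

`fit_penalized_cox` delegates the L1 path to scikit-survival's Coxnet
solver with per-feature penalty factors (0 for the unpenalised covariate
block), over 100 log-spaced λ from the smallest all-zero λ down by 1e-3.
Cross-validation is stratified on the event indicator and scored by the
Verweij–van Houwelingen deviance
D_k(λ) = −2·[ℓ_full(β̂₋ₖ(λ)) − ℓ₋ₖ(β̂₋ₖ(λ))]; `lambda_1se` is the largest λ
whose mean CV deviance is within one fold-SE of the minimum. λ = 0, when
requested explicitly, is solved exactly by the Newton fitter rather than
the coordinate-descent solver.

`fit_gompertz_ph` maximises the left-truncated Gompertz PH log likelihood

ℓ = Σᵢ dᵢ(log b + γ tᵢ + xᵢᵀβ) − (e^{log b + xᵢᵀβ}/γ)(e^{γ tᵢ} − e^{γ aᵢ})

on the age timescale (aᵢ entry age, tᵢ exit age) with analytic gradients
(L-BFGS-B, γ ≥ 1e-8, start: log crude rate and γ₀ = 0.08). **Numerical
note:** with the baseline referred to age 0, (log b, γ) lie on a near
ridge (corr ≈ −0.999) and quasi-Newton steps can false-converge; the
implementation therefore centers the age scale at the mean exit age
internally and maps the covariance back by the delta method. Standard
errors come from the observed information obtained by central differences
of the analytic gradient.

`harrell_c` counts usable pairs (the earlier time has the event),
concordant when the earlier event carries the higher risk, with 1/2 for
tied risks.

## 3. Metabolic age

The clock is MA = CA + s/γ with s = xᵀβ̂ centered, where β̂ and γ come from
the Gompertz PH fit on the LASSO-selected metabolite panel (γ is taken
from the fit that includes the score covariates; an age-only γ could be
substituted through the same single entry point, `compute_metabolic_age`,
which is deliberately the only place the formula lives). MAA is the OLS
residual of MA on CA — exactly orthogonal to CA by construction — and
"accelerated" means MAA > 0. Validation computes, on a held-out split:
Harrell's C of a base covariate Cox model vs base + MA per endpoint,
the Cox HR of the accelerated indicator, linear associations of
acceleration with telomere z-score and FI, and Spearman r / MAE between MA
and CA. Train/validation splits group by simulated assessment center
(70/30 of centers, seeded), never by row.

## 4. Proteome-wide scans

Continuous phenotypes (MA, FI, telomere): per-protein OLS of the phenotype
on protein + covariates, vectorised via Frisch–Waugh residualisation
(numerically identical to the full per-protein OLS, including SEs).
Event phenotypes (death, CVD, T2D): per-protein Cox fits; a degenerate
protein is logged and skipped, never fatal to the scan. Effects are per SD
of (standardized) protein. Bonferroni correction is applied within each
phenotype over the proteins scanned (m configurable); Benjamini–Hochberg
is computed alongside for sensitivity analyses. Proteins Bonferroni-
significant in all six scans form the metabolic-aging-related set; top-k
ranking sorts by adjusted p with raw p, |effect|, then label as
tie-breaks; replication reports, among train-significant proteins, the
fraction validation-significant with the same sign and the fraction
sign-consistent regardless of significance.

## 5. Wave detection (sliding-window differential expression)

At each center c (default integers 40…70) the window is |MA − c| ≤ 1.5
years, ties included; the contrast group is MA ≥ c (the "low/high" cut at
the center is a convention the data cannot decide; it is configurable).
Windows with fewer than 30 members or a single group are skipped — sparse
MA tails otherwise produce unstable fits. Per protein, OLS of expression
on the group indicator plus covariates gives β₁ (with no covariates this
is exactly the high-minus-low mean difference); per-center Bonferroni
(or FDR) correction over proteins; the per-center count of significant
proteins is the wave curve. `detect_peaks` returns strict local maxima
(plateaus at their leftmost center; boundary centers qualify against
their single neighbour), with a minimum-count threshold (operation
default 1). **The pipeline reports peaks with min_count = 3**: under the
null, a center's expected number of falsely significant proteins is
≈ α = 0.05, so counts of 1–2 are noise; planted 10-protein waves carry
counts of 4–11 in the reference experiments. Peak protein sets are
compared with an upset-style exclusive partition whose cells sum to the
union.

## 6. Trajectories

Per-protein LOESS: local linear regression with tricube weights over the
span-fraction nearest neighbours (span 0.5, grid 40…70 step 0.5 years by
default — stable from n ≈ 60 to several thousand; nothing in the data
pins these, so they are exposed in the config), evaluated strictly inside
the observed MA range. The smoother reproduces constants and exact lines,
and matches the statsmodels `lowess` oracle to ~1e-10 on shared settings.
Curves are clustered by Ward linkage on Euclidean distance and cut to k =
3 groups; labels are renumbered by ascending cluster-mean curve value at
the grid midpoint so group indices are comparable across runs.
Mann–Kendall trend tests (tie-corrected variance, ±1 continuity
correction) are applied to the smoothed curve values on the grid; a
raw-data mode exists.

## 7. Enrichment

One-sided over-representation only: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), exact tail, Bonferroni over the sets tested.
The background universe defaults to all assayed proteins; gene sets are
restricted to the universe before counting. GMT files are read via
gseapy.

## 8. Synthetic-cohort generator

The generator emulates the structure the analysis assumes, with every
draw taken from named substreams of one root seed (bit-reproducible, and
stable per block under unrelated config changes).

* **Ages** uniform on [40, 70]; a latent aging rate a ~ N(0, 1) shared
  across blocks gives the cross-phenotype correlation that a six-way
  intersection requires.
* **Metabolites**: latent z = w_age·age_std + w_lat·a + noise with unit
  marginal variance; w_age = 0.3 and w_lat = 0.3 (sign-matched to the
  causal effect) for the 18 causal metabolites, background loadings
  0.3/0.075 otherwise. Raw scale: x = expm1(μ + 0.4 z), so the pipeline's
  ln(x+1) + z-score recovers z exactly.
* **Mortality**: Gompertz with log b₀ = ln 1e-5, γ = 0.09/yr on the age
  timescale, score s = zᵀβ with planted |β| ∈ [0.15, 0.30] (every fourth
  negative); event ages by closed-form inversion of the cumulative hazard
  conditional on entry, administrative censoring at 13.5 years. CVD and
  T2D are independent Gompertz processes (log b₀ = ln 4e-5 / ln 1.2e-5,
  score effects 0.4/0.5) — endpoints are analysed separately, so
  semi-competing risks are out of scope.
* **Proteins**: the first 60 are "aging proteins" with a latent loading
  of 0.35, one of three planted trajectory shapes (linear slope 0.03/yr,
  logistic amplitude 1.2 centered at MA 51, linear slope 0.06/yr) and
  noise SD 0.8; waves add effect·sigmoid((MA_true − c)/0.5) steps at
  centers 44/51/63 to 10 proteins each; remaining proteins are noise.
* **Frailty/telomere/flags**: 49 Bernoulli deficit items loaded on age
  and the latent rate; telomere loaded negatively on both; health flags
  drawn so that a configurable fraction (default 0.6) of the cohort is
  flag-free ("healthy subset").
* **Missingness** is completely at random (mean/median imputation in the
  pipeline presumes MCAR tolerance), with a 1% sub-population given ≥ 10
  missing frailty items so the exclusion rule is exercised.

**Scale and effect sizes.** Defaults are n = 5,000 (healthy subset
≈ 3,000 for the wave analysis), 168 metabolites, 200 proteins — sizes at
which every bundled experiment runs in seconds to minutes. Planted effect
sizes are deliberately larger than what population cohorts show (the
score SD ≈ 1.9 log-hazard units implies an MA–age MAE of ~15 years and a
~18% 13.5-year death rate, against a few percent and an MAE of ~3.5 years
in large biobanks): at desk-scale n, realistic effects would leave the
recovery experiments powerless, so the generator trades realism of effect
magnitude for testability at reduced n. Consequences worth keeping in
mind: passing recovery tests demonstrate correctness of the estimators
and the planted-structure logic, not attainable effect sizes, C-indices
or MAEs in real cohorts; and the MCAR missingness and Gaussian-on-
transformed-scale metabolite law are modelling conveniences, not claims
about any real assay.

## 9. Reference experiments (what the acceptance battery runs)

* Cox vs an exhaustive partial-likelihood grid (step 1e-4) on 50 tiny
  datasets; Gompertz vs a refined 2-D likelihood grid on a toy.
* Gompertz parameter recovery at n = 20,000 over 10 seeds with
  β = (0.3, −0.2): each estimate within 3 reported SE; the 10-seed mean
  bias is tested in one-sided equivalence form — observed |mean bias|
  minus twice its own Monte-Carlo SE must lie below 5% of |truth| —
  because with ~1,100 deaths per cohort the Monte-Carlo SE of a 10-seed
  mean (~3–6% of truth) is of the same order as the bias bound, and a
  literal point comparison would reject an exactly unbiased estimator a
  third of the time. A 60-seed calibration run measured relative biases
  of (−0.4%, +2.9%, +0.4%) and z-score SDs near 1.
* Family-wise error of the Bonferroni-controlled scan over 100 null
  cohorts (200 proteins each): nominal within a 2-SE binomial band.
* Wave recovery: 1-SD steps at 44/51/63 on aging proteins with
  trajectory amplitudes zeroed (the logistic family otherwise creates
  genuine secondary contrast near 48–50 that is not wave noise), scanned
  at the generator's true MA: the clock's coefficient noise at desk-scale
  event counts smears MA by several years, which would blur the planted
  steps — at biobank scale (~14k deaths) that smear is negligible, so the
  experiment isolates the wave engine while the pipeline itself scans the
  estimated MA. Three peaks within ±1 year in ≥ 8/10 seeds (observed
  10/10 and 9/10 across seed sets).
* Trajectory clustering of 60 planted curves: ARI 1.0 at noise SD 0.05.
* Mann–Kendall against all 5,040 orderings at n = 7; hypergeometric
  tails against complete enumeration for N ≤ 15; Bonferroni/BH against
  brute-force definitions; and byte-identical manifests for two pipeline
  runs at the same seed.

## 10. Known limitations

* Proportional-hazards diagnostics (Schoenfeld residuals), competing
  risks, and time-varying effects are not implemented.
* The MA formula is the hazard-matching solution MA = CA + s/γ; other
  anchorings (e.g. population-average hazard at a reference age) would
  shift MA by a constant and are isolated behind one function if needed.
* The Cox scans use follow-up time as the timescale with age as a
  covariate; the Gompertz clock uses attained age with left truncation.
  Real analyses should pick one deliberately.
* Enrichment results depend entirely on the user-supplied GMT content;
  the package ships no annotation databases.
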