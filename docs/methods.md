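# Methods

## The estimation problem

The package targets the average treatment effect of a binary exposure on a
time-to-event outcome in a cohort drawn from a coded healthcare database.
Confounding is assumed to act through latent patient-level constructs that
are observed only through proxy codes scattered across several data
dimensions. The HDPS procedure converts those codes into binary recurrence
covariates, ranks them by empirical confounding potential, and adjusts for
the top k through a propensity score.

## Model and estimators

**Propensity score.** Maximum-likelihood logistic regression of exposure on
the pre-defined covariates, optionally augmented with the selected HDPS
covariates. Perfectly collinear columns are removed by pivoted-QR rank
detection before fitting (the fit is invariant to which duplicate is kept;
the dropped names are logged). The fit is delegated to statsmodels'
binomial GLM (IRLS), which tolerates near-collinear designs better than a
Newton solve. Complete separation is detected as a residual deviance below
1e-4 — a fit that classifies exposure essentially perfectly — and raised as
an error advising trimming or fewer covariates; quasi-separated rare binary
cells, which are routine when hundreds of indicator covariates enter the
model, are tolerated.

**Weights.** IPTW for the ATE: 1/ps (exposed), 1/(1−ps) (unexposed).
Stabilised weights multiply by the marginal exposure probability of the
patient's own group. Stabilisation cancels exactly in weighted prevalences
and rates; in the Cox partial likelihood the two group scalings interact
through shared risk sets, so stabilised and unstabilised point estimates
agree closely but not to machine precision (a global rescaling of all
weights is exactly invariant). The default is unstabilised, with
stabilisation behind a flag. Optional trimming removes patients outside
chosen percentiles of the pooled PS distribution; the default is no
trimming, and trimming that empties an exposure group is an error.

**Outcome model.** Cox regression with exposure as the sole term, fitted by
weighted partial likelihood (lifelines, Efron tie handling) with a robust
sandwich variance treating the weights as fixed. Weight-estimation
uncertainty is not propagated, matching standard IPTW practice; the
resulting intervals are mildly conservative. The confidence level is fixed
at 95%. The confidence limit ratio (CLR = upper/lower bound) is the
precision summary carried through all outputs.

## Feature generation conventions

* The pre-exposure window is half-open: `[index − lookback, index)`.
  Records on the index date are ambiguous pre/post exposure and always
  excluded.
* The prevalence filter ranks codes by the number of distinct patients with
  the code, ties broken lexicographically. "Most common" is implemented
  literally; ranking by closeness of prevalence to 0.5 is a known variant
  that is deliberately not the default.
* Recurrence thresholds use the nearest-rank percentile (no interpolation)
  of the per-patient counts **among patients with at least one
  occurrence**. Computed over the whole cohort instead, the median would be
  0 for any code under 50% prevalence and every cut-off would collapse to
  "once".
* Cut-off columns that are element-wise identical within one feature (e.g.
  when the median count is 1) are collapsed, keeping the least stringent
  name; the merge is recorded in the covariate matrix. Collapsing is
  deliberately *not* applied across codes — cross-code merges would destroy
  the (dimension, code) identity needed by prioritisation and concept
  summaries — and any remaining cross-code duplicates are dropped by the
  PS fit's collinearity screen instead.

## Prioritisation conventions

* The covariate–outcome association uses the binary any-event indicator by
  default (risk ratio); a person-time incidence-rate-ratio variant is
  available behind a flag.
* Zero cells: 0.1 is added to every cell of the affected 2×2 table before
  computing that ratio (the convention of the original HDPS
  implementation). Prevalences are reported uncorrected.
* Protective outcome associations enter the Bross formula as
  max(RR, 1/RR); without the inversion, protective confounders rank
  spuriously low.
* Exposure-only ranking scores covariates by |log RR_CE| (the symmetric
  choice; distance of RR_CE from 1 is the alternative reading).
* All ranking ties break lexicographically by covariate name, so ranks are
  a deterministic permutation of 1..N.
* Covariates constant across all patients carry no information and are
  excluded with a logged reason.

## Diagnostics conventions

* ASDs are reported on the percent scale; 10% is the conventional concern
  reference. Weighted ASDs compare weighted group prevalences/means but
  keep the **unweighted** pooled-variance denominator by default, so the
  weighted and unweighted columns share one scale; a fully weighted
  denominator is available behind a flag.
* Importance weights for mean-ASD summaries are ((N+1) − rank)/N on the
  ranked set of size N; pre-defined covariates, which have no rank, get
  weight 1.
* The PS overlap coefficient is the area under the pointwise minimum of the
  two group densities on 100 equal-width bins over [0, 1] (configurable).
* The near-instrument rule is read as thresholds on absolute natural-log
  risk ratios: flag when |log RR_CE| > τ_E and |log RR_CD| < 0.5, with
  presets τ_E = 1.5 (strict) and τ_E = 1.1 (relaxed). The relaxed preset
  flags a superset of the strict one by construction. The association
  scatter additionally reports strengths on the |RR − 1| scale; the two
  scales are computed side by side rather than conflated.
* Undefined prevalence ratios (zero prevalence in one group) reuse the
  0.1-per-cell continuity correction and are flagged.

## The synthetic-data generator

The generator emulates the structure the HDPS assumes rather than any
specific coding system:

* K latent confounders Z ~ N(0, 1) enter both the exposure logit and the
  log-hazard with coefficient `confounding_log_hr`; an exposure-only latent
  U drives planted instrument-like codes.
* Exposure is logistic; event times are exponential with administrative
  censoring only — the simplest censoring consistent with a weighted Cox
  analysis, chosen so closed-form reasoning about bias is possible.
* Each code has a log-uniform base Poisson rate; confounder-proxy codes
  multiply it by exp(proxy_loading · Z_k) (round-robin over latents),
  iv_like codes by exp(iv_code_loading · U), noise codes are constant.
  Counts expand to dated records uniform in the lookback window (the
  recurrence assessment ignores timing, so uniform dates suffice).
* Because U never enters the hazard, iv_like codes have true RR_CD = 1:
  they are near-instruments by construction. Their base prevalence is kept
  low so that the prevalence ratio tracks the rate ratio and the planted
  exposure association survives dichotomisation; `iv_exposure_log_or` = 1.5
  and `iv_code_loading` = 2.0 make them clearly flaggable at the default
  sample sizes.
* Two pre-defined covariates (standardised age, sex) predict the outcome
  only. Routing all confounding through Z keeps the crude estimator
  exactly unbiased when `confounding_log_hr` = 0, which the tests exploit.

**Calibration.** The reference scenario has a true hazard ratio of 1.0 and
confounding strong enough to push the crude hazard ratio to roughly 1.2 —
the classic spurious-harm pattern that proxy adjustment should remove. A
logistic-covariance approximation (crude log-HR bias ≈ K γ² · E[p(1−p)] /
p̄(1−p̄) for K latents with coefficient γ) gives γ = 0.35 with K = 2 at the
default exposure-logit variance; one confirmatory simulation matched
(mean crude HR ≈ 1.18) and the value was frozen. `proxy_loading` = 1.5
makes the binary proxies informative enough that IPTW on the top-ranked
covariates removes most of the confounding (residual log-HR bias ≈ 0.03 at
n = 3000, against a robust SE of ≈ 0.10), which is the regime the method is
designed for.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic disease natural histories or UK
primary-care coding distributions; informative censoring or dropout;
time-varying confounding; measurement processes where code presence depends
on exposure itself (proxies here are conditionally independent of exposure
given the latents); correlated code co-occurrence beyond what shared
latents induce.

## Simulation study sizes

The replicated studies in the acceptance tests use scaled-down
configurations chosen once: parameter recovery uses 100 replicates of
n = 3000 patients, 60 codes (4 instrument-like, 20 noise), k = 50; the
near-instrument operating characteristics use 50 replicates of n = 2000;
the balance pattern uses one run of the full default scenario (n = 5000,
120 codes, k = 100). These sizes give Monte-Carlo error small enough for
the qualitative orderings being tested while keeping the whole suite
desk-scale.

## Known limitations

* Prioritisation is univariate: covariates that confound only jointly are
  ranked poorly, and conditionally-null covariates can be selected. This is
  a property of the method, not of the implementation.
* The near-instrument rule is an empirical heuristic; no statistical test
  distinguishes instruments from confounders, and the rule's thresholds are
  conventions.
* Estimands other than the IPTW ATE (matching, fine stratification, doubly
  robust estimation) and machine-learning prioritisation are out of scope.
* Free-text features and timing-aware ("proximity to exposure start")
  recurrence variants are not implemented; the feature layer exposes the
  covariate dictionary needed to build such extensions.
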