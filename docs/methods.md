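# Methods

`hospbench` implements a complete hospital outcome-benchmarking workflow:
case-mix-adjusted standardized ratios for three administrative outcomes
(in-hospital mortality, 30-day unplanned same-hospital readmission, long
length of stay), a 5-level ordinal composite of the three, and the
rankability statistic that separates true between-hospital differences from
estimation noise.  Because real multi-hospital administrative data cannot be
shipped, every stage is exercised against a synthetic admissions generator
with *known planted effects*; all empirical statements below are recomputed
by the test suite or `scripts/acceptance.py`.

## Outcome definitions

* **Mortality** — death in hospital during the index admission.
* **Readmission** — unplanned readmission to the same hospital within 30
  days of discharge, defined for survivors only.  Deaths carry a *missing*
  readmission value, never 0, so downstream denominators cannot silently
  include them.
* **Long LOS** — a stay strictly greater than the 75th percentile of LOS for
  the patient's diagnosis/procedure group (90th percentile for the
  upper-decile sensitivity analysis).  Percentiles use the nearest-rank
  convention (the `ceil(p/100·n)`-th order statistic) on LOS pooled over all
  hospitals and years; pooling and nearest-rank were chosen because they are
  deterministic and closed-form checkable.  Readmission and long-LOS
  analyses run over survivors; mortality over all admissions.

## Synthetic admissions generator

Each of `n_hospitals` hospitals draws a volume uniformly from
`volume_range`, creating the precision heterogeneity that rankability needs.
Hospital quality is a trivariate normal effect
`(eta_mort, eta_readm, eta_los)` on the log-odds scale with variances
`(tau2_mort, tau2_readm, tau2_los)` and a configurable 3×3 correlation;
draws are sample-centered so the planted effects average exactly zero.
Admission covariates (5 ordered age bands, sex, planned/unplanned admission,
transfer-in, urgent prior admission, Poisson Elixhauser count) are sampled
i.i.d. within hospital; their log-odds contributions are mean-centered so
marginal outcome rates sit near the group baselines (with large covariate
effects the marginal rate still exceeds the baseline slightly, by Jensen's
inequality — visible in the all-patients preset, ~4.3% crude mortality for a
3.1% baseline).

**LOS is log-logistic**: `log LOS ~ Logistic(location, scale)` per group.
This right-skewed choice has closed-form quantiles (upper quartile
`exp(location + scale·ln 3)`), and — the deciding property — a location
shift of `scale · eta_los` changes the log-odds of exceeding *any* fixed
cutoff by exactly `eta_los`.  The planted `tau2_los` therefore genuinely is
a between-hospital variance on the log-odds scale of the long-LOS outcome,
and scenarios that share one latent effect across all three outcomes are
exact.

Mortality is Bernoulli with logit = group baseline + centered case-mix
contribution + `eta_mort` + `coupling · (upper-quartile indicator − 0.25)` +
calendar trend, where the indicator uses the group's *distributional*
quartile at generation time (downstream analysis re-estimates the empirical
quartile; the mismatch is negligible and intentional).  Readmission is
analogous for survivors.  With `early_death_short_los` (the stroke-like
pattern) deaths have their LOS redrawn from a shorter distribution (location
shift −0.3, scale ×0.9), which produces a patient-level adjusted OR of long
LOS on mortality of roughly 0.5 while correlated `eta_mort`/`eta_los`
keep the hospital-level correlation of standardized mortality and long LOS
positive — the patient/hospital Simpson-type reversal.

All randomness flows from one integer seed: `SeedSequence(seed)` spawns one
child for the hospital effects and one per hospital, so partial reruns are
reproducible and output is byte-identical for a fixed config.

**What the generator does not emulate**: within-hospital case-mix
differences (covariates are i.i.d. across hospitals, so case-mix adjustment
is exercised but not stressed by confounding between hospital and case mix),
coding differences between hospitals, between-country structure, transfers
between hospitals, and readmissions to other hospitals.  Passing tests show
the *methods* behave correctly under known truth, not that any particular
real-world hospital comparison is unbiased.

### Preset scenarios

| preset | purpose | key settings |
|---|---|---|
| `null` | calibration checks | all tau²=0, couplings 0, covariate effects 0; baseline mortality 3.1%, readmission 7.8% |
| `all_patients` | headline pipeline | 3 groups, tau²=(0.15, 0.05, 0.15), r(mort,LOS)=0.8, coupling ln 1.45, full case-mix effects |
| `stroke_like` | Simpson reversal | baseline mortality 13.6%, early-death redraw, r(mort,LOS)=0.8 |
| `colorectal_like` / `heart_failure_like` | stratum profiles | baselines 5.0%/10.6% and 6.7%/16.9%, couplings ln 1.31 / ln 1.38 |
| `coupled` | correlation structure | tau²=(0.20, 0.10, 0.20), r(mort,LOS)=0.9, readmission independent |
| `shared_effect` | recovery & rankability | one latent effect, tau²=0.25 on all three outcomes, no covariate effects |
| `improving` | period comparison | mortality trend −0.06, LOS trend −0.04 log-odds/year |

Baseline rates mirror the overall/stratum profiles of large international
administrative cohorts (3.1% mortality overall, 13.6% for stroke, 16.9%
readmission for heart failure, ~21% long LOS by construction).

## Case-mix models

Separate logistic regressions per diagnosis/procedure group and outcome
(statsmodels GLM/Binomial under the hood).  The candidate set is the six
case-mix main effects, discharge year (categorical — no functional form is
assumed), and two a-priori interactions: age×Elixhauser and admission
method×transfer.  Backward elimination removes one term per iteration — the
eligible term with the largest block-Wald p ≥ 0.1 — and refits; a
multi-level factor is kept or dropped as a block; an interaction is eligible
before its main effects, and a main effect only becomes eligible when no
retained interaction contains it; ties break by reverse-alphabetical term
name for determinism.  Age bands with fewer than 10 events are iteratively
merged into the immediately older band before fitting (a sparse oldest band
merges downward).  Groups with <25 admissions or <10 events (or non-events)
get intercept-only models; separation or non-convergence triggers a ridge
refit (L2 penalty 1e-3 on non-intercept terms, flagged) and, failing that,
intercept-only.  Converged ML fits satisfy the calibration identity
Σ expected = Σ observed to 1e-6 relative, which forces the all-hospitals
standardized ratio to exactly 100.

Prediction on unseen categorical levels raises an error rather than
imputing.

## Standardized ratios and patient-level ORs

Per hospital and outcome, `ratio = 100 · observed / expected`, expected
being the sum of model probabilities over the hospital's denominator
population (in-sample, as is standard for indirect standardization).
Patient-level ORs of upper-quartile LOS on mortality/readmission come from
logistic fits, unadjusted or adjusted for hospital (fixed-effect dummies)
plus the case-mix main effects; Wald 95% CIs.  Hospital-level associations
are Pearson correlations of the standardized ratios (t-distribution p-values,
n−2 df).

## Ordinal composite

Levels: 1 alive/normal LOS/no readmission, 2 alive/long LOS/no readmission,
3 alive/normal LOS/readmission, 4 alive/long LOS/readmission, 5 death
(death dominates regardless of the other flags).  The composite is analysed
with a cumulative-logit proportional-odds model — the standard model behind
"one coefficient per hospital" — parameterized so a positive hospital
coefficient means higher odds of a worse level.  Hospital enters as a fixed
effect with the largest-volume hospital as reference (numerical stability;
the centering below makes the choice immaterial, and a test asserts it).
The case-mix covariates enter as one pooled set with group as a covariate.

The fitter is in-package (L-BFGS on the exact likelihood with analytic
gradients; thresholds optimized through a log-increment reparameterization;
standard errors from the observed information in the natural
parameterization).  It supports case weights — covariate-free fits aggregate
to (hospital, level) sufficient statistics — and a ridge fallback
(penalty 1e-3 on coefficients, flagged) for monotone likelihood, e.g. a
hospital with all-best outcomes.  It is cross-checked in the tests against a
brute-force optimization of an independently written likelihood (≤1e-4) and
against statsmodels' OrderedModel.

**Standardized composite rate**: `100 · exp(beta_h − mean(beta))`, the
unweighted mean over all hospitals including the reference's 0 — an odds
ratio against the average hospital; the geometric mean of rate/100 is
exactly 1.  Centered effects carry delta-method standard errors so the
reference hospital also receives a proper uncertainty.

No proportional-odds assumption test is run by default, and no explicit
outcome weights are offered: the ordering itself encodes the (implicit)
weighting, and defensible explicit weights do not exist.

## Rankability

`rankability = 100 · tau² / (tau² + median sigma²)`, where tau² is the
between-hospital variance from a random-intercept fit and median sigma² the
median squared standard error of the fixed-effect hospital estimates.

* **tau²** — maximum likelihood with *adaptive* Gauss–Hermite quadrature
  (15 nodes recentred and rescaled at each hospital's posterior mode), for
  both the binary outcomes and the ordinal composite.  Non-adaptive
  quadrature is badly biased here (it underestimated a planted tau² of 0.25
  by ~30% at 26×5,000, because per-hospital likelihoods are far narrower
  than the prior).  A DerSimonian–Laird moments estimator on the centered
  fixed-effect coefficients (inverse-variance weights, truncated at zero)
  serves as fallback and cross-check.
* **median sigma²** — binary outcomes use per-hospital fixed-effect logits
  (scalar Newton per hospital) reported as contrasts against the
  largest-volume reference, the same dummy-coding convention as the ordinal
  fit, so the medians are comparable across outcome types; the reference's
  artifactual zero SE is excluded from the median.
* **Case-mix adjustment** enters both fits through a shared per-record
  offset (the case-mix linear predictor), keeping tau² and sigma² on one
  scale; the composite's random-intercept fit omits the offset (case mix is
  i.i.d. across hospitals in the generator, so it contributes no
  between-hospital variance).

Under a shared latent hospital effect, the composite's rankability matches
or exceeds each component's because the ordinal likelihood extracts more
information per admission (smaller sigma²) at essentially the same tau².

## Pipeline, period comparison, problem sizes

`run_full_analysis` chains all stages deterministically from one seed and
emits per-hospital composite distributions, ratio summaries (median/IQR),
OR and correlation tables, rankability, and a two-period comparison
(level-1 proportion per period, two-proportion chi-square without continuity
correction, per-group breakdown, and per-period composite tau² via the
moments estimator on hospital fixed effects).

Analyses in the tests and acceptance script run at desk scale, chosen as the
package's own study conditions: 26 hospitals throughout; 400–800 admissions
per hospital for replicated scenario checks (40 replicates for the
correlation pattern, 25 for the stroke reversal, 20 for the composite
rankability comparison), 2,000 per hospital for hospital-effect recovery,
5,000 per hospital (30 replicates) for tau² recovery, and ~3,000-record
cohorts × 1,000 replicates for the null calibration of the period
comparison.

## Known limitations

* Expected counts come from in-sample fits; no shrinkage or cross-fitting.
* The adjusted patient-level OR conditions on the empirical (not latent)
  LOS quartile; with the planted coupling of ln 1.45 the recovered OR is
  compatible within CI but not bias-free in principle.
* The moments tau² on centered coefficients ignores the small negative
  correlation the centering induces (standard DL behavior).
* Backward elimination inference (post-selection) is taken at face value,
  as is conventional in this literature.
* With strong covariate effects, marginal preset rates exceed the stated
  baselines slightly (Jensen); calibration statements are exact only for
  the null/covariate-free presets.
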