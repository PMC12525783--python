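# Methods

This note records the statistical conventions the package implements, the
choices made where the underlying definitions leave room, and what the
synthetic-data tests do and do not establish.

## Cohort assembly

Energy-implausible reporters are removed with fixed sex-specific bounds:
males kept at 800–4200 kcal/day, females at 600–3500, boundaries inclusive
(records missing sex or energy are excluded with reason "missing").  No
individualized (Henry-equation or Goldberg) screening is applied; the fixed
published bounds are the filter.

Repeated 24-h recalls are averaged item-wise over *all* recalls, counting an
item absent from a recall as a recorded zero — a 24-h instrument records
non-consumption as zero intake, so a food eaten on two of five days
contributes two-fifths of its recalled amount.

The eligibility cascade runs in a fixed order — frailty-data completeness,
mortality linkage, minimum age (kept iff age ≥ 45 by default) — and the
`CascadeReport` enforces exact accounting: exclusions plus the final count
always reproduce the initial count, and each step starts where the previous
ended.

The landmark sensitivity option removes only *deaths* within the first
`landmark_exclusion_years` of follow-up; survivors censored early are kept
and person-time is not truncated.  Whether early survivors should also be
altered is genuinely ambiguous; dropping deaths alone is the literal reading
of "excluding deaths during the first two years" and is what is implemented.

Missing covariates are imputed explicitly after the cascade: column median
for numerics and most-frequent level for categoricals by default, with a
chained-equations option (scikit-learn `IterativeImputer` on the numeric
block, mode for categoricals).  Random-forest imputation is intentionally
out of scope.

## Diet scores

All component mappings, cutoffs and reference statistics live in an editable
YAML taxonomy (`dietfrail/data/taxonomy.yaml`); the code fixes only the
scoring *shapes*.  Defaults follow the published original definitions
(AHEI-2010, the Fung DASH adherence score, the Trichopoulou Mediterranean
score, the Shivappa DII, the Satija plant-based indices), with two caveats:

- AHEI sodium uses fixed linear cutoffs (10 points at ≤1112 mg/day, 0 at
  ≥3337) as a stand-in for the original cohort-decile scoring, so the score
  stays a per-participant function of intake alone.
- The DII reference table ships with representative global means/SDs and
  inflammatory effect scores for the eight parameters the synthetic taxonomy
  carries (energy, fiber, vitamin C, alcohol, SFA, MUFA, PUFA, long-chain
  n-3).  Users analyzing real data should replace it with the full published
  table; the arithmetic (z-score → doubled cumulative proportion − 1 →
  effect-weighted sum) is unchanged by the parameter list.

The DII centered percentile uses the normal CDF of the z-score against the
global reference mean/SD, not a cohort-empirical CDF — the construction the
published index prescribes.  MED medians are sex-specific within the
analysis cohort.  DASH and PDI quintiles are computed within the analysis
cohort at fit time.

**Rank categories (quintiles, tertiles).**  Ties are handled by midrank:
p = (n_below + ½·n_equal)/n, cut at equal-probability boundaries with
right-*closed* intervals (a participant exactly at the 33.3rd percentile
falls in the bottom tertile).  This makes integer scores 1..9 split into
exact thirds and keeps assignments deterministic and order-independent.  A
fully degenerate component (a single distinct value) places all mass in the
lowest category.  Out-of-sample scoring (`transform` on new data) evaluates
the same midrank percentile against the stored fit cohort.

Tertile orientation: for AHEI/DASH/MED/PDI/HPDI the top tertile is labelled
"healthier"; for DII and UPDI the bottom tertile is.

## Frailty

Phenotype: count of five binary criteria; 0 robust, 1–2 prefrail, ≥3 frail.
Index: FI = present deficits / 49.  The printed category cutoffs overlap at
their boundaries ("≤ 0.12" robust and "0.12–0.24" prefrail; "0.24" appears
in both prefrail and frail); closure is assigned to the outer categories —
FI = 0.12 is robust and FI = 0.24 is frail — so both printed inequalities
hold and only the interior interval is narrowed.  The 49-deficit and
5-criterion column lists are configuration; the module fixes only the
arithmetic.

## Survival models

Cox partial likelihood (via lifelines) with Efron tie handling, although the
synthetic generator draws continuous times so ties never drive results.
Age at recruitment and assessment center enter as baseline-hazard strata —
age in 5-year bands by default (configurable width); the band width is a
convention, not an estimate, since only "age (strata)" is specified by
common practice.  Reported CIs are exp(β ± 1.96·SE).

- AIC = 2k − 2·logL; BIC = k·ln(d) − 2·logL with d = number of events (the
  effective sample size of a partial likelihood).
- An exposure level with zero events is not estimable; its rows are withheld
  from the fit and the level is reported as unavailable (NaN) rather than as
  a divergent estimate.
- p-for-trend: Wald test of a single coefficient on integer level scores
  0, 1, 2 in the stated order.
- Multiplicative interaction: LRT of the model with all diet × frailty
  indicator products against the main-effects model; df = number of product
  terms.
- Additive interaction: RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1 on the 2×2 corner
  cells (unhealthier/robust, healthier/frail, unhealthier/frail vs the
  common reference), delta-method CI by default with a parametric-bootstrap
  alternative.  RERI is used because "additive interaction" without a
  formula is conventionally operationalized this way.
- Restricted cubic splines use the truncated-power basis with Harrell
  scaling (division by (t_k − t_1)²): k knots give k−1 columns including the
  linear term, and the expansion is exactly linear beyond the boundary
  knots.  Default knots at the 5th/35th/65th/95th score percentiles; curves
  are reported relative to the cohort median score.
- Proportionality diagnostics: scaled-Schoenfeld correlation-with-(rank)time
  tests per term; the "global" row sums the per-term chi-squares (an
  approximation — the terms are treated as independent) and is advisory
  only.

## Life tables

Ages 50..100.  Calibration runs on the hazard scale h = −ln(1−q), because
hazard ratios compose multiplicatively in hazards, not in annual death
probabilities: h_ref = h / Σ_g p_g·HR_g and h_g = HR_g·h_ref, which
conserves Σ_g p_g·h_g = h to machine precision at every age (a q-scale
option exists for comparison and clamps at 1 with a warning).  HRs are
treated as age-constant within sex; prevalences are baseline proportions.

Person-years follow the abridged convention L(a) = l(a)·(1 − q(a)/2)
(deaths credited half a year).  Survivors of the open interval at 100 are
credited 1/h(100) years each — the constant-hazard expectation — except
when the closing hazard is zero, where the table truncates (zero extra
years) rather than crediting an infinite remainder.

ΔLE = LE_ref − LE_g (positive = years lost).  CIs are percentile intervals
over parametric-bootstrap draws of the log-HR vector from a multivariate
normal at the estimates with the fitted covariance (10,000 runs by default;
deterministic given the seed).  Prevalence estimation error is *not*
propagated; with cohort sizes in the thousands it is an order of magnitude
smaller than the HR uncertainty.

## Synthetic-data model

The generator emulates the structure the analysis assumes, not any specific
population:

- One latent diet-healthfulness factor and one latent frailty propensity,
  standard bivariate normal with correlation `diet_frailty_corr` (default
  −0.35: healthier diets accompany fewer deficits).
- Per-item intakes are lognormal with signed loadings on the diet factor;
  the 49 deficits and 5 phenotype criteria are Bernoulli with logistic
  probabilities monotone in the frailty factor, with intercepts set so the
  marginal frailty categories land near community frequencies (~62% robust
  and ~8% frail on the index; ~2% frail on the phenotype).
- Covariates are drawn independently from their level sets with plausible
  marginal frequencies (54% female, 56% never-smokers, 21% BMI ≥ 30, ...).
- Survival is inverse-transform exponential at rate
  λ₀·exp(log-HR(joint group) + covariate effects) per month (λ₀ = 4·10⁻⁴ by
  default), administratively censored at 150 months, giving event fractions
  and median follow-up (~12.5 years) typical of a mid-life cohort followed
  for a decade.  Default true log-HRs rise from 0 in the reference cell to
  1.1 (HR ≈ 3) for unhealthier-diet frail participants.
- The full generative path assigns each participant the joint group that
  the pipeline itself reconstructs (score tertile × frailty category), so
  parameter recovery is testable end to end; a direct group-sampling path
  with specified prevalences serves simulation studies that only exercise
  the survival and life-table stages.
- A Gompertz schedule q(a) = 1 − exp(−a·e^{b(age−50)}) stands in for a
  national mortality-rate table.

What passing tests show: the estimators recover known proportional-hazards
effects, the interaction tests hold their nominal size, and the bootstrap
ΔLE intervals attain close-to-nominal coverage *under the generative model*.
What they do not show: robustness to measurement error in recalls,
informative censoring, time-varying diet, non-proportional hazards, or
confounding structures beyond the simple covariate effects generated —
real-data behaviour on those axes is untested by construction.

## Problem sizes and numerics

Simulation-based checks use cohorts of 50,000 (parameter recovery, 100
replicates), 2,000 (interaction size, 200 replicates) and 4,000 (CI
coverage, 200 truths at 1,000 bootstrap runs) — sizes chosen so each check
has the power it needs while the whole suite stays desk-scale.  The Cox
Newton iterations run at a 10⁻⁹ convergence tolerance so tiny-data fits
match a direct partial-likelihood maximization to 10⁻⁶.  Floating-point
round-trips through delimited text are exact (correctly rounded parsing on
read).  All randomness flows through numpy Generators seeded from explicit
integers; pipeline reruns with the same config and seed are byte-identical.

## Known limitations

- The taxonomy's AHEI sodium cutoffs and DII reference list are editable
  stand-ins (see above), not the exact appendix tables of any one study.
- Townsend deprivation arrives as a precomputed quartile; no postcode
  derivation.
- No competing-risks or cause-specific mortality; no healthy-life-expectancy
  decomposition; no projection beyond age 100.
- The multiplicative-interaction LRT and the spline curves assume the
  stratified Cox model is correctly specified; diagnostics are advisory.
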