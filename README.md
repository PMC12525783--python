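# dietfrail

Joint diet-quality × frailty survival analysis for epidemiological cohorts.

`dietfrail` is aimed at nutritional and geriatric epidemiologists who want to
ask: *does a healthier diet still pay off once someone is frail, and by how
many years?*  It implements, as one tested pipeline:

- **Seven diet-quality indices** — AHEI (0–110), DASH (8–40), MED (0–9), the
  Dietary Inflammatory Index (DII), and the three plant-based diet indices
  (PDI / HPDI / UPDI, 18–90 each) — with orientation-aware cohort tertiles
  (top tertile of a healthy score, bottom tertile of DII/UPDI = "healthier").
- **Two frailty constructs** — the 5-criterion frailty phenotype
  (0 robust / 1–2 prefrail / ≥3 frail) and the 49-deficit frailty index
  FI = deficits/49 (≤0.12 robust / ≥0.24 frail).
- **Stratified Cox proportional-hazards models** for the nine mutually
  exclusive diet-tertile × frailty-category cells (reference: healthier ×
  robust), with baseline hazards stratified by age band and assessment
  center, Efron tie handling, AIC/BIC, p-for-trend, restricted-cubic-spline
  dose–response (4 knots at the 5th/35th/65th/95th percentiles), and
  scaled-Schoenfeld proportionality diagnostics.
- **Interaction on both scales** — multiplicative via likelihood-ratio tests
  on cross-product terms, additive via the relative excess risk due to
  interaction, RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1, with a delta-method CI.
- **Life expectancy from age 50** — group-specific life tables obtained by
  calibrating the reference hazard so that prevalence-weighted group hazards
  reproduce a national mortality schedule: h_ref(a) = h(a) / Σ_g p_g·HR_g,
  h_g(a) = HR_g·h_ref(a), with parametric-bootstrap CIs for ΔLE.
- **A synthetic-cohort generator** with known ground truth (latent
  diet-healthfulness and frailty-propensity factors, proportional-hazards
  survival with configurable true log-HRs per joint group), so every stage
  is testable without access to any restricted cohort.

Cohort and mortality-rate inputs are plain delimited text; real participant
data (e.g. a cohort-study extract) plug in through a column-mapping schema.

## Worked example

```python
import numpy as np
from dietfrail import TruthParams, simulate_cohort, fit_cox, group_life_expectancy
from dietfrail.simulate import generate_population_rates
from dietfrail.io import mortality_q_vector

cohort = simulate_cohort(TruthParams(n=20_000, seed=1))   # AHEI x frailty index
hrset = fit_cox(cohort, exposure="joint_group",
                covariates=["sex", "smoking"], strata=["center"],
                age_col="age_at_recruitment")
print(hrset.summary_frame()[["term", "hr", "ci_low", "ci_high"]]
      .round(2).to_string(index=False))
```

```
                            term   hr  ci_low  ci_high
    joint_group=healthier_robust 1.00    1.00     1.00
       joint_group=medium_robust 1.11    0.97     1.28
  joint_group=unhealthier_robust 1.45    1.26     1.66
  joint_group=healthier_prefrail 1.46    1.23     1.75
     joint_group=medium_prefrail 1.52    1.30     1.78
joint_group=unhealthier_prefrail 1.90    1.65     2.19
     joint_group=healthier_frail 2.10    1.53     2.87
        joint_group=medium_frail 2.53    2.03     3.16
   joint_group=unhealthier_frail 2.80    2.35     3.33
```

Hazard ratios rise along both axes: frail participants in the unhealthier
AHEI tertile carry ~2.8× the mortality hazard of robust participants in the
healthier tertile (the generating truth for that cell was HR = 3.0).
Translating the fitted HRs into male life expectancy at age 50 against a
Gompertz population schedule:

```python
hrs = {lv: 1.0 if lv == "healthier_robust"
       else float(np.exp(hrset.beta[f"joint_group={lv}"]))
       for lv in hrset.exposure_levels}
prev = cohort["joint_group"].value_counts(normalize=True).to_dict()
q = mortality_q_vector(generate_population_rates(), "male")
le = group_life_expectancy(q, prev, hrs, reference="healthier_robust")
print(le.to_frame().round(2).to_string(index=False))
```

```
               group  le_years  delta_le_years
    healthier_robust     32.93            0.00
       medium_robust     31.89            1.04
  unhealthier_robust     29.36            3.57
unhealthier_prefrail     26.83            6.10
     medium_prefrail     28.91            4.02
  healthier_prefrail     29.26            3.67
   unhealthier_frail     23.37            9.57
        medium_frail     24.24            8.69
     healthier_frail     25.94            6.99
```

`delta_le_years` is years of life lost relative to the healthier-diet robust
reference; within the frail stratum, moving from the healthier to the
unhealthier tertile costs 9.57 − 6.99 ≈ 2.6 years here.

The same analysis is scriptable from the shell:

```bash
dietfrail simulate --n 20000 --seed 1 --out-cohort cohort.csv --out-rates rates.csv
dietfrail run --cohort cohort.csv --rates rates.csv --outdir results/
```

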