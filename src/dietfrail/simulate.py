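"""Synthetic cohort generator with known ground truth.

Produces participant tables with the statistical structure the downstream
analysis assumes: correlated diet and frailty (one latent diet-healthfulness
factor and one latent frailty propensity, coupled through a bivariate
Gaussian copula), categorical covariates with plausible marginal frequencies,
and survival times drawn from a proportional-hazards model whose true
log-hazard-ratios for the nine joint diet-by-frailty groups are configurable.
A Gompertz generator stands in for national sex- and age-specific mortality
rates.

Everything is deterministic given ``TruthParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import DEFICIT_COLUMNS, FP_CRITERIA_COLUMNS, N_DEFICITS

DIET_TERTILES = ("healthier", "medium", "unhealthier")
FRAILTY_CATEGORIES = ("robust", "prefrail", "frail")

#: Canonical order of the nine joint exposure groups; the first is the
#: reference (healthier diet, robust).
JOINT_GROUPS = tuple(
    f"{d}_{f}" for f in FRAILTY_CATEGORIES for d in DIET_TERTILES
)
REFERENCE_GROUP = "healthier_robust"

DEFAULT_TRUE_LOG_HR: dict[str, float] = {
    "healthier_robust": 0.0,
    "medium_robust": 0.15,
    "unhealthier_robust": 0.30,
    "healthier_prefrail": 0.35,
    "medium_prefrail": 0.50,
    "unhealthier_prefrail": 0.65,
    "healthier_frail": 0.80,
    "medium_frail": 0.95,
    "unhealthier_frail": 1.10,
}

#: Baseline joint-group prevalences for the direct-sampling path: equal diet
#: tertiles crossed with deficit-index frailty margins (robust-heavy, few
#: frail), as seen in community cohorts of this age range.
DEFAULT_GROUP_PREVALENCE: dict[str, float] = {
    f"{d}_{f}": p / 3.0
    for f, p in zip(FRAILTY_CATEGORIES, (0.615, 0.34, 0.045))
    for d in DIET_TERTILES
}

#: Per-item lognormal intake models: (log-median, log-SD, healthfulness
#: loading).  Positive loadings rise with the latent diet factor.
ITEM_MODELS: dict[str, tuple[float, float, float]] = {
    "vegetables":     (0.92, 0.40, 0.35),
    "fruit":          (0.69, 0.45, 0.35),
    "fruit_juice":    (-0.69, 0.60, -0.25),
    "whole_grains":   (3.69, 0.50, 0.35),
    "refined_grains": (0.41, 0.50, -0.30),
    "potatoes":       (-0.22, 0.50, -0.20),
    "ssb":            (-0.92, 0.80, -0.40),
    "nuts":           (-0.69, 0.70, 0.35),
    "legumes":        (-0.92, 0.60, 0.30),
    "tea_coffee":     (1.10, 0.40, 0.10),
    "vegetable_oils": (0.00, 0.50, 0.25),
    "sweets":         (0.00, 0.60, -0.35),
    "red_meat":       (-0.36, 0.50, -0.35),
    "processed_meat": (-0.92, 0.60, -0.40),
    "fish":           (-0.92, 0.50, 0.30),
    "eggs":           (-0.69, 0.50, -0.10),
    "dairy_low_fat":  (0.00, 0.50, 0.20),
    "dairy_high_fat": (-0.22, 0.50, -0.20),
    "animal_fat":     (-1.20, 0.60, -0.30),
    "misc_animal":    (-1.20, 0.50, -0.10),
    "alcohol_g":      (2.48, 0.90, 0.00),
    "sodium_mg":      (7.82, 0.25, -0.20),
    "trans_fat_pct":  (-0.22, 0.50, -0.40),
    "pufa_pct":       (1.79, 0.30, 0.30),
    "pufa_g":         (2.64, 0.30, 0.30),
    "mufa_g":         (3.30, 0.25, 0.10),
    "sfa_g":          (3.33, 0.30, -0.30),
    "n3_g":           (-1.20, 0.80, 0.35),
    "fiber_g":        (2.83, 0.30, 0.40),
    "vitamin_c_mg":   (4.60, 0.50, 0.35),
}

_COVARIATE_MARGINALS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "sex": (("female", "male"), (0.54, 0.46)),
    "center": (("England", "Wales", "Scotland"), (0.89, 0.04, 0.07)),
    "bmi_category": (("<25.0", "25.0-29.9", ">=30.0"), (0.37, 0.42, 0.21)),
    "ethnicity": (("white", "other"), (0.96, 0.04)),
    "education": (("degree", "secondary", "primary", "professional"),
                  (0.45, 0.30, 0.10, 0.15)),
    "employment": (("employed", "other"), (0.60, 0.40)),
    "income": (("<18000", "18000-30999", "31000-51999", "52000-100000", ">100000"),
               (0.17, 0.25, 0.26, 0.21, 0.11)),
    "smoking": (("never", "previous", "current"), (0.561, 0.350, 0.089)),
    "alcohol_freq": ((">=3/week", "<3/week", "never"), (0.45, 0.47, 0.08)),
    "sleep": (("7-8h", "<7h", ">8h"), (0.68, 0.24, 0.08)),
    "physical_activity": (("high", "moderate", "low"), (0.35, 0.40, 0.25)),
}

_FAMILY_HISTORY = {"family_history_cvd": 0.40, "family_history_cancer": 0.30,
                   "family_history_diabetes": 0.20}

# Latent-to-indicator logistic slopes/intercepts for the frailty blocks,
# set so the marginal frailty categories land near community frequencies
# (index: ~62% robust / ~4% frail; phenotype: ~64% robust / ~2% frail).
_DEFICIT_SLOPE = 0.8
_DEFICIT_INTERCEPTS = (-3.5, -1.5)  # linspace endpoints over the 49 deficits
_FP_SLOPE = 1.2
_FP_INTERCEPTS = (-3.4, -3.0, -2.8, -3.2, -2.6)


@dataclass
class TruthParams:
    """Ground-truth generative parameters for a synthetic cohort."""

    n: int = 10_000
    seed: int = 0
    true_log_hr: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_LOG_HR))
    baseline_hazard: float = 4e-4  # events per person-month
    admin_censor_months: float = 150.0
    uniform_censor_months: float | None = None
    diet_frailty_corr: float = -0.35
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex:male": 0.45, "smoking:current": 0.60,
                                 "smoking:previous": 0.15})
    age_range: tuple[float, float] = (45.0, 70.0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("cohort size n must be >= 1")
        if not -1.0 <= self.diet_frailty_corr <= 1.0:
            raise ParameterError("diet_frailty_corr must lie in [-1, 1]")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be > 0")
        if self.admin_censor_months < 0:
            raise ParameterError("admin_censor_months must be >= 0")
        missing = set(JOINT_GROUPS) - set(self.true_log_hr)
        if missing:
            raise ParameterError(f"true_log_hr missing group(s): {sorted(missing)}")
        if self.true_log_hr[REFERENCE_GROUP] != 0.0:
            raise ParameterError("reference group log-HR must be fixed at 0")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(params: TruthParams) -> pd.DataFrame:
    """Generate participants with diet, frailty items and covariates.

    A bivariate standard-normal latent pair (diet healthfulness, frailty
    propensity) with correlation ``diet_frailty_corr`` drives the intake
    distributions (lognormal per item, loading-signed) and the Bernoulli
    probabilities of the 49 deficits and 5 phenotype criteria, which are
    monotone in the frailty latent.  Covariates are drawn from their level
    sets with plausible marginal frequencies.

    Returns a cohort DataFrame without survival columns (see
    :func:`generate_survival`).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    rho = params.diet_frailty_corr
    z_diet = rng.standard_normal(n)
    z_frail = rho * z_diet + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)

    cols: dict[str, np.ndarray | list] = {"id": [f"P{i:07d}" for i in range(n)]}
    cols["age_at_recruitment"] = rng.uniform(*params.age_range, size=n)
    for col, (levels, probs) in _COVARIATE_MARGINALS.items():
        cols[col] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))
    cols["townsend_quartile"] = rng.integers(1, 5, size=n)
    for col, p in _FAMILY_HISTORY.items():
        cols[col] = rng.random(n) < p
    sex_shift = np.where(cols["sex"] == "male", 0.12, 0.0)
    cols["energy_kcal"] = np.exp(7.56 + sex_shift + 0.18 * rng.standard_normal(n))

    for item, (mu, sigma, load) in ITEM_MODELS.items():
        cols[f"diet_{item}"] = np.exp(mu + load * z_diet + sigma * rng.standard_normal(n))
    cols["n_recalls"] = rng.integers(1, 6, size=n).astype(float)

    for col, intercept in zip(FP_CRITERIA_COLUMNS, _FP_INTERCEPTS):
        cols[col] = rng.random(n) < _sigmoid(intercept + _FP_SLOPE * z_frail)
    intercepts = np.linspace(*_DEFICIT_INTERCEPTS, N_DEFICITS)
    for col, intercept in zip(DEFICIT_COLUMNS, intercepts):
        cols[col] = rng.random(n) < _sigmoid(intercept + _DEFICIT_SLOPE * z_frail)

    cols["latent_diet"] = z_diet
    cols["latent_frailty"] = z_frail
    return pd.DataFrame(cols)


def _linear_predictor(cohort: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(cohort), dtype=float)
    for key, beta in effects.items():
        if ":" in key:
            col, level = key.split(":", 1)
            lp += beta * (cohort[col].to_numpy() == level)
        else:
            lp += beta * cohort[key].to_numpy(dtype=float)
    return lp


def generate_survival(
    cohort: pd.DataFrame,
    params: TruthParams,
    group_col: str = "joint_group",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw proportional-hazards survival for a cohort with joint groups.

    Event times are inverse-transform exponential draws at rate
    ``baseline_hazard * exp(true_log_hr[group] + covariate effects)`` per
    month, administratively censored at ``admin_censor_months`` (optionally
    also uniformly censored).  Returns a copy of the cohort with
    ``followup_months`` and boolean ``event`` columns.
    """
    if group_col not in cohort.columns:
        raise ParameterError(f"cohort lacks joint-group column '{group_col}'")
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    group_lhr = cohort[group_col].map(dict(params.true_log_hr))
    if group_lhr.isna().any():
        bad = sorted(set(cohort.loc[group_lhr.isna(), group_col]))
        raise ParameterError(f"unknown joint group label(s): {bad}")
    lp = group_lhr.to_numpy(dtype=float) + _linear_predictor(cohort, params.covariate_effects)
    rate = params.baseline_hazard * np.exp(lp)
    t_event = -np.log(rng.random(len(cohort))) / rate
    t_censor = np.full(len(cohort), float(params.admin_censor_months))
    if params.uniform_censor_months is not None:
        t_censor = np.minimum(
            t_censor, rng.uniform(0.0, params.uniform_censor_months, len(cohort)))
    out = cohort.copy()
    out["event"] = t_event <= t_censor
    out["followup_months"] = np.minimum(t_event, t_censor)
    return out


def sample_joint_groups(
    n: int,
    prevalence: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.Series:
    """Directly sample joint-group labels with given prevalences.

    A fast path for simulation studies that exercise only the survival and
    life-table stages (no diet scoring needed).
    """
    prevalence = dict(prevalence or DEFAULT_GROUP_PREVALENCE)
    labels = list(prevalence)
    probs = np.array([prevalence[g] for g in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"group prevalences sum to {probs.sum():.6f}, not 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return pd.Series(rng.choice(labels, size=n, p=probs), name="joint_group")


def generate_population_rates(
    gompertz: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Gompertz stand-in for a national sex/age mortality-rate table.

    q(age) = 1 - exp(-a * exp(b * (age - 50))) clamped to [0, 1] over ages
    50..100 for both sexes.  Defaults give q(50) of 0.25% (female) and 0.4%
    (male) rising to roughly 30% at 100.
    """
    gompertz = dict(gompertz or {"female": (0.0025, 0.098), "male": (0.004, 0.094)})
    rows = []
    ages = np.arange(50, 101)
    for sex in ("female", "male"):
        a, b = gompertz[sex]
        if a <= 0:
            raise ParameterError(f"Gompertz level 'a' must be > 0 (sex={sex})")
        if b < 0:
            raise ParameterError(f"Gompertz slope 'b' must be >= 0 (sex={sex})")
        q = np.clip(1.0 - np.exp(-a * np.exp(b * (ages - 50.0))), 0.0, 1.0)
        rows.append(pd.DataFrame({"sex": sex, "age": ages, "q": q}))
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(params: TruthParams, score: str = "ahei",
                    frailty_measure: str = "fi") -> pd.DataFrame:
    """Full generative path: cohort, diet score tertiles, frailty, survival.

    The joint exposure group assigned here is the one the analysis pipeline
    will itself reconstruct (score tertile crossed with frailty category), so
    parameter recovery is testable end to end.
    """
    from .frailty import assess_frailty
    from .scores import score_all
    from .survival import joint_groups

    cohort = generate_cohort(params)
    scores = score_all(cohort)
    frail = assess_frailty(cohort)
    tertile = scores[f"{score}_tertile"]
    category = frail[f"{frailty_measure}_category"]
    cohort = pd.concat([cohort, scores, frail], axis=1)
    cohort["joint_group"] = joint_groups(tertile, category)
    return generate_survival(cohort, params)
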