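"""Diet-quality indices: AHEI, DASH, MED, DII and the plant-based index family.

Each index is an sklearn-style transformer over an *intake frame* — a
DataFrame holding one column per taxonomy item (servings, grams or %-energy
per day) plus ``sex`` for the indices with sex-specific cutoffs or medians.
``fit`` learns whatever cohort statistics the index definition requires
(quintile positions for DASH and the plant indices, sex-specific medians for
MED; AHEI and DII are defined by fixed external constants and learn nothing),
``transform`` returns the scores.

Rank-based categories (quintiles here, tertiles in :class:`TertileAssigner`)
use the midrank percentile p = (n_less + 0.5 * n_equal) / n against the fit
cohort, cut at k equal probability boundaries with right-closed intervals, so
ties receive identical categories and a cohort of 1..9 splits into exact
thirds.  A degenerate component (a single distinct value) puts all mass in
the lowest category.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, ParameterError
from .io import DIET_PREFIX
from .taxonomy import FoodGroupTaxonomy, component_total, load_taxonomy

#: Orientation of each score: for "healthy" scores the TOP tertile is the
#: healthier diet; for "unhealthy" scores (DII, UPDI) the BOTTOM tertile is.
SCORE_ORIENTATION: dict[str, str] = {
    "ahei": "healthy",
    "dash": "healthy",
    "med": "healthy",
    "dii": "unhealthy",
    "pdi": "healthy",
    "hpdi": "healthy",
    "updi": "unhealthy",
}

TERTILE_LABELS = ("healthier", "medium", "unhealthier")


def intake_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extract the intake frame (taxonomy-named columns + sex) from a cohort table.

    Diet columns are stored in the cohort table under a ``diet_`` prefix;
    total energy doubles as the DII energy parameter.
    """
    diet_cols = [c for c in cohort.columns if c.startswith(DIET_PREFIX)]
    out = cohort[diet_cols].rename(columns=lambda c: c[len(DIET_PREFIX):]).astype(float)
    out["energy_kcal"] = cohort["energy_kcal"].astype(float).to_numpy()
    out["sex"] = cohort["sex"].to_numpy()
    out.index = cohort.index
    return out


# --------------------------------------------------------------- rank helpers

def midrank_percentile(reference: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Midrank percentile of ``x`` within the sorted ``reference`` sample."""
    left = np.searchsorted(reference, x, side="left")
    right = np.searchsorted(reference, x, side="right")
    return (left + 0.5 * (right - left)) / len(reference)


def quantile_category(p: np.ndarray, n_categories: int) -> np.ndarray:
    """Map midrank percentiles to 1..n_categories with right-closed cuts."""
    boundaries = np.arange(1, n_categories) / n_categories
    return 1 + (p[:, None] > boundaries[None, :]).sum(axis=1)


class _RankQuantiler:
    """Quintile/tertile machinery shared by the rank-scored indices."""

    def __init__(self, values: np.ndarray, n_categories: int):
        self.reference = np.sort(np.asarray(values, dtype=float))
        self.n_categories = n_categories
        self.degenerate = self.reference[0] == self.reference[-1]

    def category(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            return np.ones(len(x), dtype=int)
        p = midrank_percentile(self.reference, x)
        return quantile_category(p, self.n_categories)


def _sex_value(spec, sex: np.ndarray) -> np.ndarray:
    """Resolve a scalar-or-per-sex taxonomy constant to a per-row array."""
    if isinstance(spec, Mapping):
        return np.where(sex == "male", float(spec["male"]), float(spec["female"]))
    return np.full(len(sex), float(spec))


# ----------------------------------------------------------------------- AHEI

class AHEIScorer(BaseEstimator, TransformerMixin):
    """Alternate Healthy Eating Index (11 components, 0-10 each, total 0-110).

    Each component scores by linear interpolation between its worst and best
    intake cutoffs (clipped outside).  The alcohol component is non-monotone:
    moderate drinkers score 10, abstainers 2.5, heavy drinkers 0.  With
    ``alcohol_item_removed`` the index drops to 10 components (range 0-100),
    the form used when alcohol is adjusted for elsewhere.
    """

    def __init__(self, taxonomy: FoodGroupTaxonomy | None = None,
                 alcohol_item_removed: bool = False):
        self.taxonomy = taxonomy
        self.alcohol_item_removed = alcohol_item_removed

    def fit(self, X: pd.DataFrame, y=None):
        self.taxonomy_ = self.taxonomy or load_taxonomy()
        self.components_ = dict(self.taxonomy_.ahei["components"])
        if self.alcohol_item_removed:
            self.components_.pop(self.taxonomy_.ahei["alcohol_component"])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "components_")
        sex = X["sex"].to_numpy()
        total = np.zeros(len(X), dtype=float)
        for name, comp in self.components_.items():
            amount = component_total(X, comp["items"], f"AHEI component '{name}'")
            if comp["kind"] == "linear":
                worst = _sex_value(comp["worst"], sex)
                best = _sex_value(comp["best"], sex)
                frac = (amount - worst) / (best - worst)
                total += 10.0 * np.clip(frac, 0.0, 1.0)
            elif comp["kind"] == "alcohol":
                total += self._alcohol_score(amount, comp, sex)
            else:  # pragma: no cover - guarded by taxonomy validation
                raise ConfigurationError(f"unknown AHEI component kind '{comp['kind']}'")
        return total

    @staticmethod
    def _alcohol_score(drinks: np.ndarray, comp, sex: np.ndarray) -> np.ndarray:
        low = _sex_value({s: comp["moderate"][s][0] for s in ("female", "male")}, sex)
        high = _sex_value({s: comp["moderate"][s][1] for s in ("female", "male")}, sex)
        heavy = _sex_value(comp["heavy_at"], sex)
        base = float(comp["nondrinker_score"])
        score = np.empty(len(drinks), dtype=float)
        score[:] = base
        light = (drinks > 0) & (drinks < low)
        score[light] = base + (10.0 - base) * drinks[light] / low[light]
        moderate = (drinks >= low) & (drinks <= high)
        score[moderate] = 10.0
        over = drinks > high
        frac = (heavy[over] - drinks[over]) / (heavy[over] - high[over])
        score[over] = 10.0 * np.clip(frac, 0.0, 1.0)
        return score


# ----------------------------------------------------------------------- DASH

class DASHScorer(BaseEstimator, TransformerMixin):
    """DASH adherence score: 8 components by cohort quintile, total 8-40.

    Healthy components (fruit, vegetables, nuts/legumes, whole grains,
    low-fat dairy) score their ascending quintile 1-5; adverse components
    (sodium, red/processed meat, sweetened beverages) score 5-1 descending.
    """

    def __init__(self, taxonomy: FoodGroupTaxonomy | None = None):
        self.taxonomy = taxonomy

    def fit(self, X: pd.DataFrame, y=None):
        self.taxonomy_ = self.taxonomy or load_taxonomy()
        self.quantilers_ = {}
        self.directions_ = {}
        for name, comp in self.taxonomy_.dash["components"].items():
            amount = component_total(X, comp["items"], f"DASH component '{name}'")
            self.quantilers_[name] = _RankQuantiler(amount, 5)
            self.directions_[name] = comp["direction"]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "quantilers_")
        total = np.zeros(len(X), dtype=float)
        for name, quantiler in self.quantilers_.items():
            comp = self.taxonomy_.dash["components"][name]
            amount = component_total(X, comp["items"], f"DASH component '{name}'")
            q = quantiler.category(amount)
            total += q if self.directions_[name] == "healthy" else 6 - q
        return total


# ------------------------------------------------------------------------ MED

class MEDScorer(BaseEstimator, TransformerMixin):
    """Mediterranean diet score (0-9) against sex-specific cohort medians.

    Beneficial components (vegetables, legumes, fruit/nuts, cereal, fish,
    MUFA:SFA ratio) score 1 at or above the median; detrimental components
    (meat, dairy) score 1 below it; alcohol scores 1 inside the sex-specific
    moderate range.  ``alcohol_item_removed`` yields the 0-8 variant.
    """

    def __init__(self, taxonomy: FoodGroupTaxonomy | None = None,
                 alcohol_item_removed: bool = False):
        self.taxonomy = taxonomy
        self.alcohol_item_removed = alcohol_item_removed

    def _component_amount(self, X: pd.DataFrame, name: str, comp) -> np.ndarray:
        if comp.get("kind") == "ratio":
            num = component_total(X, comp["numerator"], f"MED component '{name}'")
            den = component_total(X, comp["denominator"], f"MED component '{name}'")
            if np.any(den <= 0):
                raise ParameterError(
                    f"MED component '{name}': non-positive denominator intake"
                )
            return num / den
        return component_total(X, comp["items"], f"MED component '{name}'")

    def fit(self, X: pd.DataFrame, y=None):
        self.taxonomy_ = self.taxonomy or load_taxonomy()
        sex = X["sex"].to_numpy()
        self.medians_: dict[str, dict[str, float]] = {}
        for name, comp in self.taxonomy_.med["components"].items():
            amount = self._component_amount(X, name, comp)
            self.medians_[name] = {
                s: float(np.median(amount[sex == s])) if np.any(sex == s) else np.nan
                for s in ("female", "male")
            }
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "medians_")
        sex = X["sex"].to_numpy()
        total = np.zeros(len(X), dtype=float)
        for name, comp in self.taxonomy_.med["components"].items():
            amount = self._component_amount(X, name, comp)
            median = _sex_value(self.medians_[name], sex)
            if comp["direction"] == "beneficial":
                total += (amount >= median).astype(float)
            else:
                total += (amount < median).astype(float)
        if not self.alcohol_item_removed:
            alc = self.taxonomy_.med["alcohol"]
            grams = component_total(X, alc["items"], "MED alcohol")
            low = _sex_value({s: alc["moderate"][s][0] for s in ("female", "male")}, sex)
            high = _sex_value({s: alc["moderate"][s][1] for s in ("female", "male")}, sex)
            total += ((grams >= low) & (grams <= high)).astype(float)
        return total


# ------------------------------------------------------------------------ DII

class DIIScorer(BaseEstimator, TransformerMixin):
    """Dietary Inflammatory Index from global reference means and SDs.

    Per parameter: z = (intake - ref_mean) / ref_sd, centered percentile
    2*Phi(z) - 1 in (-1, 1), weighted by the published inflammatory effect
    score and summed.  ``drop_alcohol_energy`` removes the alcohol and energy
    parameters (the overadjustment-avoiding variant).
    """

    def __init__(self, taxonomy: FoodGroupTaxonomy | None = None,
                 drop_alcohol_energy: bool = False):
        self.taxonomy = taxonomy
        self.drop_alcohol_energy = drop_alcohol_energy

    def fit(self, X: pd.DataFrame, y=None):
        self.taxonomy_ = self.taxonomy or load_taxonomy()
        params = dict(self.taxonomy_.dii["parameters"])
        if self.drop_alcohol_energy:
            for name in self.taxonomy_.dii["alcohol_energy_parameters"]:
                params.pop(name, None)
        self.parameters_ = params
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "parameters_")
        total = np.zeros(len(X), dtype=float)
        for name, param in self.parameters_.items():
            amount = component_total(X, param["items"], f"DII parameter '{name}'")
            z = (amount - float(param["ref_mean"])) / float(param["ref_sd"])
            centered = 2.0 * norm.cdf(z) - 1.0
            total += centered * float(param["effect"])
        return total


# ----------------------------------------------------------------- PDI family

class PlantIndexScorer(BaseEstimator, TransformerMixin):
    """Plant-based diet indices over 18 food groups (each 18-90).

    Groups are quintile-scored 1-5 within the cohort; the direction of each
    group depends on the index: overall PDI rewards all plant groups and
    reverses animal groups; the healthful index (HPDI) rewards only healthy
    plant groups; the unhealthful index (UPDI) rewards only less-healthy plant
    groups.  ``transform`` returns an (n, 3) array of (pdi, hpdi, updi).
    """

    POSITIVE = {
        "pdi": ("healthy_plant", "less_healthy_plant"),
        "hpdi": ("healthy_plant",),
        "updi": ("less_healthy_plant",),
    }

    def __init__(self, taxonomy: FoodGroupTaxonomy | None = None):
        self.taxonomy = taxonomy

    def fit(self, X: pd.DataFrame, y=None):
        self.taxonomy_ = self.taxonomy or load_taxonomy()
        groups = self.taxonomy_.pdi["groups"]
        if len(groups) != 18:
            raise ConfigurationError(
                f"plant-based indices require 18 food groups, taxonomy has {len(groups)}"
            )
        self.quantilers_ = {
            name: _RankQuantiler(
                component_total(X, spec["items"], f"plant-index group '{name}'"), 5
            )
            for name, spec in groups.items()
        }
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "quantilers_")
        groups = self.taxonomy_.pdi["groups"]
        totals = {"pdi": np.zeros(len(X)), "hpdi": np.zeros(len(X)), "updi": np.zeros(len(X))}
        for name, spec in groups.items():
            amount = component_total(X, spec["items"], f"plant-index group '{name}'")
            q = self.quantilers_[name].category(amount)
            for index, positive_classes in self.POSITIVE.items():
                totals[index] += q if spec["class"] in positive_classes else 6 - q
        return np.column_stack([totals["pdi"], totals["hpdi"], totals["updi"]]).astype(float)


# -------------------------------------------------------------------- tertiles

class TertileAssigner(BaseEstimator, TransformerMixin):
    """Orientation-aware cohort tertiles of a score vector.

    ``orientation="healthy"`` labels the top tertile "healthier";
    ``orientation="unhealthy"`` (DII, UPDI) labels the bottom tertile
    "healthier".  Cuts follow the midrank-percentile rule described in the
    module docstring.
    """

    def __init__(self, orientation: str = "healthy"):
        self.orientation = orientation

    def fit(self, X, y=None):
        if self.orientation not in ("healthy", "unhealthy"):
            raise ParameterError(f"unknown orientation '{self.orientation}'")
        values = np.asarray(X, dtype=float).ravel()
        self.quantiler_ = _RankQuantiler(values, 3)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "quantiler_")
        t = self.quantiler_.category(np.asarray(X, dtype=float).ravel())
        if self.orientation == "healthy":
            labels = np.array(["unhealthier", "medium", "healthier"])
        else:
            labels = np.array(["healthier", "medium", "unhealthier"])
        return labels[t - 1]


# ------------------------------------------------------------ thin functions

def score_ahei(intakes: pd.DataFrame, taxonomy: FoodGroupTaxonomy | None = None,
               alcohol_item_removed: bool = False) -> np.ndarray:
    return AHEIScorer(taxonomy, alcohol_item_removed).fit(intakes).transform(intakes)


def score_dash(intakes: pd.DataFrame, taxonomy: FoodGroupTaxonomy | None = None) -> np.ndarray:
    return DASHScorer(taxonomy).fit(intakes).transform(intakes)


def score_med(intakes: pd.DataFrame, taxonomy: FoodGroupTaxonomy | None = None,
              alcohol_item_removed: bool = False) -> np.ndarray:
    return MEDScorer(taxonomy, alcohol_item_removed).fit(intakes).transform(intakes)


def score_dii(intakes: pd.DataFrame, taxonomy: FoodGroupTaxonomy | None = None,
              drop_alcohol_energy: bool = False) -> np.ndarray:
    return DIIScorer(taxonomy, drop_alcohol_energy).fit(intakes).transform(intakes)


def score_pdi_family(intakes: pd.DataFrame,
                     taxonomy: FoodGroupTaxonomy | None = None) -> pd.DataFrame:
    arr = PlantIndexScorer(taxonomy).fit(intakes).transform(intakes)
    return pd.DataFrame(arr, columns=["pdi", "hpdi", "updi"], index=intakes.index)


def assign_tertiles(scores: Sequence[float], orientation: str = "healthy") -> np.ndarray:
    values = np.asarray(scores, dtype=float)
    return TertileAssigner(orientation).fit(values).transform(values)


def score_all(cohort: pd.DataFrame, taxonomy: FoodGroupTaxonomy | None = None,
              alcohol_item_removed: bool = False,
              dii_drop_alcohol_energy: bool = False) -> pd.DataFrame:
    """Compute all seven indices plus orientation-aware tertile labels.

    Returns a DataFrame with one column per score and ``<score>_tertile``
    label columns, indexed like ``cohort``.
    """
    intakes = intake_frame(cohort)
    out = pd.DataFrame(index=cohort.index)
    out["ahei"] = score_ahei(intakes, taxonomy, alcohol_item_removed)
    out["dash"] = score_dash(intakes, taxonomy)
    out["med"] = score_med(intakes, taxonomy, alcohol_item_removed)
    out["dii"] = score_dii(intakes, taxonomy, dii_drop_alcohol_energy)
    out = pd.concat([out, score_pdi_family(intakes, taxonomy)], axis=1)
    for score, orientation in SCORE_ORIENTATION.items():
        out[f"{score}_tertile"] = assign_tertiles(out[score].to_numpy(), orientation)
    return out
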