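"""Cohort assembly: plausibility filters, recall averaging, imputation.

Mirrors the eligibility pipeline of a prospective diet-mortality cohort:
energy-implausible reporters are removed with fixed sex-specific kcal bounds,
repeated 24-h recalls are averaged item-wise (non-consumption counts as zero
intake), records lacking complete frailty data or mortality linkage or below
the minimum age are excluded, missing covariates are imputed explicitly, and
every step is accounted for in an exclusion cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import (
    CATEGORICAL_LEVELS,
    DEFICIT_COLUMNS,
    DIET_PREFIX,
    FP_CRITERIA_COLUMNS,
    INTEGER_LEVEL_COLUMNS,
)

# Fixed energy-plausibility bounds (kcal/day), boundaries inclusive.
ENERGY_BOUNDS = {"male": (800.0, 4200.0), "female": (600.0, 3500.0)}


@dataclass
class CascadeReport:
    """Ordered exclusion cascade: one row per filtering step."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_excluded: int) -> None:
        n_after = n_before - n_excluded
        if self.steps and self.steps[-1][3] != n_before:
            raise ParameterError(
                f"cascade step '{name}' starts at n={n_before} but previous step "
                f"ended at n={self.steps[-1][3]}"
            )
        self.steps.append((name, n_before, n_excluded, n_after))

    @property
    def final_n(self) -> int:
        return self.steps[-1][3] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "n_before", "n_excluded", "n_after"])


def filter_energy_plausibility(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into energy-plausible and excluded.

    Males are kept at 800-4200 kcal/day, females at 600-3500 (boundaries
    kept).  Records with missing sex or energy are excluded with reason
    "missing".
    """
    sex = records["sex"]
    energy = records["energy_kcal"]
    missing = sex.isna() | energy.isna() | ~sex.isin(list(ENERGY_BOUNDS))
    low = sex.map({s: b[0] for s, b in ENERGY_BOUNDS.items()})
    high = sex.map({s: b[1] for s, b in ENERGY_BOUNDS.items()})
    plausible = ~missing & (energy >= low) & (energy <= high)
    excluded = records.loc[~plausible].copy()
    excluded["exclusion_reason"] = np.where(missing[~plausible], "missing", "implausible_energy")
    return records.loc[plausible].copy(), excluded


def average_recalls(recalls: pd.DataFrame, id_col: str = "id") -> pd.DataFrame:
    """Average repeated 24-h recalls into one diet record per participant.

    ``recalls`` holds one row per (participant, recall) with ``diet_*`` intake
    columns; an item absent from a given recall is a recorded zero, so means
    run over *all* recalls.  Returns one row per participant with mean intakes
    and ``n_recalls``.
    """
    if recalls.empty:
        raise ParameterError("average_recalls requires at least one recall")
    diet_cols = [c for c in recalls.columns if c.startswith(DIET_PREFIX)]
    filled = recalls[[id_col] + diet_cols].copy()
    filled[diet_cols] = filled[diet_cols].astype(float).fillna(0.0)
    grouped = filled.groupby(id_col, sort=False)
    out = grouped.mean()
    out["n_recalls"] = grouped.size()
    return out.reset_index()


def apply_eligibility(
    records: pd.DataFrame,
    min_age: float = 45.0,
    require_complete_frailty: bool = True,
    require_mortality: bool = True,
    frailty_columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, CascadeReport]:
    """Apply the eligibility cascade in fixed order and account for every row.

    Step order: frailty completeness, mortality availability, minimum age at
    recruitment (kept iff age >= ``min_age``).
    """
    report = CascadeReport()
    kept = records

    n = len(kept)
    if require_complete_frailty:
        cols = list(frailty_columns) if frailty_columns is not None else [
            c for c in FP_CRITERIA_COLUMNS + DEFICIT_COLUMNS if c in kept.columns
        ]
        complete = ~kept[cols].isna().any(axis=1) if cols else pd.Series(True, index=kept.index)
        report.add("incomplete_frailty_data", n, int((~complete).sum()))
        kept = kept.loc[complete]
    else:
        report.add("incomplete_frailty_data", n, 0)

    n = len(kept)
    if require_mortality:
        have = kept["followup_months"].notna() & kept["event"].notna()
        report.add("missing_mortality_data", n, int((~have).sum()))
        kept = kept.loc[have]
    else:
        report.add("missing_mortality_data", n, 0)

    n = len(kept)
    old_enough = kept["age_at_recruitment"] >= min_age
    report.add(f"age_under_{min_age:g}", n, int((~old_enough).sum()))
    kept = kept.loc[old_enough]

    return kept.copy(), report


def impute_missing(
    records: pd.DataFrame,
    strategy: str = "median_mode",
    columns: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing covariate cells.

    ``median_mode`` fills numerics with the column median and categoricals
    with the most frequent level (ties broken by level order).  ``chained``
    runs chained-equation regression imputation on the numeric block
    (scikit-learn IterativeImputer) and mode-fills categoricals.

    Returns the completed frame and a per-column imputation report.
    Missingness is only expected in covariates; exposure and outcome columns
    should already be complete.
    """
    if strategy not in ("median_mode", "chained"):
        raise ParameterError(f"unknown imputation strategy '{strategy}'")
    out = records.copy()
    if columns is None:
        columns = [
            c for c in records.columns
            if c in CATEGORICAL_LEVELS or c in INTEGER_LEVEL_COLUMNS
            or c in ("age_at_recruitment", "energy_kcal")
            or c.startswith("family_history_")
        ]
    counts = {}
    numeric = [c for c in columns if pd.api.types.is_numeric_dtype(records[c])
               and c not in INTEGER_LEVEL_COLUMNS]
    other = [c for c in columns if c not in numeric]

    for col in columns:
        n_missing = int(out[col].isna().sum())
        counts[col] = n_missing
        if n_missing == len(out):
            raise ParameterError(f"column '{col}' is entirely missing; cannot impute")

    if strategy == "chained" and numeric:
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        imputer = IterativeImputer(random_state=seed, sample_posterior=False)
        out[numeric] = imputer.fit_transform(out[numeric].astype(float))
    else:
        for col in numeric:
            out[col] = out[col].fillna(out[col].median())

    for col in other:
        series = out[col]
        if series.isna().any():
            levels, freq = np.unique(series.dropna().to_numpy(), return_counts=True)
            mode = levels[np.argmax(freq)]
            out[col] = series.fillna(mode)

    report = pd.DataFrame(
        {"column": list(counts), "n_imputed": list(counts.values())}
    )
    return out, report


def landmark_exclusion(records: pd.DataFrame, years: float) -> pd.DataFrame:
    """Drop deaths within the first ``years`` of follow-up (survivors kept).

    Intended to limit reverse causation; only records with ``event`` true and
    follow-up shorter than ``12 * years`` months are removed.
    """
    if years < 0:
        raise ParameterError("landmark exclusion years must be >= 0")
    early_death = records["event"].astype(bool) & (records["followup_months"] < 12.0 * years)
    return records.loc[~early_death].copy()
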