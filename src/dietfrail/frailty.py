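"""Frailty phenotype and frailty index construction.

Two complementary operationalizations of frailty:

* the phenotype (FP): a count of five binary criteria — unintentional weight
  loss, exhaustion, weakness, slow gait speed, low physical activity —
  categorized 0 = robust, 1-2 = prefrail, >=3 = frail;
* the deficit-accumulation index (FI): the fraction of 49 health deficits
  present, categorized robust at FI <= 0.12, frail at FI >= 0.24, prefrail in
  the open interval between (the printed cutoffs overlap at the boundaries;
  closure is assigned to the outer categories so both printed inequalities
  hold).

The deficit and criterion lists themselves are configuration (named boolean
columns); this module fixes only the counting arithmetic and category
boundaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataValidationError
from .io import DEFICIT_COLUMNS, FP_CRITERIA_COLUMNS, N_DEFICITS

FI_ROBUST_MAX = 0.12
FI_FRAIL_MIN = 0.24

FRAILTY_CATEGORIES = ("robust", "prefrail", "frail")


def fp_category_from_count(count: np.ndarray) -> np.ndarray:
    """Phenotype category: 0 robust, 1-2 prefrail, >=3 frail."""
    count = np.asarray(count)
    out = np.where(count >= 3, "frail", np.where(count >= 1, "prefrail", "robust"))
    return out.astype(object)


def fi_category_from_value(value: np.ndarray) -> np.ndarray:
    """Index category: <=0.12 robust, >=0.24 frail, open interval prefrail."""
    value = np.asarray(value, dtype=float)
    out = np.where(value >= FI_FRAIL_MIN, "frail",
                   np.where(value <= FI_ROBUST_MAX, "robust", "prefrail"))
    return out.astype(object)


def _boolean_block(df: pd.DataFrame, columns, what: str) -> np.ndarray:
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"missing {what} column(s): {missing_cols}")
    block = df[list(columns)]
    if block.isna().to_numpy().any():
        bad = block.isna().any(axis=1)
        raise DataValidationError(
            f"{int(bad.sum())} record(s) with missing {what} values; "
            "incomplete records must be excluded upstream"
        )
    return block.to_numpy(dtype=bool)


def frailty_phenotype(criteria: pd.DataFrame,
                      columns=FP_CRITERIA_COLUMNS) -> pd.DataFrame:
    """Score the 5-criterion frailty phenotype.

    Returns a frame with ``fp_count`` and ``fp_category``; raises if any
    criterion is missing (such records should have been excluded upstream).
    """
    block = _boolean_block(criteria, columns, "frailty phenotype criterion")
    count = block.sum(axis=1)
    return pd.DataFrame(
        {"fp_count": count, "fp_category": fp_category_from_count(count)},
        index=criteria.index,
    )


def frailty_index(deficits: pd.DataFrame, columns=DEFICIT_COLUMNS) -> pd.DataFrame:
    """Score the 49-deficit frailty index (present deficits / 49)."""
    if len(columns) != N_DEFICITS:
        raise DataValidationError(
            f"frailty index requires exactly {N_DEFICITS} deficit columns, got {len(columns)}"
        )
    block = _boolean_block(deficits, columns, "deficit")
    value = block.sum(axis=1) / float(N_DEFICITS)
    return pd.DataFrame(
        {"fi_value": value, "fi_category": fi_category_from_value(value)},
        index=deficits.index,
    )


def assess_frailty(cohort: pd.DataFrame,
                   criteria_columns=FP_CRITERIA_COLUMNS,
                   deficit_columns=DEFICIT_COLUMNS) -> pd.DataFrame:
    """Full frailty assessment (phenotype + index) for a cohort table."""
    fp = frailty_phenotype(cohort, criteria_columns)
    fi = frailty_index(cohort, deficit_columns)
    return pd.concat([fp, fi], axis=1)


class FrailtyPhenotype(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`frailty_phenotype`."""

    def __init__(self, columns=FP_CRITERIA_COLUMNS):
        self.columns = columns

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return frailty_phenotype(X, self.columns)


class FrailtyIndex(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`frailty_index`."""

    def __init__(self, columns=DEFICIT_COLUMNS):
        self.columns = columns

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return frailty_index(X, self.columns)
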