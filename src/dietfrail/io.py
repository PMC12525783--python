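"""Data model and delimited-text IO for cohort and mortality-rate tables.

The canonical in-memory containers are pandas DataFrames with a fixed column
vocabulary.  ``CohortSchema`` maps arbitrary source column names onto the
canonical names so files exported from any fieldwork database can feed the
pipeline.  Validation is total: a row with an out-of-domain categorical value
or an unparseable numeric is routed to a rejects report rather than silently
coerced.  Missing covariate cells are permitted at read time (imputation is a
separate, explicit assembly step); missingness in exposure or outcome columns
is handled by the eligibility filters.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataValidationError

logger = logging.getLogger("dietfrail")

SEXES = ("female", "male")

#: Level sets for every categorical participant field.  ``center`` defaults to
#: country granularity but finer site codes may be declared via the schema.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": SEXES,
    "center": ("England", "Wales", "Scotland"),
    "bmi_category": ("<25.0", "25.0-29.9", ">=30.0"),
    "ethnicity": ("white", "other"),
    "education": ("degree", "secondary", "primary", "professional"),
    "employment": ("employed", "other"),
    "income": ("<18000", "18000-30999", "31000-51999", "52000-100000", ">100000"),
    "smoking": ("never", "previous", "current"),
    "alcohol_freq": (">=3/week", "<3/week", "never"),
    "sleep": ("7-8h", "<7h", ">8h"),
    "physical_activity": ("high", "moderate", "low"),
}

BOOLEAN_COLUMNS = (
    "family_history_cvd",
    "family_history_cancer",
    "family_history_diabetes",
    "event",
)

NUMERIC_COLUMNS = ("age_at_recruitment", "energy_kcal", "followup_months")

#: townsend_quartile is an integer-coded categorical.
INTEGER_LEVEL_COLUMNS: dict[str, tuple[int, ...]] = {"townsend_quartile": (1, 2, 3, 4)}

REQUIRED_COLUMNS = (
    ("id",)
    + tuple(CATEGORICAL_LEVELS)
    + tuple(INTEGER_LEVEL_COLUMNS)
    + BOOLEAN_COLUMNS
    + NUMERIC_COLUMNS
)

#: Canonical frailty phenotype criterion columns (boolean).
FP_CRITERIA_COLUMNS = (
    "fp_weight_loss",
    "fp_exhaustion",
    "fp_weakness",
    "fp_slow_gait",
    "fp_low_activity",
)

N_DEFICITS = 49
DEFICIT_COLUMNS = tuple(f"deficit_{i:02d}" for i in range(1, N_DEFICITS + 1))

DIET_PREFIX = "diet_"


@dataclass
class CohortSchema:
    """Column mapping from source file names to canonical names.

    ``columns`` maps canonical -> source column name; canonical names missing
    from the mapping are assumed to appear verbatim in the file.  ``center_levels``
    may widen the accepted assessment-center codes (e.g. 22 site codes instead
    of 3 countries).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    center_levels: Sequence[str] | None = None

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def levels_for(self, canonical: str) -> tuple[str, ...]:
        if canonical == "center" and self.center_levels is not None:
            return tuple(self.center_levels)
        return CATEGORICAL_LEVELS[canonical]


@dataclass
class AnalysisConfig:
    """Run-wide analysis settings (sensitivity toggles, model knobs)."""

    scores: tuple[str, ...] = ("ahei",)
    frailty_measures: tuple[str, ...] = ("fi",)
    alcohol_item_removed: bool = False
    dii_drop_alcohol_energy: bool = False
    landmark_exclusion_years: float = 0.0
    min_age: float = 45.0
    age_strata_width_years: int = 5
    n_bootstrap: int = 10_000
    seed: int = 0
    knot_percentiles: tuple[float, ...] = (5.0, 35.0, 65.0, 95.0)
    covariates: tuple[str, ...] = (
        "sex",
        "bmi_category",
        "smoking",
        "physical_activity",
        "energy_kcal",
    )
    imputation_strategy: str = "median_mode"

    def __post_init__(self) -> None:
        kp = tuple(float(p) for p in self.knot_percentiles)
        if not all(0.0 < p < 100.0 for p in kp):
            raise ConfigurationError("knot_percentiles must lie strictly inside (0, 100)")
        if any(b <= a for a, b in zip(kp, kp[1:])):
            raise ConfigurationError("knot_percentiles must be strictly increasing")
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")
        if self.landmark_exclusion_years < 0:
            raise ConfigurationError("landmark_exclusion_years must be >= 0")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("scores", "frailty_measures", "knot_percentiles", "covariates"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = series.astype("string").str.strip().str.lower().map(mapping)
    return out


def read_cohort(
    path: str | Path,
    schema: CohortSchema | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a participant-level cohort table.

    Parameters
    ----------
    path
        Comma- or tab-delimited text file with a header row.
    schema
        Optional column mapping; canonical names are used as-is when absent.

    Returns
    -------
    cohort, rejects
        ``cohort`` holds the validated rows under canonical column names with
        canonical dtypes.  ``rejects`` reports each rejected source row
        (0-based ``row`` index within the file body) with a ``reason``.

    Raises
    ------
    ConfigurationError
        If a required column is absent from the file.
    """
    path = Path(path)
    schema = schema or CohortSchema()
    raw = pd.read_csv(path, sep=_detect_sep(path), dtype="string")

    rename = {}
    missing = []
    for canonical in REQUIRED_COLUMNS:
        src = schema.source_name(canonical)
        if src not in raw.columns:
            missing.append(src)
        else:
            rename[src] = canonical
    if missing:
        raise ConfigurationError(f"required column(s) missing from {path.name}: {missing}")
    # Optional blocks pass through under their canonical names.
    for canonical in FP_CRITERIA_COLUMNS + DEFICIT_COLUMNS + ("n_recalls",):
        src = schema.source_name(canonical)
        if src in raw.columns:
            rename[src] = canonical
    for col in raw.columns:
        if col.startswith(DIET_PREFIX) and col not in rename:
            rename[col] = col
    df = raw.rename(columns=rename)[list(rename.values())].copy()

    bad_reason = pd.Series("", index=df.index, dtype="string")

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (bad_reason == "")
        bad_reason[fresh] = reason

    for col, levels in INTEGER_LEVEL_COLUMNS.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(df[col].notna() & ~vals.isin(levels), f"invalid value in '{col}'")
        df[col] = vals.astype("Int64")
    for col in CATEGORICAL_LEVELS:
        levels = schema.levels_for(col)
        flag(df[col].notna() & ~df[col].isin(levels), f"invalid value in '{col}'")
    for col in BOOLEAN_COLUMNS:
        coerced = _coerce_bool(df[col])
        flag(df[col].notna() & coerced.isna(), f"unparseable boolean in '{col}'")
        df[col] = coerced.astype("boolean")
    for col in FP_CRITERIA_COLUMNS + DEFICIT_COLUMNS:
        if col in df.columns:
            coerced = _coerce_bool(df[col])
            flag(df[col].notna() & coerced.isna(), f"unparseable boolean in '{col}'")
            df[col] = coerced.astype("boolean")
    numeric_cols = list(NUMERIC_COLUMNS) + [c for c in df.columns if c.startswith(DIET_PREFIX)]
    if "n_recalls" in df.columns:
        numeric_cols.append("n_recalls")
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(df[col].notna() & vals.isna(), f"unparseable numeric in '{col}'")
        # re-parse from text for exact (correctly rounded) float round-trips
        df[col] = df[col].where(vals.notna()).astype(float)
    flag(df["age_at_recruitment"].notna() & (df["age_at_recruitment"] < 0), "negative age")
    flag(df["followup_months"].notna() & (df["followup_months"] < 0), "negative followup")
    flag(df["energy_kcal"].notna() & (df["energy_kcal"] <= 0), "non-positive energy")

    bad = bad_reason != ""
    rejects = pd.DataFrame(
        {"row": np.flatnonzero(bad.to_numpy()), "id": df.loc[bad, "id"].to_numpy(),
         "reason": bad_reason[bad].to_numpy()}
    )
    cohort = df.loc[~bad].reset_index(drop=True)
    if len(rejects):
        logger.warning("read_cohort: rejected %d of %d rows", len(rejects), len(df))
    return cohort, rejects


def write_cohort(cohort: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a cohort table as delimited text (booleans as 0/1)."""
    out = cohort.copy()
    for col in out.columns:
        if str(out[col].dtype) in ("bool", "boolean"):
            out[col] = out[col].astype("Int64")
    out.to_csv(path, sep=sep, index=False)


def read_mortality_rates(path: str | Path) -> pd.DataFrame:
    """Read an ONS-style sex- and age-specific mortality-rate table.

    The file must carry columns ``sex, age, q`` covering the complete grid of
    both sexes by integer ages 50..100, with every annual death probability
    ``q`` inside [0, 1].

    Returns a DataFrame sorted by (sex, age).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    for col in ("sex", "age", "q"):
        if col not in df.columns:
            raise ConfigurationError(f"mortality table missing required column '{col}'")
    df["sex"] = df["sex"].astype(str)
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise DataValidationError(f"unknown sex value(s) in mortality table: {sorted(bad_sex)}")
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
    df["q"] = pd.to_numeric(df["q"], errors="raise").astype(float)
    out_of_range = df[(df["q"] < 0) | (df["q"] > 1)]
    if len(out_of_range):
        row = out_of_range.iloc[0]
        raise DataValidationError(
            f"mortality probability out of [0, 1]: q={row['q']} at ({row['sex']}, {row['age']})"
        )
    expected = {(s, a) for s in SEXES for a in range(50, 101)}
    present = set(zip(df["sex"], df["age"]))
    missing = sorted(expected - present)
    if missing:
        sex, age = missing[0]
        raise DataValidationError(f"mortality table missing ({sex}, {age})")
    dupes = df.duplicated(subset=["sex", "age"])
    if dupes.any():
        raise DataValidationError("duplicate (sex, age) rows in mortality table")
    return df.sort_values(["sex", "age"]).reset_index(drop=True)


def write_mortality_rates(rates: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    rates[["sex", "age", "q"]].to_csv(path, sep=sep, index=False)


def mortality_q_vector(rates: pd.DataFrame, sex: str) -> np.ndarray:
    """Return q(50..100) for one sex as a length-51 array."""
    sub = rates[rates["sex"] == sex].sort_values("age")
    return sub["q"].to_numpy(dtype=float)


def setup_logging(level: int = logging.INFO) -> None:
    """Configure package logging to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
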