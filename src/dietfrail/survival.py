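"""Stratified proportional-hazards models for the joint diet-frailty analysis.

Fits Cox models with Efron tie handling and baseline stratification by age
band and assessment center (the covariates that typically violate
proportionality), via lifelines behind a scikit-learn-style estimator.  On
top of the basic fit this module provides the joint 3x3 exposure encoding,
multiplicative interaction by likelihood-ratio test, additive interaction as
the relative excess risk due to interaction (RERI) with a delta-method CI,
an ordinal trend test, restricted-cubic-spline dose-response curves, and a
scaled-Schoenfeld proportionality diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import FitError, ParameterError
from .io import CATEGORICAL_LEVELS
from .simulate import DIET_TERTILES, FRAILTY_CATEGORIES, JOINT_GROUPS, REFERENCE_GROUP

Z_95 = 1.96  # reported CIs are exp(beta +/- 1.96 se)


# ------------------------------------------------------------------ results

@dataclass
class HRSet:
    """Coefficients, covariance and fit statistics from a stratified Cox fit."""

    terms: list[str]
    beta: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int
    exposure: str | None = None
    reference: str | None = None
    exposure_levels: tuple[str, ...] = ()
    unavailable_levels: tuple[str, ...] = ()
    model: CoxPHFitter | None = field(default=None, repr=False)
    design: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.beta)

    def summary_frame(self) -> pd.DataFrame:
        """Per-term HR table with 95% Wald CIs (reference level HR = 1)."""
        rows = []
        if self.exposure is not None:
            rows.append({"term": f"{self.exposure}={self.reference}", "beta": 0.0,
                         "se": 0.0, "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                         "reference": True})
        for term in self.terms:
            b, s = self.beta[term], self.se[term]
            rows.append({"term": term, "beta": b, "se": s, "hr": float(np.exp(b)),
                         "ci_low": float(np.exp(b - Z_95 * s)),
                         "ci_high": float(np.exp(b + Z_95 * s)),
                         "reference": False})
        for level in self.unavailable_levels:
            rows.append({"term": f"{self.exposure}={level}", "beta": np.nan,
                         "se": np.nan, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "reference": False})
        return pd.DataFrame(rows)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


@dataclass
class RERIResult:
    """Relative excess risk due to interaction with delta-method 95% CI."""

    reri: float
    se: float | None
    ci_low: float | None
    ci_high: float | None
    method: str = "delta"


@dataclass
class SplineCurve:
    """Restricted-cubic-spline log-HR curve relative to a reference score."""

    knots: np.ndarray
    basis_dim: int
    grid: np.ndarray
    log_hr: np.ndarray
    se: np.ndarray
    ref_value: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.log_hr - Z_95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.log_hr + Z_95 * self.se)


# -------------------------------------------------------------- design build

def _categorical_levels(series: pd.Series, name: str) -> list[str]:
    if name in CATEGORICAL_LEVELS:
        declared = [lv for lv in CATEGORICAL_LEVELS[name] if lv in set(series)]
        if declared:
            return declared
    return sorted(pd.unique(series.dropna()).tolist())


def encode_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Indicator-encode categoricals (first level reference), pass numerics."""
    blocks = []
    for col in covariates:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series) and col not in ("townsend_quartile",):
            blocks.append(series.astype(float).rename(col))
        else:
            levels = _categorical_levels(series.astype(str) if not
                                         pd.api.types.is_numeric_dtype(series) else series,
                                         col)
            values = series if pd.api.types.is_numeric_dtype(series) else series.astype(str)
            for level in levels[1:]:
                blocks.append((values == level).astype(float).rename(f"{col}={level}"))
    if not blocks:
        return pd.DataFrame(index=df.index)
    return pd.concat(blocks, axis=1)


def _age_band(age: pd.Series, width: int) -> pd.Series:
    return (np.floor(age.astype(float) / width) * width).astype(int)


def _fit_lifelines(design: pd.DataFrame, duration_col: str, event_col: str,
                   strata: Sequence[str] | None) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=duration_col, event_col=event_col,
                    strata=list(strata) if strata else None,
                    fit_options={"precision": 1e-9})
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise FitError(f"Cox partial-likelihood fit failed: {exc}") from exc
    return cph


# ----------------------------------------------------------------- estimator

class StratifiedCoxPH(BaseEstimator):
    """Cox proportional-hazards model with baseline stratification.

    Parameters
    ----------
    exposure
        Categorical column encoded as indicator contrasts against
        ``reference``.  ``None`` fits covariates only (used for spline and
        trend designs where the columns are prebuilt).
    covariates
        Additional adjustment columns; categoricals are indicator-encoded.
    strata
        Columns defining baseline-hazard strata (e.g. assessment center).
    age_col / age_band_years
        When ``age_col`` is given, a ``age_band_years``-wide age band is
        added to the strata (default 5-year bands).

    Fitted attributes follow sklearn conventions: ``params_``, ``cov_``,
    ``hrset_`` etc.  Exposure levels with zero events are not estimable under
    the partial likelihood and are reported in ``hrset_.unavailable_levels``
    (their rows are withheld from the fit) rather than returned as infinite
    estimates.
    """

    def __init__(self, exposure: str | None = "joint_group",
                 reference: str | None = REFERENCE_GROUP,
                 covariates: Sequence[str] = (),
                 strata: Sequence[str] = (),
                 age_col: str | None = None,
                 age_band_years: int = 5,
                 duration_col: str = "followup_months",
                 event_col: str = "event"):
        self.exposure = exposure
        self.reference = reference
        self.covariates = covariates
        self.strata = strata
        self.age_col = age_col
        self.age_band_years = age_band_years
        self.duration_col = duration_col
        self.event_col = event_col

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        event = df[self.event_col].astype(bool)
        unavailable: tuple[str, ...] = ()
        levels: tuple[str, ...] = ()
        blocks = []
        keep = pd.Series(True, index=df.index)

        if self.exposure is not None:
            exp_series = df[self.exposure].astype(str)
            observed = pd.unique(exp_series).tolist()
            if len(observed) < 2:
                raise FitError(
                    f"exposure '{self.exposure}' takes a single value; no estimable contrast"
                )
            reference = self.reference if self.reference is not None else observed[0]
            if reference not in observed:
                raise FitError(f"reference level '{reference}' absent from exposure")
            canonical = [g for g in JOINT_GROUPS if g in observed]
            ordered = canonical if len(canonical) == len(observed) else \
                [reference] + sorted(lv for lv in observed if lv != reference)
            events_by_level = event.groupby(exp_series, sort=False).sum()
            dead_levels = tuple(lv for lv in ordered
                                if lv != reference and events_by_level.get(lv, 0) == 0)
            if dead_levels:
                keep &= ~exp_series.isin(dead_levels)
            unavailable = dead_levels
            levels = tuple(lv for lv in ordered if lv not in dead_levels)
            for lv in levels:
                if lv != reference:
                    blocks.append((exp_series == lv).astype(float)
                                  .rename(f"{self.exposure}={lv}"))

        cov_block = encode_covariates(df, self.covariates)
        if len(cov_block.columns):
            blocks.append(cov_block)

        design = pd.concat(blocks + [df[self.duration_col].astype(float),
                                     event.astype(int)], axis=1)
        strata_cols = list(self.strata)
        if self.age_col is not None:
            design["_age_band"] = _age_band(df[self.age_col], self.age_band_years)
            strata_cols.append("_age_band")
        for col in self.strata:
            design[col] = df[col].to_numpy()
        design = design.loc[keep]

        cph = _fit_lifelines(design, self.duration_col, self.event_col, strata_cols)

        terms = list(cph.params_.index)
        beta = cph.params_.astype(float)
        cov = cph.variance_matrix_.astype(float)
        se = pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=terms)
        loglik = float(cph.log_likelihood_)
        k = len(terms)
        n_events = int(design[self.event_col].sum())
        aic = 2.0 * k - 2.0 * loglik
        bic = k * np.log(n_events) - 2.0 * loglik

        self.params_ = beta
        self.cov_ = cov
        self.standard_errors_ = se
        self.log_likelihood_ = loglik
        self.AIC_ = aic
        self.BIC_ = bic
        self.n_ = int(len(design))
        self.n_events_ = n_events
        self.model_ = cph
        self.design_ = design
        self.strata_cols_ = strata_cols
        self.hrset_ = HRSet(
            terms=terms, beta=beta, se=se, cov=cov, loglik=loglik, aic=aic,
            bic=bic, n=self.n_, n_events=n_events, exposure=self.exposure,
            reference=self.reference if self.exposure is not None else None,
            exposure_levels=levels, unavailable_levels=unavailable,
            model=cph, design=design,
        )
        return self

    def predict_partial_hazard(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        shared = [c for c in self.design_.columns if c in X.columns]
        return self.model_.predict_partial_hazard(X[shared]).to_numpy()


def fit_cox(df: pd.DataFrame, exposure: str | None = "joint_group",
            reference: str | None = REFERENCE_GROUP,
            covariates: Sequence[str] = (), strata: Sequence[str] = (),
            age_col: str | None = None, age_band_years: int = 5,
            duration_col: str = "followup_months", event_col: str = "event") -> HRSet:
    """Fit a stratified Cox model and return its :class:`HRSet`."""
    est = StratifiedCoxPH(exposure, reference, covariates, strata, age_col,
                          age_band_years, duration_col, event_col)
    return est.fit(df).hrset_


# -------------------------------------------------------------- joint groups

def joint_groups(diet_tertile: pd.Series, frailty_category: pd.Series) -> pd.Series:
    """Combine diet tertile and frailty category into the 9-cell exposure.

    Labels are ``<tertile>_<category>``; the reference cell is
    ``healthier_robust``.
    """
    diet = pd.Series(diet_tertile).astype("string")
    frail = pd.Series(frailty_category).astype("string")
    if diet.isna().any() or frail.isna().any():
        raise ParameterError("joint_groups: missing diet tertile or frailty category")
    bad_diet = set(diet) - set(DIET_TERTILES)
    bad_frail = set(frail) - set(FRAILTY_CATEGORIES)
    if bad_diet or bad_frail:
        raise ParameterError(
            f"joint_groups: unknown labels {sorted(bad_diet | bad_frail)}")
    return (diet + "_" + frail).astype(object).rename("joint_group")


# ---------------------------------------------------------------- interaction

def likelihood_ratio_test(loglik_full: float, loglik_reduced: float, df: int) -> LRTResult:
    if df < 0 or loglik_full < loglik_reduced - 1e-8:
        raise ParameterError("models are not nested (full log-likelihood below reduced)")
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(stat, df, p, loglik_full, loglik_reduced)


def multiplicative_interaction(
    df: pd.DataFrame, diet_col: str, frailty_col: str,
    covariates: Sequence[str] = (), strata: Sequence[str] = (),
    age_col: str | None = None, age_band_years: int = 5,
    duration_col: str = "followup_months", event_col: str = "event",
) -> LRTResult:
    """LRT for diet-by-frailty product terms on the log-hazard scale.

    Compares the main-effects model against the model with all cross-product
    indicator terms; the degrees of freedom equal the number of product
    columns.
    """
    work = df.copy()
    main_terms: list[str] = []
    product_terms: list[str] = []
    for col, ref_excluded in ((diet_col, None), (frailty_col, None)):
        levels = _categorical_levels(work[col].astype(str), col)
        for lv in levels[1:]:
            name = f"{col}={lv}"
            work[name] = (work[col].astype(str) == lv).astype(float)
            main_terms.append(name)
    diet_terms = [t for t in main_terms if t.startswith(f"{diet_col}=")]
    frail_terms = [t for t in main_terms if t.startswith(f"{frailty_col}=")]
    for dt in diet_terms:
        for ft in frail_terms:
            name = f"{dt}*{ft}"
            work[name] = work[dt] * work[ft]
            product_terms.append(name)

    common = dict(exposure=None, reference=None, strata=strata, age_col=age_col,
                  age_band_years=age_band_years, duration_col=duration_col,
                  event_col=event_col)
    reduced = fit_cox(work, covariates=main_terms + list(covariates), **common)
    full = fit_cox(work, covariates=main_terms + product_terms + list(covariates),
                   **common)
    return likelihood_ratio_test(full.loglik, reduced.loglik, len(product_terms))


def additive_interaction_reri(
    beta: Sequence[float],
    cov: np.ndarray | None = None,
    method: str = "delta",
    n_boot: int = 10_000,
    seed: int = 0,
) -> RERIResult:
    """RERI = HR11 - HR10 - HR01 + 1 from log-HRs (b10, b01, b11).

    ``beta`` holds the log-HRs of the two single exposures and the double
    exposure against the common unexposed reference; ``cov`` their 3x3
    covariance.  The CI is delta-method on the exp-transformed coefficients
    by default, or a parametric bootstrap (``method="bootstrap"``).  With no
    covariance the point estimate alone is returned.
    """
    b = np.asarray(beta, dtype=float)
    if b.shape != (3,):
        raise ParameterError("additive_interaction_reri expects exactly 3 log-HRs")
    hr10, hr01, hr11 = np.exp(b)
    reri = float(hr11 - hr10 - hr01 + 1.0)
    if cov is None:
        return RERIResult(reri, None, None, None, method="point")
    cov = np.asarray(cov, dtype=float)
    if method == "delta":
        grad = np.array([-hr10, -hr01, hr11])
        var = float(grad @ cov @ grad)
        se = float(np.sqrt(max(var, 0.0)))
        return RERIResult(reri, se, reri - Z_95 * se, reri + Z_95 * se, "delta")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(b, cov, size=n_boot)
        vals = (np.exp(draws[:, 2]) - np.exp(draws[:, 0])
                - np.exp(draws[:, 1]) + 1.0)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return RERIResult(reri, float(np.std(vals, ddof=1)), float(lo), float(hi),
                          "bootstrap")
    raise ParameterError(f"unknown RERI CI method '{method}'")


def reri_from_corner_cells(hrset: HRSet, g10: str, g01: str, g11: str,
                           method: str = "delta", seed: int = 0) -> RERIResult:
    """RERI from three joint-group terms of a fitted 9-group (or 2x2) model."""
    terms = [f"{hrset.exposure}={g}" for g in (g10, g01, g11)]
    missing = [t for t in terms if t not in hrset.beta.index]
    if missing:
        raise ParameterError(f"corner cell term(s) not in fit: {missing}")
    beta = hrset.beta[terms].to_numpy()
    cov = hrset.cov.loc[terms, terms].to_numpy()
    return additive_interaction_reri(beta, cov, method=method, seed=seed)


# ---------------------------------------------------------------------- trend

def trend_test(df: pd.DataFrame, exposure: str, ordered_levels: Sequence[str],
               covariates: Sequence[str] = (), strata: Sequence[str] = (),
               age_col: str | None = None, age_band_years: int = 5,
               duration_col: str = "followup_months",
               event_col: str = "event") -> tuple[float, HRSet]:
    """Wald p-for-trend from an integer-scored ordinal exposure coding.

    Levels are scored 0, 1, 2, ... in the stated order and entered as a
    single term; returns (p-value, fit).
    """
    if len(ordered_levels) < 3:
        raise ParameterError("trend test requires at least 3 ordered exposure levels")
    codes = {lv: float(i) for i, lv in enumerate(ordered_levels)}
    work = df.copy()
    work["_trend"] = work[exposure].astype(str).map(codes)
    if work["_trend"].isna().any():
        bad = sorted(set(work.loc[work["_trend"].isna(), exposure].astype(str)))
        raise ParameterError(f"exposure value(s) outside ordered levels: {bad}")
    hrset = fit_cox(work, exposure=None, reference=None,
                    covariates=["_trend"] + list(covariates), strata=strata,
                    age_col=age_col, age_band_years=age_band_years,
                    duration_col=duration_col, event_col=event_col)
    z = hrset.beta["_trend"] / hrset.se["_trend"]
    p = float(2.0 * stats.norm.sf(abs(z)))
    return p, hrset


# -------------------------------------------------------------------- splines

def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form, Harrell scaling).

    k knots yield k-1 columns: the linear term plus k-2 cubic terms each of
    the form

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which makes the expansion linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if len(t) < 3:
        raise ParameterError("restricted cubic splines require at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ParameterError(
            "coincident or unsorted knots; the score has too few distinct values "
            "at the requested percentiles - use fewer knots")
    scale = (t[-1] - t[0]) ** 2

    def plus3(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(len(t) - 2):
        term = (plus3(x - t[j])
                - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])) / scale
        cols.append(term)
    return np.column_stack(cols)


def rcs_dose_response(
    df: pd.DataFrame, score_col: str,
    covariates: Sequence[str] = (), strata: Sequence[str] = (),
    age_col: str | None = None, age_band_years: int = 5,
    knot_percentiles: Sequence[float] = (5.0, 35.0, 65.0, 95.0),
    ref_value: float | None = None, grid: np.ndarray | None = None,
    duration_col: str = "followup_months", event_col: str = "event",
) -> tuple[SplineCurve, HRSet]:
    """Spline dose-response curve of the log-HR against a continuous score.

    Knots sit at the stated percentiles of the observed score; the curve is
    reported relative to ``ref_value`` (cohort median by default) with
    delta-method pointwise CIs.
    """
    x = df[score_col].to_numpy(dtype=float)
    if len(np.unique(x)) < len(knot_percentiles):
        raise ParameterError("score has fewer distinct values than requested knots")
    knots = np.percentile(x, list(knot_percentiles))
    basis = rcs_basis(x, knots)
    names = [f"{score_col}_rcs{i}" for i in range(basis.shape[1])]
    work = df.copy()
    work[names] = basis
    hrset = fit_cox(work, exposure=None, reference=None,
                    covariates=names + list(covariates), strata=strata,
                    age_col=age_col, age_band_years=age_band_years,
                    duration_col=duration_col, event_col=event_col)
    if ref_value is None:
        ref_value = float(np.median(x))
    if grid is None:
        grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 100)
    grid = np.asarray(grid, dtype=float)
    contrast = rcs_basis(grid, knots) - rcs_basis(np.full_like(grid, ref_value), knots)
    beta = hrset.beta[names].to_numpy()
    cov = hrset.cov.loc[names, names].to_numpy()
    log_hr = contrast @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, cov, contrast).clip(min=0.0))
    curve = SplineCurve(knots=knots, basis_dim=basis.shape[1], grid=grid,
                        log_hr=log_hr, se=se, ref_value=ref_value)
    return curve, hrset


# ----------------------------------------------------------------- PH checks

def ph_diagnostics(fit: StratifiedCoxPH | HRSet) -> pd.DataFrame:
    """Scaled-Schoenfeld proportionality test per term, plus a global row.

    Advisory output: per-term chi-square statistics and p-values for
    correlation of the scaled Schoenfeld residuals with (rank) time, and a
    global test summing the per-term statistics.  An empty frame is returned
    for a fit with no covariates.
    """
    hrset = fit.hrset_ if isinstance(fit, StratifiedCoxPH) else fit
    if not hrset.terms:
        return pd.DataFrame(columns=["term", "statistic", "p"])
    if hrset.model is None or hrset.design is None:
        raise ParameterError("fit does not retain residual inputs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = proportional_hazard_test(hrset.model, hrset.design,
                                          time_transform="rank")
    summary = result.summary
    stat = summary["test_statistic"]
    rows = [{"term": term, "statistic": float(stat.loc[term].iloc[0])
             if isinstance(stat.loc[term], pd.Series) else float(stat.loc[term]),
             "p": float(summary["p"].loc[term].iloc[0])
             if isinstance(summary["p"].loc[term], pd.Series)
             else float(summary["p"].loc[term])}
            for term in hrset.terms]
    total = sum(r["statistic"] for r in rows)
    rows.append({"term": "GLOBAL", "statistic": total,
                 "p": float(stats.chi2.sf(total, len(hrset.terms)))})
    return pd.DataFrame(rows)
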