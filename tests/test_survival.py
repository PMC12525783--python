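import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from dietfrail import (
    FitError,
    ParameterError,
    additive_interaction_reri,
    fit_cox,
    joint_groups,
    likelihood_ratio_test,
    multiplicative_interaction,
    ph_diagnostics,
    rcs_basis,
    rcs_dose_response,
    trend_test,
)
from dietfrail.simulate import (
    DEFAULT_TRUE_LOG_HR,
    TruthParams,
    generate_survival,
    sample_joint_groups,
)
from dietfrail.survival import HRSet, StratifiedCoxPH


def _group_cohort(n, seed, true_log_hr=None, baseline=8e-4, covariate_effects=None):
    rng = np.random.default_rng(seed)
    params = TruthParams(
        n=n, seed=seed,
        true_log_hr=true_log_hr or dict(DEFAULT_TRUE_LOG_HR),
        baseline_hazard=baseline,
        covariate_effects=covariate_effects if covariate_effects is not None else {},
    )
    df = pd.DataFrame({"joint_group": sample_joint_groups(n, rng=rng)})
    df["sex"] = rng.choice(["female", "male"], n)
    df["age_at_recruitment"] = rng.uniform(45, 70, n)
    return generate_survival(df, params, rng=rng), params


# ------------------------------------------------------------------ joint cells

def test_joint_groups_labels_and_partition():
    diet = pd.Series(["healthier", "unhealthier", "medium"])
    frail = pd.Series(["robust", "frail", "prefrail"])
    out = joint_groups(diet, frail)
    assert out.tolist() == ["healthier_robust", "unhealthier_frail", "medium_prefrail"]

    df, _ = _group_cohort(500, 1)
    counts = df["joint_group"].value_counts()
    assert counts.sum() == 500 and len(counts) == 9

    with pytest.raises(ParameterError):
        joint_groups(pd.Series(["healthier", None]), pd.Series(["robust", "frail"]))
    with pytest.raises(ParameterError):
        joint_groups(pd.Series(["best"]), pd.Series(["robust"]))


# ------------------------------------------------------------------- Cox fitting

def test_partial_likelihood_matches_hand_enumeration_on_tiny_data():
    # 6 records, one binary covariate, no ties: the estimate must maximize
    # the explicitly enumerated risk-set product.
    df = pd.DataFrame({
        "followup_months": [2.0, 3.5, 5.0, 7.0, 8.5, 10.0],
        "event": [True, False, True, True, False, True],
        "x": [1.0, 1.0, 0.0, 1.0, 0.0, 0.0],
    })

    def neg_log_pl(beta):
        order = np.argsort(df["followup_months"].to_numpy())
        t = df["followup_months"].to_numpy()[order]
        d = df["event"].to_numpy()[order]
        x = df["x"].to_numpy()[order]
        ll = 0.0
        for i in range(len(t)):
            if d[i]:
                risk = x[i:]  # later exit times: still at risk
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
        return -ll

    brute = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded",
                            options={"xatol": 1e-10})
    hrset = fit_cox(df, exposure=None, covariates=["x"])
    assert hrset.beta["x"] == pytest.approx(brute.x, abs=1e-6)
    assert hrset.loglik == pytest.approx(-neg_log_pl(brute.x), abs=1e-8)


def test_cox_recovers_known_hazard_ratio():
    truth = dict(DEFAULT_TRUE_LOG_HR)
    truth["unhealthier_frail"] = np.log(2.0)
    df, _ = _group_cohort(20_000, 31, true_log_hr=truth,
                          covariate_effects={"sex:male": 0.45})
    hrset = fit_cox(df, covariates=["sex"], age_col="age_at_recruitment")
    term = "joint_group=unhealthier_frail"
    assert abs(hrset.beta[term] - np.log(2.0)) < 3 * hrset.se[term]
    # reference group is never among the fitted terms (HR identically 1)
    assert "joint_group=healthier_robust" not in hrset.beta.index
    summary = hrset.summary_frame()
    ref_row = summary[summary["reference"]]
    assert ref_row["hr"].iloc[0] == 1.0


def test_constant_exposure_is_an_explicit_error():
    df, _ = _group_cohort(100, 2)
    df["joint_group"] = "healthier_robust"
    with pytest.raises(FitError, match="single value"):
        fit_cox(df)


def test_zero_event_group_reported_unavailable_not_infinite():
    df, _ = _group_cohort(2_000, 4)
    mask = df["joint_group"] == "medium_frail"
    df.loc[mask, "event"] = False
    hrset = fit_cox(df)
    assert "medium_frail" in hrset.unavailable_levels
    summary = hrset.summary_frame()
    row = summary[summary["term"] == "joint_group=medium_frail"]
    assert np.isnan(row["hr"].iloc[0])


def test_information_criteria_consistent_with_loglik():
    df, _ = _group_cohort(3_000, 6)
    hrset = fit_cox(df)
    k = len(hrset.terms)
    assert hrset.aic == pytest.approx(2 * k - 2 * hrset.loglik)
    assert hrset.bic == pytest.approx(k * np.log(hrset.n_events) - 2 * hrset.loglik)


def test_hazard_ratios_invariant_to_time_rescaling():
    df, _ = _group_cohort(2_000, 13)
    months = fit_cox(df)
    years = df.copy()
    years["followup_months"] = years["followup_months"] / 12.0
    refit = fit_cox(years)
    np.testing.assert_allclose(months.beta.to_numpy(), refit.beta.to_numpy(),
                               atol=1e-6)


def test_estimator_follows_sklearn_conventions():
    df, _ = _group_cohort(1_000, 5)
    est = StratifiedCoxPH(covariates=("sex",), age_col="age_at_recruitment")
    assert est.get_params()["age_band_years"] == 5
    cloned = est.set_params(age_band_years=10)
    fitted = cloned.fit(df)
    for attr in ("params_", "cov_", "log_likelihood_", "AIC_", "BIC_", "n_events_"):
        assert hasattr(fitted, attr)


# ------------------------------------------------------------------ interaction

def test_lrt_identical_models_give_zero_statistic_p_one():
    result = likelihood_ratio_test(-120.5, -120.5, 0)
    assert result.statistic == 0.0 and result.p_value == 1.0
    with pytest.raises(ParameterError):
        likelihood_ratio_test(-130.0, -120.0, 1)  # full worse than reduced


def test_multiplicative_interaction_detects_strong_product_effect():
    truth = dict(DEFAULT_TRUE_LOG_HR)
    # multiplicative scale: add a large product effect on the frail rows
    truth["unhealthier_frail"] = truth["unhealthier_robust"] + \
        truth["healthier_frail"] + 1.0
    df, _ = _group_cohort(20_000, 44, true_log_hr=truth, baseline=2e-3)
    df["diet"] = df["joint_group"].str.split("_").str[0]
    df["frail"] = df["joint_group"].str.split("_").str[1]
    lrt = multiplicative_interaction(df, "diet", "frail")
    assert lrt.df == 4
    assert lrt.p_value < 0.001


def test_reri_arithmetic_from_definition():
    exact = additive_interaction_reri(np.log([2.0, 3.0, 4.0]))
    assert exact.reri == pytest.approx(0.0, abs=1e-12)   # 4 - 2 - 3 + 1
    super_add = additive_interaction_reri(np.log([2.0, 3.0, 6.0]))
    assert super_add.reri == pytest.approx(2.0, abs=1e-12)
    null = additive_interaction_reri(np.log([1.0, 1.0, 1.0]))
    assert null.reri == pytest.approx(0.0, abs=1e-12)


def test_reri_delta_and_bootstrap_intervals_agree():
    beta = np.log([2.0, 3.0, 6.0])
    cov = np.diag([0.01, 0.01, 0.01])
    delta = additive_interaction_reri(beta, cov, method="delta")
    boot = additive_interaction_reri(beta, cov, method="bootstrap", seed=1)
    assert delta.ci_low < 2.0 < delta.ci_high
    assert boot.ci_low == pytest.approx(delta.ci_low, abs=0.3)
    assert boot.ci_high == pytest.approx(delta.ci_high, abs=0.3)
    point = additive_interaction_reri(beta, None)
    assert point.se is None and point.ci_low is None


# ------------------------------------------------------------------------ trend

def test_trend_test_requires_three_levels_and_detects_gradient():
    df, _ = _group_cohort(20_000, 51, baseline=1e-3)
    df["tertile"] = df["joint_group"].str.split("_").str[0]
    with pytest.raises(ParameterError):
        trend_test(df, "tertile", ["healthier", "unhealthier"])
    # monotone true effects across diet tertiles exist in the default truth
    p, hrset = trend_test(df, "tertile", ["healthier", "medium", "unhealthier"])
    assert 0.0 <= p <= 1.0
    assert "_trend" in hrset.beta.index


# ---------------------------------------------------------------------- splines

def test_rcs_basis_dimension_and_boundary_linearity():
    knots = [10.0, 30.0, 60.0, 90.0]
    x = np.linspace(0, 100, 41)
    basis = rcs_basis(x, knots)
    assert basis.shape == (41, 3)
    # linear beyond boundary knots: second differences vanish there
    for col in range(basis.shape[1]):
        below = x < knots[0]
        above = x > knots[-1]
        for region in (below, above):
            vals = basis[region, col]
            second = np.diff(vals, 2)
            np.testing.assert_allclose(second, 0.0, atol=1e-9)
    with pytest.raises(ParameterError, match="knots"):
        rcs_basis(x, [10.0, 10.0, 60.0, 90.0])


def test_rcs_basis_matches_truncated_power_closed_form():
    knots = np.array([5.0, 35.0, 65.0, 95.0])
    grid = np.linspace(0.0, 100.0, 20)
    basis = rcs_basis(grid, knots)
    t = knots
    scale = (t[3] - t[0]) ** 2
    for i, x in enumerate(grid):
        assert basis[i, 0] == pytest.approx(x, abs=1e-9)
        for j in range(2):
            pp = lambda v: max(v, 0.0) ** 3
            expected = (pp(x - t[j])
                        - pp(x - t[2]) * (t[3] - t[j]) / (t[3] - t[2])
                        + pp(x - t[3]) * (t[2] - t[j]) / (t[3] - t[2])) / scale
            assert basis[i, j + 1] == pytest.approx(expected, abs=1e-9)


def test_rcs_dose_response_curve_is_zero_at_reference():
    df, _ = _group_cohort(4_000, 23)
    rng = np.random.default_rng(0)
    df["score"] = rng.normal(60, 15, len(df))
    curve, hrset = rcs_dose_response(df, "score")
    assert curve.basis_dim == 3
    ref_idx = np.argmin(np.abs(curve.grid - curve.ref_value))
    on_grid = rcs_basis(np.array([curve.ref_value]), curve.knots)
    # log-HR at the reference value itself is exactly zero by construction
    contrast = on_grid - on_grid
    assert np.allclose(contrast, 0.0)
    assert np.abs(curve.log_hr[ref_idx]) < 0.2  # nearest grid point, small
    assert (curve.ci_low <= curve.hr).all() and (curve.hr <= curve.ci_high).all()


# ------------------------------------------------------------------ diagnostics

def test_ph_diagnostics_reports_each_term_and_global():
    df, _ = _group_cohort(3_000, 71)
    est = StratifiedCoxPH(covariates=("sex",)).fit(df)
    report = ph_diagnostics(est)
    assert "GLOBAL" in report["term"].tolist()
    assert len(report) == len(est.hrset_.terms) + 1
    assert report["p"].between(0, 1).all()


def test_ph_diagnostics_empty_for_fit_without_terms():
    empty = HRSet(terms=[], beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
                  cov=pd.DataFrame(), loglik=0.0, aic=0.0, bic=0.0, n=0, n_events=0)
    assert ph_diagnostics(empty).empty
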