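"""Life-table translation of hazard ratios into life expectancy from age 50.

Given a population mortality schedule q(a) for ages 50..100, joint-group
prevalences and group hazard ratios, the reference-group hazard is calibrated
so that the prevalence-weighted mixture of group hazards reproduces the
population hazard at every age:

    h(a) = -ln(1 - q(a));   h_ref(a) = h(a) / sum_g p_g HR_g;
    h_g(a) = HR_g * h_ref(a);   q_g(a) = 1 - exp(-h_g(a)).

Calibration runs on the hazard scale because hazard ratios compose
multiplicatively there (a q-scale option is provided).  Group life tables use
the standard abridged conventions: half-year person-year credit in the year
of death, and survivors of the open interval at 100 credited 1/h(100) years.
Confidence intervals for life-expectancy differences come from a parametric
bootstrap over the fitted log-HR vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

AGES = np.arange(50, 101)
N_AGES = len(AGES)


@dataclass
class GroupMortalitySchedule:
    """Calibrated per-group death probabilities over ages 50..100."""

    groups: tuple[str, ...]
    prevalence: np.ndarray          # (G,)
    hazard_ratio: np.ndarray        # (G,)
    q: np.ndarray                   # (G, 51)
    population_q: np.ndarray        # (51,)


@dataclass
class LifeTableResult:
    """Per-group life expectancy at the index age with differences vs reference."""

    groups: tuple[str, ...]
    index_age: int
    le: np.ndarray                  # (G,) years
    delta_le: np.ndarray            # (G,) reference minus group (positive = years lost)
    reference: str
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"group": self.groups, "le_years": self.le,
                            "delta_le_years": self.delta_le})
        if self.ci_low is not None:
            out["delta_ci_low"] = self.ci_low
            out["delta_ci_high"] = self.ci_high
        return out


def hazard_from_q(q: np.ndarray) -> np.ndarray:
    """Annual hazard -ln(1 - q); infinite where q = 1."""
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        return -np.log1p(-q)


def calibrate_group_rates(
    q: np.ndarray,
    prevalence: Sequence[float] | Mapping[str, float],
    hazard_ratio: Sequence[float] | Mapping[str, float],
    groups: Sequence[str] | None = None,
    scale: str = "hazard",
) -> GroupMortalitySchedule:
    """Split a population mortality schedule into group schedules.

    ``prevalence`` must sum to 1 (tolerance 1e-9); ``hazard_ratio`` must be
    positive with the reference at 1.  ``scale="hazard"`` (default) preserves
    the prevalence-weighted hazard exactly; ``scale="q"`` performs the same
    calibration directly on death probabilities (approximate for large q).
    Any group probability exceeding 1 is clamped with a warning.
    """
    if isinstance(prevalence, Mapping):
        groups = tuple(prevalence)
        prev = np.array([prevalence[g] for g in groups], dtype=float)
        hrs = np.array([hazard_ratio[g] for g in groups], dtype=float)
    else:
        prev = np.asarray(prevalence, dtype=float)
        hrs = np.asarray(hazard_ratio, dtype=float)
        groups = tuple(groups) if groups is not None else tuple(
            f"group_{i}" for i in range(len(prev)))
    q = np.asarray(q, dtype=float)
    if q.shape != (N_AGES,):
        raise ParameterError(f"population schedule must cover ages 50..100 ({N_AGES} values)")
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ParameterError(f"group prevalences sum to {prev.sum():.12f}, not 1")
    if np.any(hrs <= 0):
        raise ParameterError("hazard ratios must be positive")

    mix = float(prev @ hrs)
    if scale == "hazard":
        h = hazard_from_q(q)
        h_g = np.outer(hrs, h / mix)
        q_g = 1.0 - np.exp(-h_g)
    elif scale == "q":
        q_g = np.outer(hrs, q / mix)
        if np.any(q_g > 1.0):
            import warnings

            warnings.warn("calibrated death probabilities exceeded 1 and were clamped")
            q_g = np.clip(q_g, 0.0, 1.0)
    else:
        raise ParameterError(f"unknown calibration scale '{scale}'")
    return GroupMortalitySchedule(groups=tuple(groups), prevalence=prev,
                                  hazard_ratio=hrs, q=q_g, population_q=q)


def life_expectancy_from_q(q: np.ndarray, terminal: bool = True) -> np.ndarray:
    """Life expectancy at the table's first age from q over its last axis.

    Vectorized over leading axes.  l(50) = 1; l(a+1) = l(a)(1 - q(a)); each
    year contributes L(a) = l(a)(1 - q(a)/2); with ``terminal`` the survivors
    of the final age are credited 1/h at the closing hazard (taken as zero
    extra years when the closing hazard is zero, i.e. hard truncation).
    """
    q = np.asarray(q, dtype=float)
    surv = np.cumprod(1.0 - q, axis=-1)
    l = np.concatenate([np.ones(q.shape[:-1] + (1,)), surv[..., :-1]], axis=-1)
    le = np.sum(l * (1.0 - q / 2.0), axis=-1)
    if terminal:
        h_last = hazard_from_q(q[..., -1])
        with np.errstate(divide="ignore", invalid="ignore"):
            extra = np.where(h_last > 0, surv[..., -1] / np.where(h_last > 0, h_last, 1.0), 0.0)
        le = le + extra
    return le


def build_life_table(q: np.ndarray, index_age: int = 50,
                     terminal: bool = True) -> pd.DataFrame:
    """Full life table for one schedule: survivors, person-years and LE."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or len(q) != N_AGES:
        raise ParameterError(f"schedule must hold {N_AGES} annual probabilities (ages 50..100)")
    if index_age != AGES[0]:
        raise ParameterError("life tables are tabulated from age 50")
    l = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
    big_l = l * (1.0 - q / 2.0)
    le = float(life_expectancy_from_q(q, terminal=terminal))
    return pd.DataFrame({"age": AGES, "q": q, "l": l, "L": big_l,
                         "le_at_index": le})


def le_differences(le: np.ndarray, groups: Sequence[str],
                   reference: str) -> np.ndarray:
    """Years of life lost vs the reference group: LE_ref - LE_g."""
    groups = list(groups)
    if reference not in groups:
        raise ParameterError(f"reference group '{reference}' not among groups")
    ref_le = le[groups.index(reference)]
    return ref_le - np.asarray(le, dtype=float)


def group_life_expectancy(
    q: np.ndarray,
    prevalence: Mapping[str, float],
    hazard_ratio: Mapping[str, float],
    reference: str,
    terminal: bool = True,
) -> LifeTableResult:
    """Calibrate group schedules and report LE and Delta-LE per group."""
    schedule = calibrate_group_rates(q, prevalence, hazard_ratio)
    le = life_expectancy_from_q(schedule.q, terminal=terminal)
    delta = le_differences(le, schedule.groups, reference)
    return LifeTableResult(groups=schedule.groups, index_age=50, le=le,
                           delta_le=delta, reference=reference)


def bootstrap_le_ci(
    beta: Mapping[str, float],
    cov: np.ndarray,
    prevalence: Mapping[str, float],
    q: np.ndarray,
    reference: str,
    n_runs: int = 10_000,
    seed: int = 0,
    terminal: bool = True,
) -> LifeTableResult:
    """Parametric-bootstrap percentile CIs for the Delta-LE estimates.

    ``beta`` maps each non-reference group to its fitted log-HR; ``cov`` is
    the corresponding covariance (order as iterated).  Each run draws the
    log-HR vector from a multivariate normal at the estimates, recomputes
    every group life expectancy, and the CI per group is the 2.5th/97.5th
    percentile of the Delta-LE draws.  Deterministic given ``seed``.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    groups = tuple(prevalence)
    if reference not in groups:
        raise ParameterError(f"reference group '{reference}' not among groups")
    nonref = [g for g in groups if g != reference]
    if set(beta) != set(nonref):
        raise ParameterError("beta must cover exactly the non-reference groups")
    b = np.array([beta[g] for g in nonref], dtype=float)
    cov = np.asarray(cov, dtype=float)
    eigvals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
        raise ParameterError("covariance matrix is not positive semi-definite")

    point = group_life_expectancy(
        q, prevalence, {reference: 1.0, **{g: float(np.exp(beta[g])) for g in nonref}},
        reference, terminal=terminal)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(b, cov, size=n_runs,
                                    method="eigh")       # (R, G-1)
    prev = np.array([prevalence[g] for g in groups], dtype=float)
    hrs = np.ones((n_runs, len(groups)))
    idx = [groups.index(g) for g in nonref]
    hrs[:, idx] = np.exp(draws)

    h = hazard_from_q(q)                                  # (51,)
    mix = hrs @ prev                                      # (R,)
    h_g = hrs[:, :, None] * (h[None, None, :] / mix[:, None, None])
    q_g = 1.0 - np.exp(-h_g)                              # (R, G, 51)
    le = life_expectancy_from_q(q_g, terminal=terminal)   # (R, G)
    delta = le[:, [groups.index(reference)]] - le         # (R, G)
    lo, hi = np.percentile(delta, [2.5, 97.5], axis=0)
    return LifeTableResult(groups=groups, index_age=50, le=point.le,
                           delta_le=point.delta_le, reference=reference,
                           ci_low=lo, ci_high=hi)
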