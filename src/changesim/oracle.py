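"""Analytic (population) estimands for the three regression analyses.

Given a scenario's implied covariance, the module computes the population
regression coefficients that each analysis converges to:

* ``alpha1`` — follow-up adjusted for baseline ("ANCOVA"):
  coefficient of WC0 in the regression of IC1 on WC0 and IC0;
* ``beta1`` — change score: coefficient of WC0 in the regression of
  IC1 − IC0 on WC0, evaluated by covariance algebra as
  ``[cov(WC0, IC1) − cov(WC0, IC0)] / var(WC0)`` — the change score is
  never materialized;
* ``gamma1`` — follow-up unadjusted: ``cov(WC0, IC1) / var(WC0)``.

The causal references (total and direct effect of WC0 on IC1) come from
the structural model itself, so bias is estimand minus reference, with no
sampling noise involved anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CollinearityError, DegenerateDifferenceError, ChangesimError
from .scenarios import ROLES, Scenario
from .sem_model import CovarianceStructure, implied_covariance, total_effect

__all__ = [
    "EstimandSet",
    "BiasDecomposition",
    "Recommendation",
    "population_ols",
    "estimands",
    "bias_decomposition",
    "oldham_correlation",
    "recommend_analysis",
    "estimand_table",
]

_COND_LIMIT = 1e12

X, Y0, Y1 = "WC0", "IC0", "IC1"

#: advisory attached to every recommendation
CHANGE_SCORE_WARNING = (
    "change-score analyses do not estimate causal effects in observational "
    "data; their coefficient conflates the exposure's effects on baseline "
    "and follow-up"
)


@dataclass(frozen=True)
class EstimandSet:
    """Population values of the three analysis coefficients and their
    causal references, in Log[mmol/L]/dm (or standardized if requested)."""

    scenario: str
    alpha0: float
    alpha1: float
    alpha2: float
    beta0: float
    beta1: float
    gamma0: float
    gamma1: float
    total_effect: float
    direct_effect: float
    units: str = "natural"


@dataclass(frozen=True)
class BiasDecomposition:
    """``beta1 = gamma1 − baseline_regression`` plus each estimand's
    deviation from the causal references."""

    scenario: str
    gamma1: float
    baseline_regression: float
    beta1: float
    deviation_from_total: dict = field(default_factory=dict)
    deviation_from_direct: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Recommendation:
    analysis: str
    adjustment_required: bool
    warnings: tuple[str, ...]


def population_ols(
    cov: CovarianceStructure, outcome: str, predictors: Sequence[str]
) -> tuple[dict[str, float], float]:
    """Population least-squares coefficients from second moments.

    Solves the normal equations ``Sigma_pp b = sigma_py`` on the supplied
    covariance; the intercept comes from the means.  Raises
    :class:`~changesim.errors.CollinearityError` if the predictor
    submatrix is (numerically) singular.
    """
    predictors = list(predictors)
    s_pp = cov.submatrix(predictors)
    s_py = np.array([cov.cov(p, outcome) for p in predictors])
    if np.linalg.cond(s_pp) > _COND_LIMIT:
        raise CollinearityError(
            f"singular predictor covariance for {predictors}"
        )
    b = np.linalg.solve(s_pp, s_py)
    coefs = dict(zip(predictors, map(float, b)))
    intercept = cov.mean(outcome) - sum(
        coefs[p] * cov.mean(p) for p in predictors
    )
    return coefs, float(intercept)


def _direct_effect(scenario: Scenario, units: str) -> float:
    """Effect of WC0 on IC1 not mediated through IC0: the direct arc."""
    for p, c, b in scenario.model.paths:
        if p == X and c == Y1:
            eff = b
            break
    else:
        return 0.0
    if units == "natural":
        eff *= scenario.model.sd(Y1) / scenario.model.sd(X)
    return eff


def estimands(scenario: Scenario, standardized: bool = False) -> EstimandSet:
    """All population analysis coefficients and causal references for one
    scenario, from the implied covariance (marginalizing over latents)."""
    units = "standardized" if standardized else "natural"
    cov = implied_covariance(scenario.model, standardized=standardized)

    gamma = population_ols(cov, Y1, [X])
    gamma1 = gamma[0][X]

    alpha = population_ols(cov, Y1, [X, Y0])
    alpha1, alpha2 = alpha[0][X], alpha[0][Y0]

    # change score by covariance algebra: cov(X, Y1 - Y0) = cov(X,Y1) - cov(X,Y0)
    beta1 = (cov.cov(X, Y1) - cov.cov(X, Y0)) / cov.var(X)
    beta0 = (cov.mean(Y1) - cov.mean(Y0)) - beta1 * cov.mean(X)

    return EstimandSet(
        scenario=scenario.name,
        alpha0=alpha[1],
        alpha1=alpha1,
        alpha2=alpha2,
        beta0=beta0,
        beta1=beta1,
        gamma0=gamma[1],
        gamma1=gamma1,
        total_effect=total_effect(scenario.model, X, Y1, units=units),
        direct_effect=_direct_effect(scenario, units),
        units=units,
    )


def bias_decomposition(
    scenario: Scenario, standardized: bool = False
) -> BiasDecomposition:
    """Split the change-score coefficient into its follow-up and baseline
    components: ``beta1 = gamma1 − cov(X, Y0)/var(X)``."""
    cov = implied_covariance(scenario.model, standardized=standardized)
    es = estimands(scenario, standardized=standardized)
    baseline_reg = cov.cov(X, Y0) / cov.var(X)
    dev_total = {
        "alpha1": es.alpha1 - es.total_effect,
        "beta1": es.beta1 - es.total_effect,
        "gamma1": es.gamma1 - es.total_effect,
    }
    dev_direct = {
        "alpha1": es.alpha1 - es.direct_effect,
        "beta1": es.beta1 - es.direct_effect,
        "gamma1": es.gamma1 - es.direct_effect,
    }
    return BiasDecomposition(
        scenario=scenario.name,
        gamma1=es.gamma1,
        baseline_regression=baseline_reg,
        beta1=es.beta1,
        deviation_from_total=dev_total,
        deviation_from_direct=dev_direct,
    )


def oldham_correlation(var_y0: float, var_y1: float, cov_y0y1: float) -> float:
    """Correlation between a baseline measure and its difference score:
    ``corr(Y0, Y1 − Y0) = (cov − var_y0) / sqrt(var_y0 (var_y0 + var_y1 − 2 cov))``.

    Two equal-variance, independent measures give exactly −1/√2 ≈ −0.707.
    """
    if var_y0 <= 0 or var_y1 <= 0:
        raise ChangesimError("variances must be positive")
    var_diff = var_y0 + var_y1 - 2.0 * cov_y0y1
    if var_diff <= 0:
        raise DegenerateDifferenceError(
            "difference score has non-positive variance (Y0 and Y1 are "
            "perfectly coupled)"
        )
    r = (cov_y0y1 - var_y0) / math.sqrt(var_y0 * var_diff)
    return max(-1.0, min(1.0, r))


def recommend_analysis(baseline_role: str, sought: str = "total") -> Recommendation:
    """Which analysis targets the sought causal effect, given the causal
    role of the baseline outcome.

    Competing exposure or confounder: adjust for baseline (for a
    confounder, adjustment is required; for a competing exposure it is
    optional but more precise).  Mediator: the unadjusted follow-up
    analysis gives the total effect; the adjusted analysis gives the
    direct effect but is vulnerable to mediator–outcome confounding.
    Every recommendation carries a warning that the change-score analysis
    is invalid for causal estimation in observational data.
    """
    if baseline_role not in ROLES:
        raise ChangesimError(f"unknown baseline role {baseline_role!r}")
    if sought not in ("total", "direct"):
        raise ChangesimError(f"sought must be 'total' or 'direct', got {sought!r}")
    warnings = [CHANGE_SCORE_WARNING]
    if baseline_role == "confounder":
        return Recommendation("followup_adjusted", True, tuple(warnings))
    if baseline_role == "competing_exposure":
        warnings.append(
            "adjusted and unadjusted follow-up analyses are both unbiased "
            "here; adjustment is preferred for precision"
        )
        return Recommendation("followup_adjusted", False, tuple(warnings))
    # mediator
    if sought == "total":
        return Recommendation("followup_unadjusted", False, tuple(warnings))
    warnings.append(
        "adjusting for a mediator requires accounting for potential "
        "mediator-outcome confounding"
    )
    return Recommendation("followup_adjusted", True, tuple(warnings))


def estimand_table(scenarios, standardized: bool = False):
    """Tidy per-scenario oracle table: columns scenario, analysis,
    estimand, value, causal_reference, bias."""
    import pandas as pd

    rows = []
    mapping = [
        ("followup_adjusted", "alpha1"),
        ("change_score", "beta1"),
        ("followup_unadjusted", "gamma1"),
    ]
    for sc in scenarios:
        es = estimands(sc, standardized=standardized)
        for analysis, name in mapping:
            ref = (
                es.direct_effect
                if (analysis == "followup_adjusted" and sc.baseline_role == "mediator")
                else es.total_effect
            )
            value = getattr(es, name)
            rows.append(
                {
                    "scenario": sc.name,
                    "analysis": analysis,
                    "estimand": name,
                    "value": value,
                    "causal_reference": ref,
                    "bias": value - ref,
                }
            )
    return pd.DataFrame(rows)
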