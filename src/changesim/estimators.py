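"""The four analyses, fitted to a finite dataset by closed-form least squares.

* ``change_score``          ΔIC = β0 + β1·WC0
* ``followup_adjusted``     IC1 = α0 + α1·WC0 + α2·IC0   (ANCOVA)
* ``followup_unadjusted``   IC1 = γ0 + γ1·WC0
* ``change_score_adjusted`` ΔIC = b0 + b1·WC0 + b2·IC0

The last is included because it is algebraically identical to the
follow-up adjusted analysis in the exposure coefficient (adjusting for
IC0 removes the −IC0 component of the outcome: [IC1−IC0 | IC0] =
[IC1 | IC0]); its IC0 coefficient equals the ANCOVA one minus 1 and must
not be read as a covariate effect.

Coefficients and classical homoskedastic standard errors come from the
normal equations; the data-generating process here is homoskedastic
Gaussian, so no robust-variance option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregateFitError, ChangesimError, CollinearityError, SampleSizeError
from .simulate import derive_change_score

__all__ = ["ANALYSES", "AnalysisResult", "fit_analysis", "fit_all", "results_to_frame"]

ANALYSES = (
    "change_score",
    "followup_adjusted",
    "followup_unadjusted",
    "change_score_adjusted",
)

#: outcome column and predictor columns for each analysis
_SPECS = {
    "change_score": ("dIC", ("WC0",)),
    "followup_adjusted": ("IC1", ("WC0", "IC0")),
    "followup_unadjusted": ("IC1", ("WC0",)),
    "change_score_adjusted": ("dIC", ("WC0", "IC0")),
}

BASELINE_COEF_WARNING = (
    "the IC0 coefficient of a baseline-adjusted change-score analysis "
    "mostly reflects the tautological association with the change score; "
    "do not interpret it as a covariate effect"
)


@dataclass(frozen=True)
class AnalysisResult:
    analysis: str
    coefficient_X: float
    se_X: float
    intercept: float
    se_intercept: float
    coefficient_Y0: float | None
    se_Y0: float | None
    n: int
    warnings: tuple[str, ...] = ()

    def __str__(self) -> str:  # rendering path carries the caveat
        s = (
            f"{self.analysis}: WC0 = {self.coefficient_X:.4f} "
            f"(SE {self.se_X:.4f}), n = {self.n}"
        )
        if self.coefficient_Y0 is not None:
            s += f", IC0 = {self.coefficient_Y0:.4f}"
        for w in self.warnings:
            s += f"\n  warning: {w}"
        return s


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal-equation OLS with intercept; returns (coefs, ses) with the
    intercept first."""
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    p = design.shape[1]
    if n <= p:
        raise SampleSizeError(f"n = {n} rows cannot fit {p} parameters")
    xtx = design.T @ design
    if np.linalg.matrix_rank(xtx) < p:
        raise CollinearityError("design matrix is rank-deficient")
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    s2 = float(resid @ resid) / (n - p)
    ses = np.sqrt(s2 * np.diag(np.linalg.inv(xtx)))
    return beta, ses


def fit_analysis(df: pd.DataFrame, analysis: str) -> AnalysisResult:
    """Fit one of the four analyses; the change-score outcomes derive
    ``dIC`` on the fly when absent."""
    if analysis not in _SPECS:
        raise ChangesimError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    outcome, predictors = _SPECS[analysis]
    if outcome == "dIC" and "dIC" not in df.columns:
        df = derive_change_score(df)
    missing = [c for c in (outcome, *predictors) if c not in df.columns]
    if missing:
        raise ChangesimError(f"{analysis}: missing columns {missing}")
    y = df[outcome].to_numpy(dtype=float)
    x = df[list(predictors)].to_numpy(dtype=float)
    beta, ses = _ols(y, x)
    has_y0 = "IC0" in predictors
    warnings = (BASELINE_COEF_WARNING,) if analysis == "change_score_adjusted" else ()
    return AnalysisResult(
        analysis=analysis,
        coefficient_X=float(beta[1]),
        se_X=float(ses[1]),
        intercept=float(beta[0]),
        se_intercept=float(ses[0]),
        coefficient_Y0=float(beta[2]) if has_y0 else None,
        se_Y0=float(ses[2]) if has_y0 else None,
        n=len(y),
        warnings=warnings,
    )


def fit_all(df: pd.DataFrame) -> dict[str, AnalysisResult]:
    """Run all four analyses; per-analysis failures do not abort the
    rest.  Returns results keyed by analysis name in stable order; raises
    :class:`~changesim.errors.AggregateFitError` only if every analysis
    fails."""
    results: dict[str, AnalysisResult] = {}
    errors: dict[str, Exception] = {}
    for analysis in ANALYSES:
        try:
            results[analysis] = fit_analysis(df, analysis)
        except ChangesimError as exc:
            errors[analysis] = exc
    if not results:
        raise AggregateFitError(errors)
    return results


def results_to_frame(
    results: dict[str, AnalysisResult], scenario: str | None = None, seed=None
) -> pd.DataFrame:
    """Tidy export: scenario, analysis, term, estimate, se, n, seed."""
    rows = []
    for r in results.values():
        terms = [("intercept", r.intercept, r.se_intercept), ("WC0", r.coefficient_X, r.se_X)]
        if r.coefficient_Y0 is not None:
            terms.append(("IC0", r.coefficient_Y0, r.se_Y0))
        for term, est, se in terms:
            rows.append(
                {
                    "scenario": scenario,
                    "analysis": r.analysis,
                    "term": term,
                    "estimate": est,
                    "se": se,
                    "n": r.n,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
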