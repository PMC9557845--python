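# Methods

## The problem

In longitudinal data it is common to form a change score ΔY = Y1 − Y0
from baseline and follow-up measures of an outcome and to regress it on
a baseline exposure X0. In observational settings this estimand,

β1 = E[Y1 − Y0 | do(X0 = x0)] − E[Y1 − Y0 | do(X0 = x0′)],

conflates the exposure's effects on the two time points: it equals the
total effect on the follow-up outcome *minus* the total effect on the
baseline outcome. Depending on whether the baseline outcome Y0 is a
competing exposure, a confounder, or a mediator for the effect of X0 on
Y1, the change-score coefficient can coincide with, diverge from, or
even reverse the sign of the causal quantities of interest — the total
effect γ1 = E[Y1 | do(x0)] − E[Y1 | do(x0′)] and the conditional
(ANCOVA) estimand α1 = E[Y1 | do(x0), Y0] − E[Y1 | do(x0′), Y0].
`changesim` makes this concrete for a worked epidemiological setting:
waist circumference at baseline (WC0, decimetres) and log insulin
concentration at baseline and follow-up (IC0, IC1, Log[mmol/L]).

## Structural model

All scenarios are linear-Gaussian structural equation models on a DAG.
Path coefficients are stored standardized (SD units of parent and
child); natural units enter only through a per-node scale (sd, mean).
Residual variances are auto-filled in topological order as one minus the
variance explained by each node's parents, so every node has unit
variance on the standardized scale; a non-positive fill is rejected as
an over-explained node. Implied second moments use the standard identity
Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ, rescaled by D = diag(sd). Total effects are
entries of (I − B)⁻¹ − I (sum over directed paths), converted to natural
units by sd(outcome)/sd(cause).

Because intercepts affect no reported coefficient, all means default
to 0. Latent variables (U, U2) are unit-variance, mean-zero, mutually
independent exogenous nodes. The latent baseline/follow-up random terms
of the conceptual model are not separate nodes; they are absorbed into
the residuals of IC0 and IC1.

## The eight scenarios and their calibration

| family | WC0–IC0 edge | role of IC0 | suffix B | suffix + |
|--------|--------------|-------------|----------|----------|
| 1 | none | competing exposure | adds U → {WC0, IC0, IC1} | — |
| 2 | IC0 → WC0 (a) | confounder | same | — |
| 3 | WC0 → IC0 (b) | mediator | same | adds U2 → {IC0, IC1} |

Fixed effect sizes: the standardized total effect of WC0 on IC1 is
0.433, equivalent to 0.200 Log[mmol/L]/dm; under mediation the
standardized direct arc is 0.108 (0.050 natural) and the indirect
component 0.325 (0.150 natural), so b·c = 0.325. Only the *ratio*
sd(WC0)/sd(IC) = 0.433/0.200 = 2.165 is identified by this pair of
statements, so the package adopts sd(WC0) = 2.165 dm and
sd(IC0) = sd(IC1) = 1 Log[mmol/L] as a convention; every reported
coefficient is invariant to the common scale.

The individual couplings a (confounding), b (mediation) and c (the
IC0 → IC1 stability arc) are not printed next to the effect sizes. They
are recovered by inverting the analytic estimands against published
coefficient values (`calibrate_constants`), with two independent routes:

* confounder route, from the 2A change-score and unadjusted cells
  (0.119, 0.351): γ1·r = t + a·c and β1·r = t + a·c − a give
  a = 0.5023, c = 0.6509;
* mediator route, from the 3A change-score cell (−0.031): β1·r = t − b
  gives b = 0.5001, then c = 0.325/b = 0.6499.

The two routes agree on c to 0.001 — strong evidence for a single
round-number parameterization a = b = 0.50, c = 0.65, which the package
uses as its default. One visible consequence: the default couplings give
a 2A unadjusted coefficient of 0.3501 (rounds to 0.350) where the
published value is 0.351; the exactly inverted couplings reproduce 0.351
to three decimals. Both are available (defaults vs
`calibrate_constants`).

### Latent loadings

The loadings of U and U2 are likewise not identifiable from the
coefficient table (five loadings, few independent cells), and the
confounded cells (1B, 2B, 3B, 3A+ adjusted, 3B+) are therefore treated
as qualitative reproductions only: the package checks bias *directions*
(e.g. the unadjusted estimate inflated by U; the 3B change score
negative; the 3A+ adjusted estimate attenuated below 0.050), and exact
values can be reproduced by supplying loadings through the config
surface. The default is a uniform loading of 0.15 on all five latent
arcs. A uniform 0.20 is infeasible: in scenario 2B the follow-up outcome's
parents (WC0 at 0.433, IC0 at 0.65, U at 0.20, with corr(WC0, IC0) = 0.54
and corr(WC0, U) = 0.30 induced by the confounding) would explain 1.058
of a unit variance, leaving no positive residual; 0.15 is the largest
round uniform value feasible in every scenario. Scenario 2B sits close
to the boundary either way (residual variance of IC1 ≈ 0.015), which is
consistent with the unusually narrow published simulation limits for the
2B adjusted cell. With *any* symmetric loading the 1B change score comes
out slightly inflated rather than slightly deflated as published,
implying the original loadings were asymmetric (weaker into IC1); the
direction checks the package asserts are the ones that are
loading-robust.

## The analytic oracle

Population coefficients are computed from the implied covariance, never
from simulated data: γ1 = cov(WC0, IC1)/var(WC0); α1 from the
two-predictor normal equations on {WC0, IC0}; and the change score by
covariance algebra, β1 = [cov(WC0, IC1) − cov(WC0, IC0)]/var(WC0) — the
composite variable is never materialized, which avoids needless
numerical error and mirrors the estimand's expansion. The decomposition
β1 = γ1 − cov(WC0, IC0)/var(WC0) is exposed directly
(`bias_decomposition`) and holds to 1e−12 by construction.

Two exact identities are worth stating because the test suite leans on
them:

* **ANCOVA equivalence.** A change-score analysis adjusted for the
  baseline outcome is mathematically identical to the follow-up
  adjusted analysis in the exposure coefficient, and its baseline
  coefficient is the ANCOVA one minus exactly 1 ([Y1 − Y0 | Y0] =
  [Y1 | Y0]). The fitted version of this identity holds to machine
  precision on every dataset.
* **Randomization limit.** When WC0 ⊥ IC0 (no edge and no shared latent
  path), α1 = β1 = γ1 exactly.

The tautological correlation between a baseline measure and its
difference score is provided as a closed form:
corr(Y0, Y1 − Y0) = (cov − var Y0)/√(var Y0 · var(Y1 − Y0)). For two
equal-variance independent measures this equals −1/√2 ≈ −0.707; the
value is often quoted as ±1/2 in the change-score literature, which
matches the *square* of neither quantity and is presumably a lost
radical — the package reports the exact closed form and leaves the
historical figure as-is.

`recommend_analysis` encodes the decision rule: competing exposure or
confounder → follow-up adjusted for baseline (for a confounder,
required; for a competing exposure optional but more precise); mediator
and total effect sought → follow-up unadjusted; mediator and direct
effect sought → follow-up adjusted, flagged for mediator–outcome
confounding. Every recommendation carries the warning that change-score
analyses do not estimate causal effects in observational data.

## Synthetic cohorts and the Monte Carlo study

`simulate_dataset` draws each node in topological order as the
coefficient-weighted sum of its parents plus a Gaussian residual, then
rescales to natural units. Gaussian residuals make the oracle values
exact population targets (the linear standardized-coefficient framework
is second-moment sufficient, and normality adds no bias to OLS); what
the generator does *not* emulate is everything a real survey cohort
would add — non-linearity, non-normal tails, measurement error,
informative follow-up — so passing tests demonstrate estimator behaviour
under the stated structural assumptions, not robustness beyond them.
Each dataset uses a single seeded generator; the study runner derives
replicate seeds as base_seed + replicate index, giving reproducibility
without stream coupling.

The study defaults are n = 1000 per replicate and 1000 replicates.
n = 1000 is back-solved from the published simulation-limit widths: the
closed-form OLS standard errors in scenario 1A give half-widths
1.96·SE = 0.0205/0.0179/0.0258 for the three analyses at n = 1000,
matching the printed 0.020/0.018/0.026. "95% simulation limits" are
interpreted as empirical 2.5/97.5 percentiles of the replicate
coefficients (linear interpolation between order statistics); for these
nearly-Gaussian sampling distributions, mean ± 1.96·SD differs
negligibly. Replicates that fail to fit are dropped and counted, with an
abort above a 1% failure rate.

## Numerical choices and edge cases

* Collinearity in either the population normal equations (condition
  number > 1e12) or a sample design matrix (rank-deficient XᵀX) raises a
  dedicated error rather than producing pseudo-inverse artifacts.
* Standard errors are classical homoskedastic OLS — exact for the
  homoskedastic Gaussian generating process; no robust option.
* Cycles, unknown nodes, non-positive scales, over-explained nodes, and
  difference scores with non-positive variance all fail loudly with
  typed exceptions.
* With two replicates the percentile interpolation degenerates to
  (nearly) the min/max of the two draws, which is tested as the boundary
  case of the summary.

## Problem sizes used in the shipped analyses

The numbered drivers under `analysis/` run the full grid (8 scenarios ×
1000 replicates × n = 1000, ~20 s on one CPU). The test suite uses the
same n = 1000 replicate size but fewer replicates (100–500) for the
stochastic checks and n up to 2·10⁵ for moment-convergence checks;
large-sample consistency is checked on the 10³–10⁵ ladder.

## Known limitations

* Linear-Gaussian only; no non-linear structural equations, percentage
  change scores, latent growth curves, or measurement-error overlays.
* The scenario library curates exactly the three-role template (plus
  latent variants); arbitrary DAGs are supported by the SEM layer but
  not curated.
* The latent-loading defaults are documented approximations, not the
  original (unpublished) values; confounded-cell magnitudes are
  reproduced only when loadings are supplied via config.
* The oracle assumes the true model: there is no identification, no
  adjustment-set search, and no d-separation machinery beyond the
  three-role classification.
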