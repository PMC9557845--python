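# changesim

Why analyses of "change scores" fail to estimate causal effects in
observational data — as a runnable, testable simulation laboratory.

Researchers studying change in a longitudinal outcome often regress the
change score ΔY = Y1 − Y0 on a baseline exposure X0. `changesim`
implements the structural-equation machinery to show what that analysis
actually estimates. It targets three estimands, written in do-notation:

* **α1** (follow-up adjusted for baseline, ANCOVA):
  E[Y1 | do(x0), Y0] − E[Y1 | do(x0′), Y0], fitted as
  Y1 = α0 + α1·X0 + α2·Y0;
* **β1** (change score): E[Y1 − Y0 | do(x0)] − E[Y1 − Y0 | do(x0′)],
  fitted as ΔY = β0 + β1·X0;
* **γ1** (follow-up unadjusted): E[Y1 | do(x0)] − E[Y1 | do(x0′)],
  fitted as Y1 = γ0 + γ1·X0.

The worked setting is waist circumference (WC0, dm) and log insulin
concentration (IC0, IC1, Log[mmol/L]), with a total causal effect of
0.200 Log[mmol/L]/dm (standardized 0.433), split 0.150 indirect / 0.050
direct when mediated through IC0. Eight scenarios vary the causal role
of the baseline outcome — competing exposure, confounder or mediator,
each with and without latent confounding. The package provides:

* `sem_model` — linear-Gaussian SEMs on DAGs with standardized path
  coefficients, implied covariance Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ, total effects,
  JSON/DOT export;
* `scenarios` — the eight-scenario library and a calibration solver
  that inverts published coefficients for the unprinted couplings;
* `oracle` — exact population values of α1/β1/γ1, the bias
  decomposition β1 = γ1 − reg(Y0 ~ X0), the baseline-vs-difference
  tautological correlation, and an analysis recommender;
* `simulate` / `estimators` — seeded Gaussian cohort generation and the
  four closed-form OLS analyses (including the change-score-adjusted
  variant, identical to ANCOVA in the exposure coefficient);
* `study` — the Monte Carlo runner that produces the coefficient table
  with 95% simulation limits, plus a `changesim` CLI.

## Worked example

```python
from changesim import build_scenario, estimands, StudyConfig, run_study, render_table1

# Scenario 3A: baseline insulin mediates the effect of waist circumference
es = estimands(build_scenario("3A"))
print(f"change score      beta1  = {es.beta1:+.3f}")
print(f"adjusted          alpha1 = {es.alpha1:+.3f}")
print(f"unadjusted        gamma1 = {es.gamma1:+.3f}")
print(f"total effect = {es.total_effect:.3f}, direct = {es.direct_effect:.3f}")
```

prints

```
change score      beta1  = -0.031
adjusted          alpha1 = +0.050
unadjusted        gamma1 = +0.200
total effect = 0.200, direct = 0.050
```

— the change-score "effect" is *negative* although both causal effects
are positive: the −IC0 component inside ΔIC, strongly correlated with
WC0 through mediation, dominates the positive effect on IC1. The
adjusted analysis recovers the direct effect and the unadjusted one the
total effect. A finite-sample version of the same table:

```python
res = run_study(StudyConfig(scenarios=("1A", "2A", "3A"), replicates=500))
print(render_table1(res))
```

```
Regression coefficient for WC0 (Log[mmol/L]/dm) (95% simulation limits)
                                   IC0 is competing exposure  IC0 is confounder     IC0 is mediator
Analysis approach                  Scenario 1A                Scenario 2A           Scenario 3A
---------------------------------------------------------------------------------------------------
Change score                       0.199 (0.177, 0.221)       0.118 (0.106, 0.132)  -0.032 (-0.056, -0.009)
Follow-up adjusted for baseline    0.200 (0.180, 0.219)       0.200 (0.189, 0.211)  0.050 (0.023, 0.074)
Follow-up unadjusted for baseline  0.200 (0.172, 0.228)       0.351 (0.331, 0.370)  0.200 (0.172, 0.228)
```

Only in scenario 1A (baseline outcome independent of the exposure, as
under randomization) do the three analyses agree; under confounding
(2A) only the adjusted analysis returns 0.200, and under mediation (3A)
each analysis estimates a different quantity.

The numbered scripts under `analysis/` run the full pipeline: `01`
inverts the published coefficients for the coupling constants (two
independent routes agree on the stability arc to 0.001), `02` tabulates
the analytic estimands and bias decomposition for all eight scenarios,
`03` runs the complete 1000-replicate Monte Carlo study (~20 s), and
`04` exports the scenario DAGs. Outputs land in `results/`.

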