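#!/usr/bin/env python
"""Population estimands for all eight scenarios, with bias decompositions.

For each scenario the analytic oracle evaluates the three analysis
coefficients (change score, follow-up adjusted, follow-up unadjusted)
from the implied covariance, together with the causal references and the
split of the change-score coefficient into its follow-up and baseline
components.  No simulation is involved: these are the exact values the
Monte Carlo study converges to.

Writes results/oracle_estimands.csv and results/bias_decomposition.csv.
"""

from pathlib import Path

import pandas as pd

from changesim import bias_decomposition, build_all_scenarios, estimand_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    scenarios = build_all_scenarios()
    table = estimand_table(scenarios.values())
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "oracle_estimands.csv", index=False)

    print("Population analysis coefficients (Log[mmol/L]/dm):")
    wide = table.pivot(index="analysis", columns="scenario", values="value")
    wide = wide[[s for s in scenarios]]
    print(wide.round(3).to_string())
    print()
    print("Every unconfounded column shows the signature pattern: the")
    print("change score is unbiased only in 1A; under confounding (2A) only")
    print("the baseline-adjusted analysis recovers 0.200; under mediation")
    print("(3A) the change score flips sign (-0.031) while the adjusted and")
    print("unadjusted analyses return the direct (0.050) and total (0.200)")
    print("effects.")

    rows = []
    for name, sc in scenarios.items():
        bd = bias_decomposition(sc)
        rows.append(
            {
                "scenario": name,
                "gamma1": bd.gamma1,
                "baseline_regression": bd.baseline_regression,
                "beta1": bd.beta1,
            }
        )
    decomp = pd.DataFrame(rows)
    decomp.to_csv(OUT / "bias_decomposition.csv", index=False)
    print()
    print("Change-score decomposition beta1 = gamma1 - reg(IC0 ~ WC0):")
    print(decomp.round(4).to_string(index=False))
    print(f"\nwrote {OUT / 'oracle_estimands.csv'} and "
          f"{OUT / 'bias_decomposition.csv'}")


if __name__ == "__main__":
    main()
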