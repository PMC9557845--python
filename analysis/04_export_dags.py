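#!/usr/bin/env python
"""Export the scenario DAGs (Graphviz DOT) and the JSON catalogue.

Latent confounders are drawn dashed; edge labels carry the standardized
path coefficients.  Writes results/dags/*.dot and results/scenarios.json.
"""

from pathlib import Path

from changesim import build_all_scenarios
from changesim.scenarios import scenario_catalogue_json, scenario_to_dot

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    dag_dir = OUT / "dags"
    dag_dir.mkdir(parents=True, exist_ok=True)
    for name, sc in build_all_scenarios().items():
        path = dag_dir / f"scenario_{name.replace('+', 'plus')}.dot"
        path.write_text(scenario_to_dot(sc))
    (OUT / "scenarios.json").write_text(scenario_catalogue_json())
    print(f"wrote 8 DOT files to {dag_dir} and {OUT / 'scenarios.json'}")


if __name__ == "__main__":
    main()
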