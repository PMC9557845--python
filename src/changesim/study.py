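"""Monte Carlo study runner: the machine twin of the published summary table.

For every requested scenario, ``replicates`` independent cohorts of
``n_per_replicate`` individuals are simulated (replicate ``r`` uses seed
``base_seed + r``), each analysis is fitted, and the exposure coefficient
is summarized by its replicate mean and empirical 2.5th/97.5th
percentiles — the "95% simulation limits".  Percentiles use linear
interpolation between order statistics.  The analytic oracle value and
the causal references (total effect 0.200; direct effect 0.050 under
mediation) are attached to every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ChangesimError
from .estimators import fit_all
from .oracle import estimands
from .scenarios import SCENARIO_NAMES, CalibrationConstants, build_scenario
from .simulate import simulate_dataset

__all__ = ["StudyConfig", "StudyResult", "run_study", "render_table1"]

#: analyses shown as table rows, in print order
TABLE_ANALYSES = ("change_score", "followup_adjusted", "followup_unadjusted")

_ANALYSIS_LABELS = {
    "change_score": "Change score",
    "followup_adjusted": "Follow-up adjusted for baseline",
    "followup_unadjusted": "Follow-up unadjusted for baseline",
    "change_score_adjusted": "Change score adjusted for baseline",
}

_ORACLE_FIELD = {
    "change_score": "beta1",
    "followup_adjusted": "alpha1",
    "followup_unadjusted": "gamma1",
    "change_score_adjusted": "alpha1",  # identical exposure coefficient
}

_ROLE_LABELS = {
    "competing_exposure": "IC0 is competing exposure",
    "confounder": "IC0 is confounder",
    "mediator": "IC0 is mediator",
}


@dataclass(frozen=True)
class StudyConfig:
    """Study settings.  ``replicates = 0`` requests oracle-only mode
    (point values, no simulation limits)."""

    scenarios: tuple[str, ...] = SCENARIO_NAMES
    n_per_replicate: int = 1000
    replicates: int = 1000
    base_seed: int = 20210607
    constants: CalibrationConstants | None = None
    max_failure_rate: float = 0.01

    def __post_init__(self):
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        unknown = set(self.scenarios) - set(SCENARIO_NAMES)
        if unknown:
            raise ChangesimError(f"unknown scenarios: {sorted(unknown)}")
        if self.n_per_replicate < 3:
            raise ChangesimError("n_per_replicate must be >= 3")
        if self.replicates != 0 and self.replicates < 2:
            raise ChangesimError("replicates must be >= 2 (or 0 for oracle-only)")


@dataclass(frozen=True)
class StudyResult:
    """Per (scenario, analysis) summaries plus the config that made them.

    ``table`` columns: scenario, baseline_role, analysis, mean, lower,
    upper, oracle, total_effect, direct_effect, replicates, failed.
    In oracle-only mode mean/lower/upper are NaN.
    """

    table: pd.DataFrame
    config: StudyConfig
    draws: dict = field(default_factory=dict, repr=False)


def run_study(config: StudyConfig) -> StudyResult:
    rows = []
    draws_by_cell: dict[tuple[str, str], np.ndarray] = {}
    for name in config.scenarios:
        scenario = build_scenario(name, config.constants)
        es = estimands(scenario)
        draws: dict[str, list[float]] = {a: [] for a in TABLE_ANALYSES}
        failed = 0
        for r in range(config.replicates):
            try:
                df = simulate_dataset(
                    scenario, config.n_per_replicate, seed=config.base_seed + r
                )
                results = fit_all(df)
                for a in TABLE_ANALYSES:
                    draws[a].append(results[a].coefficient_X)
            except ChangesimError:
                failed += 1
        if config.replicates and failed > config.max_failure_rate * config.replicates:
            raise ChangesimError(
                f"scenario {name}: {failed}/{config.replicates} replicates failed"
            )
        for a in TABLE_ANALYSES:
            arr = np.asarray(draws[a])
            draws_by_cell[(name, a)] = arr
            if arr.size:
                mean = float(arr.mean())
                lower, upper = (
                    float(np.percentile(arr, q, method="linear")) for q in (2.5, 97.5)
                )
            else:
                mean = lower = upper = float("nan")
            rows.append(
                {
                    "scenario": name,
                    "baseline_role": scenario.baseline_role,
                    "analysis": a,
                    "mean": mean,
                    "lower": lower,
                    "upper": upper,
                    "oracle": getattr(es, _ORACLE_FIELD[a]),
                    "total_effect": es.total_effect,
                    "direct_effect": es.direct_effect,
                    "replicates": int(arr.size),
                    "failed": failed,
                }
            )
    return StudyResult(table=pd.DataFrame(rows), config=config, draws=draws_by_cell)


def _fmt_cell(row: pd.Series, oracle_only: bool) -> str:
    if oracle_only or not np.isfinite(row["mean"]):
        return f"{row['oracle']:.3f}"
    return f"{row['mean']:.3f} ({row['lower']:.3f}, {row['upper']:.3f})"


def render_table1(result: StudyResult, fmt: str = "text") -> str:
    """Render the study as the 3-analyses × scenarios summary table.

    ``fmt`` is ``"text"`` (aligned columns with role group headings and
    footnotes) or ``"csv"``.
    """
    t = result.table
    oracle_only = result.config.replicates == 0
    scen_order = [s for s in SCENARIO_NAMES if s in set(t["scenario"])]
    cells = {
        (r["scenario"], r["analysis"]): _fmt_cell(r, oracle_only)
        for _, r in t.iterrows()
    }
    header = ["Analysis approach"] + [f"Scenario {s}" for s in scen_order]
    body = [
        [_ANALYSIS_LABELS[a]] + [cells.get((s, a), "") for s in scen_order]
        for a in TABLE_ANALYSES
    ]
    if fmt == "csv":
        lines = [",".join(header)]
        lines += [",".join(f'"{c}"' if "," in c else c for c in row) for row in body]
        return "\n".join(lines) + "\n"
    if fmt != "text":
        raise ChangesimError(f"unknown table format {fmt!r}")

    roles = {
        s: _ROLE_LABELS[t.loc[t["scenario"] == s, "baseline_role"].iloc[0]]
        for s in scen_order
    }
    widths = [
        max(len(header[j]), max((len(row[j]) for row in body), default=0), len(roles.get(scen_order[j - 1], "")) if j else 0)
        for j in range(len(header))
    ]
    def line(cols):
        return "  ".join(c.ljust(w) for c, w in zip(cols, widths)).rstrip()

    role_row = [""] + [roles[s] for s in scen_order]
    out = [
        "Regression coefficient for WC0 (Log[mmol/L]/dm)"
        + ("" if oracle_only else " (95% simulation limits)"),
        line(role_row),
        line(header),
        "-" * (sum(widths) + 2 * (len(widths) - 1)),
    ]
    out += [line(row) for row in body]
    out += [
        "",
        "Simulated total causal effect of WC0 on IC1: 0.200 Log[mmol/L]/dm.",
        "When mediated through IC0: indirect 0.150, direct 0.050 Log[mmol/L]/dm.",
        "Deviations from these values reflect statistical or inferential bias.",
    ]
    return "\n".join(out) + "\n"
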