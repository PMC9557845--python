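"""Draw finite samples from a scenario's structural equations.

Each node is generated in topological order as the coefficient-weighted
sum of its parents plus a Gaussian residual with the node's (auto-filled)
residual variance, all on the standardized scale, then rescaled and
shifted to natural units.  Identical (scenario, n, seed) triples give
bit-identical datasets.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChangesimError, SampleSizeError
from .scenarios import Scenario

__all__ = [
    "simulate_dataset",
    "derive_change_score",
    "write_dataset",
    "read_dataset",
]

MIN_ROWS = 3


def simulate_dataset(
    scenario: Scenario, n: int, seed: int, keep_latents: bool = False
) -> pd.DataFrame:
    """Simulate ``n`` rows of WC0, IC0, IC1 (plus latents on request).

    Latent columns, when kept, are non-analysis columns and are listed in
    ``df.attrs["latent_columns"]``.  Provenance (scenario name, n, seed)
    travels in ``df.attrs``.
    """
    if n < MIN_ROWS:
        raise SampleSizeError(f"need at least {MIN_ROWS} rows, got {n}")
    rng = np.random.default_rng(seed)
    model = scenario.model
    std: dict[str, np.ndarray] = {}
    for node in model.nodes:  # already topologically sorted
        psi = model.residual_variance[node]
        x = rng.normal(0.0, np.sqrt(psi), size=n)
        for parent, coef in model.parents(node):
            x = x + coef * std[parent]
        std[node] = x

    cols = list(model.observed) + (sorted(scenario.latents) if keep_latents else [])
    data = {
        c: model.mean(c) + model.sd(c) * std[c] for c in cols
    }
    df = pd.DataFrame(data, columns=cols)
    df.attrs.update(
        scenario=scenario.name,
        n=n,
        seed=int(seed),
        latent_columns=sorted(scenario.latents) if keep_latents else [],
    )
    return df


def derive_change_score(df: pd.DataFrame) -> pd.DataFrame:
    """Append the change score ``dIC = IC1 − IC0``; idempotent."""
    for col in ("IC0", "IC1"):
        if col not in df.columns:
            raise ChangesimError(f"cannot derive change score: missing column {col!r}")
    out = df.copy()
    out.attrs.update(df.attrs)
    out["dIC"] = out["IC1"] - out["IC0"]
    return out


def write_dataset(df: pd.DataFrame, path) -> None:
    """CSV with a one-line header plus a sidecar ``<path>.meta.json``
    recording scenario, n and seed."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {
        "scenario": df.attrs.get("scenario"),
        "n": int(df.attrs.get("n", len(df))),
        "seed": df.attrs.get("seed"),
        "latent_columns": df.attrs.get("latent_columns", []),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        df.attrs.update(json.loads(sidecar.read_text()))
    return df
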