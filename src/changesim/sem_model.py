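"""Linear-Gaussian structural equation models over a DAG.

A :class:`StructuralModel` stores *standardized* path coefficients — each
coefficient is in standard-deviation units of parent and child — together
with a per-node ``scale`` mapping that carries the natural-unit standard
deviation and mean.  Natural units therefore enter every derived quantity
as a pure rescaling, which keeps the correspondence between a standardized
effect and its natural-unit regression coefficient exact.

By default the model is *auto-standardized*: residual variances are filled
in topological order as one minus the variance explained by each node's
parents, so every node has unit variance on the standardized scale.
Explicit residual variances may be supplied to override this.

The implied second moments follow the standard linear-SEM identity

    Sigma = (I - A)^{-1} Psi (I - A)^{-T}

where ``A[child, parent]`` holds the path coefficients and ``Psi`` is the
diagonal matrix of residual variances; the natural-unit covariance is
``D Sigma D`` with ``D = diag(sd)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import (
    ChangesimError,
    CyclicGraphError,
    OverExplainedNodeError,
    UnknownNodeError,
)

__all__ = [
    "StructuralModel",
    "CovarianceStructure",
    "validate_model",
    "implied_covariance",
    "total_effect",
    "model_to_json",
    "model_from_json",
    "model_to_dot",
]

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class StructuralModel:
    """A DAG with standardized path coefficients and natural-unit scales.

    Parameters
    ----------
    nodes
        Variable names, observed and latent.  After validation the tuple is
        topologically sorted (stable with respect to the declared order).
    paths
        ``(parent, child, standardized coefficient)`` triples.
    residual_variance
        Optional explicit residual variances on the standardized scale.
        Nodes absent from the mapping are auto-filled at validation time so
        that their implied variance is 1.
    scale
        ``node -> (sd, mean)`` in natural units.  Missing nodes default to
        ``(1.0, 0.0)``.
    latents
        Names of latent (unobserved) nodes.
    """

    nodes: tuple[str, ...]
    paths: tuple[tuple[str, str, float], ...] = ()
    residual_variance: Mapping[str, float] | None = None
    scale: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    latents: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "paths", tuple((p, c, float(b)) for p, c, b in self.paths)
        )
        object.__setattr__(self, "latents", frozenset(self.latents))
        object.__setattr__(
            self, "scale", {k: (float(s), float(m)) for k, (s, m) in dict(self.scale).items()}
        )

    # -- conveniences -----------------------------------------------------
    def sd(self, node: str) -> float:
        return self.scale.get(node, (1.0, 0.0))[0]

    def mean(self, node: str) -> float:
        return self.scale.get(node, (1.0, 0.0))[1]

    def parents(self, node: str) -> list[tuple[str, float]]:
        return [(p, b) for p, c, b in self.paths if c == node]

    def has_edge(self, parent: str, child: str) -> bool:
        return any(p == parent and c == child for p, c, _ in self.paths)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.paths)
        return g

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.latents)


@dataclass(frozen=True)
class CovarianceStructure:
    """Implied second moments: an ordered variable list, covariance matrix
    and mean vector, all in the units they were computed in."""

    variables: tuple[str, ...]
    matrix: np.ndarray
    means: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        m = np.asarray(self.matrix, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        k = len(self.variables)
        if m.shape != (k, k):
            raise ValueError(f"covariance matrix shape {m.shape} != ({k}, {k})")
        if mu.shape != (k,):
            raise ValueError(f"mean vector shape {mu.shape} != ({k},)")
        if not np.allclose(m, m.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("covariance matrix is not symmetric within 1e-12")
        if np.any(np.diag(m) <= 0):
            raise ValueError("covariance matrix has a non-positive diagonal entry")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)
        object.__setattr__(self, "means", mu)

    def index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise UnknownNodeError(f"unknown variable {name!r}") from None

    def cov(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])

    def var(self, a: str) -> float:
        return self.cov(a, a)

    def mean(self, a: str) -> float:
        return float(self.means[self.index(a)])

    def submatrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.index(n) for n in names]
        return self.matrix[np.ix_(idx, idx)]


def _topological_order(model: StructuralModel) -> list[str]:
    g = model.graph()
    missing = {n for e in model.paths for n in e[:2]} - set(model.nodes)
    if missing:
        raise UnknownNodeError(f"path endpoints not declared as nodes: {sorted(missing)}")
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CyclicGraphError(f"directed cycle detected: {cycle}")
    rank = {n: i for i, n in enumerate(model.nodes)}
    return list(nx.lexicographical_topological_sort(g, key=rank.get))


def _standardized_moments(
    order: list[str],
    paths: Iterable[tuple[str, str, float]],
    explicit_psi: Mapping[str, float] | None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Covariance recursion in topological order.

    Nodes without an explicit residual variance are auto-standardized:
    psi = 1 - explained variance, which must be positive.
    """
    explicit_psi = dict(explicit_psi or {})
    k = len(order)
    idx = {n: i for i, n in enumerate(order)}
    sigma = np.zeros((k, k))
    psi: dict[str, float] = {}
    parent_map: dict[str, list[tuple[str, float]]] = {n: [] for n in order}
    for p, c, b in paths:
        parent_map[c].append((p, b))
    for j, node in enumerate(order):
        pars = parent_map[node]
        a = np.array([b for _, b in pars])
        pidx = [idx[p] for p, _ in pars]
        # cross-covariances with all previously placed nodes
        for i in range(j):
            sigma[i, j] = sigma[j, i] = float(a @ sigma[pidx, i]) if pars else 0.0
        explained = float(a @ sigma[np.ix_(pidx, pidx)] @ a) if pars else 0.0
        if node in explicit_psi:
            p_j = float(explicit_psi[node])
            if p_j <= 0:
                raise OverExplainedNodeError(node, explained)
        else:
            p_j = 1.0 - explained
            if p_j <= 0:
                raise OverExplainedNodeError(node, explained)
        psi[node] = p_j
        sigma[j, j] = explained + p_j
    return sigma, psi


def validate_model(model: StructuralModel) -> StructuralModel:
    """Check acyclicity and scales, sort nodes topologically, and fill
    residual variances (auto-standardized where not explicit).

    Returns a new :class:`StructuralModel`; raises
    :class:`~changesim.errors.CyclicGraphError` or
    :class:`~changesim.errors.OverExplainedNodeError` on invalid input.
    """
    order = _topological_order(model)
    for n, (sd, _) in model.scale.items():
        if n not in model.nodes:
            raise UnknownNodeError(f"scale given for unknown node {n!r}")
        if sd <= 0:
            raise ValueError(f"standard deviation of {n!r} must be > 0, got {sd}")
    unknown_latents = model.latents - set(model.nodes)
    if unknown_latents:
        raise UnknownNodeError(f"latent flags for unknown nodes: {sorted(unknown_latents)}")
    _, psi = _standardized_moments(order, model.paths, model.residual_variance)
    return replace(model, nodes=tuple(order), residual_variance=psi)


def _coef_matrix(model: StructuralModel) -> np.ndarray:
    """A[child, parent] in the model's node order."""
    idx = {n: i for i, n in enumerate(model.nodes)}
    a = np.zeros((len(model.nodes),) * 2)
    for p, c, b in model.paths:
        a[idx[c], idx[p]] = b
    return a


def implied_covariance(
    model: StructuralModel, standardized: bool = False
) -> CovarianceStructure:
    """Model-implied covariance via ``(I-A)^{-1} Psi (I-A)^{-T}``.

    With ``standardized=True`` the result is on the unit-variance scale
    (auto-standardized nodes have diagonal exactly 1); otherwise each node
    is rescaled by its natural-unit standard deviation and shifted to its
    mean.
    """
    model = validate_model(model)
    k = len(model.nodes)
    a = _coef_matrix(model)
    psi = np.diag([model.residual_variance[n] for n in model.nodes])
    eye_minus = np.eye(k) - a
    # (I - A) is unit lower-triangular in topological order, hence always
    # invertible for a DAG; guard anyway.
    try:
        inv = np.linalg.inv(eye_minus)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - unreachable for DAGs
        raise ChangesimError(f"(I - A) is singular: {exc}") from exc
    sigma = inv @ psi @ inv.T
    sigma = (sigma + sigma.T) / 2.0
    if standardized:
        means = np.zeros(k)
        return CovarianceStructure(model.nodes, sigma, means)
    d = np.array([model.sd(n) for n in model.nodes])
    means = np.array([model.mean(n) for n in model.nodes])
    return CovarianceStructure(model.nodes, sigma * np.outer(d, d), means)


def total_effect(
    model: StructuralModel, cause: str, outcome: str, units: str = "natural"
) -> float:
    """Total causal effect of ``cause`` on ``outcome``: the sum over all
    directed paths of the product of path coefficients, i.e. the
    ``(outcome, cause)`` entry of ``(I-A)^{-1} - I``.

    ``units="natural"`` multiplies the standardized effect by
    ``sd(outcome)/sd(cause)``; 0 is returned when no directed path exists.
    """
    if units not in ("natural", "standardized"):
        raise ValueError(f"units must be 'natural' or 'standardized', got {units!r}")
    model = validate_model(model)
    for n in (cause, outcome):
        if n not in model.nodes:
            raise UnknownNodeError(f"unknown node {n!r}")
    idx = {n: i for i, n in enumerate(model.nodes)}
    k = len(model.nodes)
    a = _coef_matrix(model)
    t = np.linalg.inv(np.eye(k) - a) - np.eye(k)
    eff = float(t[idx[outcome], idx[cause]])
    if units == "natural":
        eff *= model.sd(outcome) / model.sd(cause)
    return eff


# -- serialization --------------------------------------------------------

def model_to_json(model: StructuralModel) -> str:
    """Lossless JSON serialization (nodes, paths, scales, latents,
    explicit residual variances)."""
    doc = {
        "nodes": list(model.nodes),
        "paths": [[p, c, b] for p, c, b in model.paths],
        "residual_variance": dict(model.residual_variance) if model.residual_variance else None,
        "scale": {n: list(v) for n, v in model.scale.items()},
        "latents": sorted(model.latents),
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> StructuralModel:
    doc = json.loads(text)
    return StructuralModel(
        nodes=tuple(doc["nodes"]),
        paths=tuple((p, c, float(b)) for p, c, b in doc["paths"]),
        residual_variance=doc.get("residual_variance"),
        scale={n: (float(s), float(m)) for n, (s, m) in doc.get("scale", {}).items()},
        latents=frozenset(doc.get("latents", [])),
    )


def model_to_dot(model: StructuralModel, name: str = "model") -> str:
    """Graphviz DOT text; latent nodes are drawn dashed."""
    lines = [f'digraph "{name}" {{', "  rankdir=LR;"]
    for n in model.nodes:
        style = ' [style=dashed]' if n in model.latents else ""
        lines.append(f'  "{n}"{style};')
    for p, c, b in model.paths:
        lines.append(f'  "{p}" -> "{c}" [label="{b:g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
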