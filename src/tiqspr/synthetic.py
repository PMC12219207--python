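"""Seeded generators for synthetic study inputs.

Three generators mirror the statistical structure each pipeline stage assumes,
so every stage can be validated without external data:

* :func:`random_molecular_graph` -- connected simple graphs with bounded
  degree (default 4, the organic valence bound), built spanning-tree-first so
  connectivity never needs rejection sampling;
* :func:`synth_qspr_dataset` -- index tables from random graphs with a linear
  response ``y = c + sum b_i I_i + Normal(0, sigma^2)`` and known truth, for
  regression-recovery and coverage studies;
* :func:`synth_decision_matrix` -- positive decision matrices, optionally with
  a planted dominant (per-criterion max) and/or dominated (per-criterion min)
  alternative, mirroring the extreme alternatives of the drug tables.

All generators are pure functions of their seed and parameters; each call
draws from its own ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices as _indices
from .mcdm import DecisionMatrix
from .molgraph import MolecularGraph

__all__ = [
    "random_molecular_graph",
    "SyntheticQsprConfig",
    "synth_qspr_dataset",
    "synth_decision_matrix",
]


def random_molecular_graph(
    n_vertices: int,
    max_degree: int = 4,
    extra_edge_prob: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> MolecularGraph:
    """Connected simple graph with all degrees <= ``max_degree``.

    A random spanning tree is grown by attaching each new vertex to a
    uniformly chosen existing vertex of residual capacity; then every
    remaining vertex pair is considered once (in fixed order) and an edge is
    added with probability ``extra_edge_prob`` if both endpoints stay within
    the degree bound.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    if max_degree == 1 and n_vertices > 2:
        raise ValueError("max_degree 1 only admits a single edge (n_vertices == 2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    degree = np.zeros(n_vertices, dtype=int)
    edges: list[tuple[int, int]] = []
    for v in range(1, n_vertices):
        candidates = [u for u in range(v) if degree[u] < max_degree]
        u = int(rng.choice(candidates))
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1
    if extra_edge_prob > 0:
        existing = set(edges)
        for u in range(n_vertices):
            for v in range(u + 1, n_vertices):
                if (u, v) in existing:
                    continue
                if degree[u] >= max_degree or degree[v] >= max_degree:
                    continue
                if rng.random() < extra_edge_prob:
                    edges.append((u, v))
                    existing.add((u, v))
                    degree[u] += 1
                    degree[v] += 1
    return MolecularGraph.from_edges(edges)


@dataclass(frozen=True)
class SyntheticQsprConfig:
    """Configuration of a synthetic structure-property dataset."""

    n_compounds: int = 50
    intercept: float = 10.0
    #: true coefficients keyed by index id; the keys are the regressor set
    coefficients: dict[str, float] = field(default_factory=lambda: {"M1": 2.0, "R": -5.0})
    noise_sd: float = 1.0
    n_vertices_range: tuple[int, int] = (8, 20)
    extra_edge_prob: float = 0.25
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = [k for k in self.coefficients if k not in _indices.INDEX_IDS]
        if unknown:
            raise ValueError(f"unknown index ids in coefficients: {unknown}")


def synth_qspr_dataset(
    cfg: SyntheticQsprConfig,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Index table, noisy linear response and ground truth.

    Compounds are random bounded-degree graphs; all eleven indices are
    computed for each, and the response is linear in the configured subset
    with additive Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.n_vertices_range
    rows = {}
    for i in range(cfg.n_compounds):
        n = int(rng.integers(lo, hi + 1))
        g = random_molecular_graph(n, extra_edge_prob=cfg.extra_edge_prob, seed=rng)
        rows[f"compound_{i:03d}"] = _indices.compute_from_graph(g)
    table = pd.DataFrame(rows).T[list(_indices.INDEX_IDS)]

    X = table[list(cfg.coefficients)].values
    beta = np.array(list(cfg.coefficients.values()))
    y = cfg.intercept + X @ beta + rng.normal(0.0, cfg.noise_sd, size=len(table))
    truth = {"intercept": cfg.intercept, **cfg.coefficients}
    return table, pd.Series(y, index=table.index, name="response"), truth


def synth_decision_matrix(
    n_alternatives: int,
    n_criteria: int,
    with_dominant: bool = False,
    with_dominated: bool = False,
    seed: int | None = None,
) -> DecisionMatrix:
    """Uniform-positive decision matrix with optional planted extremes.

    The dominant alternative is set to 1.1x the per-criterion maximum of the
    others; the dominated one to 0.9x the per-criterion minimum.
    """
    if n_alternatives < 2:
        raise ValueError("need at least 2 alternatives")
    rng = np.random.default_rng(seed)
    data = rng.uniform(1.0, 10.0, size=(n_alternatives, n_criteria))
    names = [f"alt_{i:02d}" for i in range(n_alternatives)]
    df = pd.DataFrame(data, index=names, columns=[f"crit_{j}" for j in range(n_criteria)])
    plain = df.index.tolist()
    if with_dominant:
        plain.remove("alt_00")
        df.loc["alt_00"] = df.loc[plain].max(axis=0) * 1.1
    if with_dominated:
        victim = "alt_01" if with_dominant else "alt_00"
        others = [a for a in df.index if a != victim]
        df.loc[victim] = df.loc[others].min(axis=0) * 0.9
    return DecisionMatrix(df)
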