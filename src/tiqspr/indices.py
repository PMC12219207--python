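"""The eleven degree-based topological indices.

Every index is a sum over the edges ``uv`` of a molecular graph of a term
depending only on the endpoint degrees ``(d_u, d_v)``:

=====  ==========================  =========================================
id     name                        per-edge term for degrees (a, b)
=====  ==========================  =========================================
M1     first Zagreb                a + b
M2     second Zagreb               a * b
H      harmonic                    2 / (a + b)
HM     hyper-Zagreb                (a + b)^2
F      forgotten                   a^2 + b^2
ABC    atom-bond connectivity      sqrt((a + b - 2) / (a * b))
R      Randic                      1 / sqrt(a * b)
SC     sum-connectivity            1 / sqrt(a + b)
GA     geometric-arithmetic        2 sqrt(a * b) / (a + b)
SO     Sombor                      sqrt(a^2 + b^2)
N      Nirmala                     sqrt(a + b)
=====  ==========================  =========================================

Because the terms depend only on degrees, each index is computed from an
:class:`~tiqspr.molgraph.EdgePartition` as ``sum(count(a,b) * term(a,b))``,
and the exact identity ``HM = F + 2*M2`` holds (per edge,
``(a+b)^2 = a^2+b^2 + 2ab``).
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import pandas as pd

from .molgraph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "INDEX_IDS",
    "edge_contribution",
    "compute_index",
    "compute_all",
    "compute_from_graph",
    "compute_table",
    "round_half_away",
]

#: Canonical ordering, matching the tabulated column order.
INDEX_IDS = ("M1", "M2", "H", "HM", "F", "ABC", "R", "SC", "GA", "SO", "N")

#: Indices that are integer-valued whenever the degree counts are integers.
INTEGER_INDEX_IDS = ("M1", "M2", "HM", "F")


def edge_contribution(index_id: str, a: int, b: int) -> float:
    """Per-edge term of index ``index_id`` for an edge with endpoint degrees
    ``a`` and ``b`` (order irrelevant).

    ABC is undefined at a (1, 1) edge (an isolated two-atom molecule), where
    the radicand is 0/1 with both endpoint degrees contributing nothing to
    connectivity beyond the edge itself; callers that sum over whole graphs
    treat it as the limit 0 (see :func:`compute_index`).
    """
    if a < 1 or b < 1 or a != int(a) or b != int(b):
        raise ValueError(f"degrees must be integers >= 1, got ({a}, {b})")
    a, b = int(a), int(b)
    s, p = a + b, a * b
    if index_id == "M1":
        return float(s)
    if index_id == "M2":
        return float(p)
    if index_id == "H":
        return 2.0 / s
    if index_id == "HM":
        return float(s * s)
    if index_id == "F":
        return float(a * a + b * b)
    if index_id == "ABC":
        if (a, b) == (1, 1):
            raise ValueError("ABC contribution is undefined for a (1, 1) edge")
        return math.sqrt((s - 2) / p)
    if index_id == "R":
        return 1.0 / math.sqrt(p)
    if index_id == "SC":
        return 1.0 / math.sqrt(s)
    if index_id == "GA":
        return 2.0 * math.sqrt(p) / s
    if index_id == "SO":
        return math.sqrt(a * a + b * b)
    if index_id == "N":
        return math.sqrt(s)
    raise ValueError(f"unknown index id {index_id!r}; valid ids: {', '.join(INDEX_IDS)}")


def compute_index(partition: EdgePartition, index_id: str) -> float:
    """Evaluate one index as a weighted sum of per-edge terms over a partition."""
    if partition.n_edges == 0:
        raise ValueError("cannot compute an index of an empty partition")
    total = 0.0
    for (a, b), n in partition.items():
        if index_id == "ABC" and (a, b) == (1, 1):
            warnings.warn(
                "ABC term at a (1, 1) edge taken as its limit 0", stacklevel=2
            )
            continue
        total += n * edge_contribution(index_id, a, b)
    return total


def compute_all(partition: EdgePartition) -> pd.Series:
    """All eleven indices of a partition, as a Series in canonical order."""
    return pd.Series(
        {idx: compute_index(partition, idx) for idx in INDEX_IDS}, name="index_value"
    )


def compute_from_graph(g: MolecularGraph) -> pd.Series:
    """Convenience: partition the graph, then compute all indices."""
    return compute_all(edge_partition(g))


def compute_table(graphs: Mapping[str, MolecularGraph]) -> pd.DataFrame:
    """Index table (rows = molecule names, columns = indices) for a batch of
    graphs, in the packaged fixture schema."""
    return pd.DataFrame({name: compute_from_graph(g) for name, g in graphs.items()}).T[
        list(INDEX_IDS)
    ]


def round_half_away(x: float, decimals: int = 3) -> float:
    """Round half away from zero, the convention used for printed comparisons
    (Python's built-in round is half-to-even)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
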