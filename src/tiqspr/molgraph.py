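"""Hydrogen-suppressed molecular graphs and edge partitions.

A molecule is modelled as a simple undirected graph on its heavy (non-hydrogen)
atoms; bond orders, charges and geometry are ignored.  All degree-based
topological indices handled by this package are sums of per-edge terms that
depend only on the two endpoint degrees, so the *edge partition* -- the count
of edges per unordered endpoint-degree pair ``(a, b)`` -- is a sufficient
statistic and the central object here.

The module also solves the inverse problem: given a vector of index values,
recover an integer edge partition that reproduces them
(:func:`recover_partition`).  This is how partitions of molecules whose graphs
are not published can be audited from their tabulated index values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "EdgeListParseError",
    "graph_from_edge_list",
    "edge_partition",
    "write_edge_list",
    "recover_partition",
    "PartitionRecovery",
    "InfeasiblePartitionError",
]

CHEMISTRY_MAX_DEGREE = 4


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list text; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class MolecularGraph:
    """Simple undirected graph of heavy atoms.

    Thin wrapper over :class:`networkx.Graph` that enforces the invariants the
    index formulas rely on: no self-loops, no parallel edges, no isolated
    vertices (every atom participates in at least one bond).  In chemistry
    mode the maximum degree is checked against the organic valence bound of 4.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops}")
        isolated = [v for v, d in g.degree() if d == 0]
        if isolated:
            raise ValueError(f"isolated vertices are not allowed: {isolated}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]]) -> "MolecularGraph":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> dict[int, int]:
        return dict(self.graph.degree())

    @property
    def max_degree(self) -> int:
        return max(d for _, d in self.graph.degree())

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def validate_chemistry(self) -> None:
        """Warn on features a heavy-atom molecular graph should not have."""
        if self.max_degree > CHEMISTRY_MAX_DEGREE:
            warnings.warn(
                f"maximum degree {self.max_degree} exceeds the organic valence "
                f"bound of {CHEMISTRY_MAX_DEGREE}",
                stacklevel=2,
            )
        if not self.is_connected():
            warnings.warn("graph is not connected", stacklevel=2)

    def edge_partition(self) -> "EdgePartition":
        return edge_partition(self)


@dataclass(frozen=True)
class EdgePartition:
    """Counts of edges by unordered endpoint-degree pair ``(a, b)``, a <= b."""

    counts: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[tuple[int, int], int] = {}
        for (a, b), n in self.counts.items():
            if not (1 <= a <= b):
                raise ValueError(f"invalid degree pair ({a}, {b}); need 1 <= a <= b")
            if n < 0 or n != int(n):
                raise ValueError(f"count for ({a}, {b}) must be a nonnegative integer, got {n}")
            if n:
                clean[(int(a), int(b))] = int(n)
        object.__setattr__(self, "counts", clean)

    @property
    def n_edges(self) -> int:
        return sum(self.counts.values())

    def items(self):
        return sorted(self.counts.items())

    def __getitem__(self, pair: tuple[int, int]) -> int:
        return self.counts.get(pair, 0)

    def __eq__(self, other) -> bool:
        if isinstance(other, EdgePartition):
            return dict(self.counts) == dict(other.counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))


def graph_from_edge_list(text: str) -> MolecularGraph:
    """Parse edge-list text: one edge per line, two whitespace-separated
    0-based integer vertex ids; ``#`` starts a comment line.

    Self-loops, duplicate edges and non-integer tokens are parse errors (with
    line numbers) rather than silently dropped, because every edge changes
    every index value.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise EdgeListParseError(f"expected two vertex ids, got {tokens!r}", lineno)
        try:
            u, v = int(tokens[0]), int(tokens[1])
        except ValueError:
            raise EdgeListParseError(f"non-integer vertex id in {tokens!r}", lineno) from None
        if u < 0 or v < 0:
            raise EdgeListParseError(f"negative vertex id in {tokens!r}", lineno)
        if u == v:
            raise EdgeListParseError(f"self-loop at vertex {u}", lineno)
        key = (min(u, v), max(u, v))
        if key in seen:
            raise EdgeListParseError(f"duplicate edge {key}", lineno)
        seen.add(key)
        edges.append((u, v))
    if not edges:
        raise ValueError("edge list is empty")
    return MolecularGraph.from_edges(edges)


def write_edge_list(g: MolecularGraph) -> str:
    """Serialise a graph to the edge-list dialect; edges sorted for determinism."""
    lines = [f"{u} {v}" for u, v in sorted((min(u, v), max(u, v)) for u, v in g.graph.edges())]
    return "\n".join(lines) + "\n"


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Group the edges of ``g`` by unordered endpoint-degree pair."""
    if g.n_edges == 0:
        raise ValueError("cannot partition an empty graph")
    deg = dict(g.graph.degree())
    counts: dict[tuple[int, int], int] = {}
    for u, v in g.graph.edges():
        a, b = sorted((deg[u], deg[v]))
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return EdgePartition(counts)


# ---------------------------------------------------------------------------
# Partition recovery from an index vector
# ---------------------------------------------------------------------------

# Per-edge contributions for a degree pair (a, b).  Kept local so the search is
# self-contained; tiqspr.indices holds the public definitions.
def _contrib(a: int, b: int) -> dict[str, float]:
    s, p = a + b, a * b
    return {
        "M1": float(s),
        "M2": float(p),
        "H": 2.0 / s,
        "HM": float(s * s),
        "F": float(a * a + b * b),
        "ABC": math.sqrt((s - 2) / p) if (a, b) != (1, 1) else 0.0,
        "R": 1.0 / math.sqrt(p),
        "SC": 1.0 / math.sqrt(s),
        "GA": 2.0 * math.sqrt(p) / s,
        "SO": math.sqrt(a * a + b * b),
        "N": math.sqrt(s),
    }


_SOFT_KEYS = ("H", "ABC", "R", "SC", "GA", "SO", "N")


class InfeasiblePartitionError(ValueError):
    """No nonnegative integer partition matches the integer-valued indices.

    ``best_residual`` is the smallest squared deviation over all eleven index
    values achieved by any partition reproducing M1 exactly (M1 is the most
    robust integer target), so the failure is auditable.
    """

    def __init__(self, message: str, best_residual: float | None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class PartitionRecovery:
    """Result of :func:`recover_partition`."""

    partition: EdgePartition
    residual: float  # squared deviation over the seven non-integer indices
    unique: bool  # whether the optimum count vector is unique


class _SearchBudgetExceeded(Exception):
    pass


def _search(
    targets: Mapping[str, float],
    pairs: list[tuple[int, int]],
    soft_tol: float,
    exact_m2_f: bool,
    max_nodes: int = 20_000_000,
) -> list[tuple[float, tuple[int, ...]]]:
    """Enumerate integer count vectors matching M1 (and optionally M2, F)
    exactly, with branch-and-bound pruning on the remaining indices.

    Every per-edge contribution is positive, so for each partial assignment and
    each index the attainable final value lies in an interval determined by the
    remaining M1 budget and the extreme per-unit-of-M1 contribution ratios of
    the remaining pairs.  Prune whenever a target falls outside that interval
    (widened by ``soft_tol``).  When ``exact_m2_f`` is false, M2 and F join the
    soft targets instead of being matched exactly.  ``max_nodes`` bounds the
    search; partial results are returned if the budget is hit.
    """
    keys = [k for k in _SOFT_KEYS if k in targets]
    if not exact_m2_f:
        keys = keys + ["M2", "F"]
    contribs = {p: _contrib(*p) for p in pairs}
    order = sorted(pairs, key=lambda p: -(p[0] + p[1]))
    n_pairs = len(order)

    tracked = list(keys) + (["M2", "F"] if exact_m2_f else [])
    min_ratio: dict[tuple[int, str], float] = {}
    max_ratio: dict[tuple[int, str], float] = {}
    for i in range(n_pairs):
        rest = order[i:]
        for k in tracked:
            ratios = [contribs[p][k] / contribs[p]["M1"] for p in rest]
            min_ratio[(i, k)] = min(ratios)
            max_ratio[(i, k)] = max(ratios)

    m1 = int(targets["M1"])
    m2 = int(targets["M2"]) if exact_m2_f else None
    f = int(targets["F"]) if exact_m2_f else None
    sols: list[tuple[float, tuple[int, ...]]] = []
    nodes = [0]

    def rec(i: int, rem1: int, rem2, remf, partial: list[float], counts: list[int]) -> None:
        nodes[0] += 1
        if nodes[0] > max_nodes:
            raise _SearchBudgetExceeded
        if rem1 == 0:
            if exact_m2_f and (rem2 != 0 or remf != 0):
                return
            resid = sum((partial[j] - targets[k]) ** 2 for j, k in enumerate(keys))
            sols.append((resid, tuple(counts + [0] * (n_pairs - len(counts)))))
            return
        if i == n_pairs:
            return
        if exact_m2_f:
            if not (rem1 * min_ratio[(i, "M2")] - 1e-9 <= rem2 <= rem1 * max_ratio[(i, "M2")] + 1e-9):
                return
            if not (rem1 * min_ratio[(i, "F")] - 1e-9 <= remf <= rem1 * max_ratio[(i, "F")] + 1e-9):
                return
        for j, k in enumerate(keys):
            lo = partial[j] + rem1 * min_ratio[(i, k)]
            hi = partial[j] + rem1 * max_ratio[(i, k)]
            if targets[k] < lo - soft_tol or targets[k] > hi + soft_tol:
                return
        p = order[i]
        cc = contribs[p]
        hi_n = rem1 // int(cc["M1"])
        if exact_m2_f:
            hi_n = min(hi_n, rem2 // int(cc["M2"]), remf // int(cc["F"]))
        for n in range(int(hi_n) + 1):
            rec(
                i + 1,
                rem1 - n * int(cc["M1"]),
                rem2 - n * int(cc["M2"]) if exact_m2_f else None,
                remf - n * int(cc["F"]) if exact_m2_f else None,
                [partial[j] + n * cc[k] for j, k in enumerate(keys)],
                counts + [n],
            )

    try:
        rec(0, m1, m2, f, [0.0] * len(keys), [])
    except _SearchBudgetExceeded:
        pass
    # canonical pair order for reported count vectors
    canon = sorted(pairs)
    remap = [order.index(p) for p in canon]
    out = [(r, tuple(c[j] for j in remap)) for r, c in sols]
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def recover_partition(
    index_vector: Mapping[str, float],
    max_degree: int = CHEMISTRY_MAX_DEGREE,
    soft_tol: float = 0.05,
) -> PartitionRecovery:
    """Recover an integer edge partition from an index vector.

    The three independent integer-valued indices M1, M2 and F are matched
    exactly (HM is determined by the identity ``HM = F + 2*M2`` and is checked
    against the input); among exact matches the squared deviation over the
    seven non-integer indices is minimised.  Ties are broken by lexicographic
    order of the count vector over degree pairs sorted ascending, and
    uniqueness of the optimum is reported.

    ``soft_tol`` is the per-index slack used for search pruning; it must cover
    the rounding of the input values (0.05 is ample for 3-decimal tables and
    for full-precision round trips alike).

    Raises
    ------
    InfeasiblePartitionError
        If the integer indices admit no nonnegative integer partition (for
        instance when the input row itself is internally inconsistent).  The
        error carries the best residual over all eleven indices achieved by
        any partition matching M1 alone.
    """
    iv = dict(index_vector)
    missing = [k for k in ("M1", "M2", "HM", "F", *_SOFT_KEYS) if k not in iv]
    if missing:
        raise ValueError(f"index vector is missing entries: {missing}")
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    pairs = [(a, b) for a in range(1, max_degree + 1) for b in range(a, max_degree + 1)]

    for k in ("M1", "M2", "HM", "F"):
        if abs(iv[k] - round(iv[k])) > 1e-6:
            raise ValueError(f"{k} must be integer-valued, got {iv[k]}")
    m1, m2, hm, f = (int(round(iv[k])) for k in ("M1", "M2", "HM", "F"))

    identity_gap = hm - f - 2 * m2
    sols = []
    if identity_gap == 0:
        # Escalate the pruning window until the optimum is certified global:
        # any count vector excluded at window tol has residual > tol^2, so a
        # found optimum with residual <= tol^2 cannot be beaten outside it.
        for tol in (soft_tol, 0.6, 2.0, 8.0):
            if tol < soft_tol:
                continue
            sols = _search(iv, pairs, tol, exact_m2_f=True)
            if sols and sols[0][0] <= tol * tol:
                break
    if not sols:
        best = None
        for relaxed_tol in (0.5, 2.0, 8.0):  # escalate until a near-miss is found
            relaxed = _search(iv, pairs, soft_tol=relaxed_tol, exact_m2_f=False, max_nodes=2_000_000)
            if relaxed:
                best = relaxed[0][0]
                break
        detail = (
            f"printed HM violates HM = F + 2*M2 by {identity_gap}; "
            if identity_gap != 0
            else ""
        )
        raise InfeasiblePartitionError(
            f"{detail}no nonnegative integer partition with max degree {max_degree} "
            f"matches M1={m1}, M2={m2}, F={f}",
            best_residual=best,
        )
    best_resid, best_counts = sols[0]
    unique = not (len(sols) > 1 and abs(sols[1][0] - best_resid) < 1e-12)
    canon = sorted(pairs)
    partition = EdgePartition({p: c for p, c in zip(canon, best_counts) if c})
    return PartitionRecovery(partition=partition, residual=best_resid, unique=unique)
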