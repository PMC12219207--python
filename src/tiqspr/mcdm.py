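"""Multi-criteria ranking of drug alternatives: TOPSIS and VIKOR.

Both methods score each alternative (drug) over a matrix of criteria.  In this
study every criterion is *beneficial* (larger is better): the drug that is
maximal on every criterion ranks first under both methods.

The published rankings are reproduced with the topological-index table as the
decision matrix -- equal weights for TOPSIS, and for the per-property VIKOR
runs "ratio" weights proportional to the absolute correlation of each index
with the target property.  The property table can be used as the matrix
instead, in which case the five missing cells must be resolved by an explicit,
logged policy (:func:`build_decision_matrix`).

TOPSIS
    vector-normalise each column, weight, then score each alternative by its
    relative closeness ``C = D-/(D+ + D-)`` to the ideal (per-criterion max)
    and anti-ideal (min) points; rank 1 = largest C.

VIKOR
    per-criterion best ``f*`` and worst ``f-``; group utility
    ``S_j = sum_i w_i (f*_i - f_ij)/(f*_i - f-_i)``, individual regret
    ``R_j = max_i`` of the same terms, and the compromise score
    ``Q_j = v (S_j - S*)/(S- - S*) + (1 - v)(R_j - R*)/(R- - R*)``;
    rank 1 = smallest Q.  ``v`` (default 0.5) trades group utility against
    regret; the standard acceptable-advantage and acceptable-stability
    conditions of the compromise solution are reported as flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DecisionMatrix",
    "build_decision_matrix",
    "equal_weights",
    "ratio_weights",
    "correlation_ratio_weights",
    "TopsisResult",
    "VikorResult",
    "topsis",
    "vikor",
    "rank_report",
]


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria matrix with per-criterion direction flags.

    ``directions`` maps each criterion to +1 (beneficial, larger is better)
    or -1 (cost).  All criteria in this study are beneficial, the default.
    ``substitutions`` records any missing-value substitutions applied while
    building the matrix, for auditability.
    """

    data: pd.DataFrame
    directions: pd.Series | None = None
    substitutions: tuple[tuple[str, str, float, str], ...] = ()  # (row, col, value, how)

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2 or self.data.shape[1] < 1:
            raise ValueError("need at least 2 alternatives and 1 criterion")
        if self.data.isna().any().any():
            raise ValueError("decision matrix has missing cells; apply a missing-value policy")
        if self.directions is None:
            object.__setattr__(
                self, "directions", pd.Series(1, index=self.data.columns, dtype=int)
            )
        elif not self.directions.index.equals(self.data.columns):
            raise ValueError("directions must be indexed by the criteria")
        norms = np.sqrt((self.data.astype(float) ** 2).sum(axis=0))
        if (norms == 0).any():
            zero = list(norms[norms == 0].index)
            raise ValueError(f"criteria with zero norm: {zero}")

    @property
    def alternatives(self) -> list:
        return list(self.data.index)

    @property
    def criteria(self) -> list:
        return list(self.data.columns)


MissingPolicy = Literal["predicted", "mean", "drop-criterion"]


def build_decision_matrix(
    source: Literal["properties", "indices"] = "indices",
    missing_policy: MissingPolicy = "predicted",
    property_table: pd.DataFrame | None = None,
    index_table: pd.DataFrame | None = None,
) -> DecisionMatrix:
    """Build the drug decision matrix from the packaged study tables.

    ``indices`` yields the complete 22 x 11 index matrix (no substitutions).
    ``properties`` yields the 22 x 7 property matrix, whose five missing cells
    are resolved by ``missing_policy``:

    * ``predicted`` -- substitute the refit regression-model prediction for
      that property (computed at run time from the index table);
    * ``mean`` -- substitute the column mean of the observed values;
    * ``drop-criterion`` -- drop every column with a missing cell.

    Every substitution is logged and recorded on the returned matrix.
    """
    from . import fixtures

    if property_table is None:
        property_table = fixtures.load_property_table()
    if index_table is None:
        index_table = fixtures.load_index_table()

    if source == "indices":
        return DecisionMatrix(index_table.astype(float).copy())
    if source != "properties":
        raise ValueError(f"unknown source {source!r}; use 'properties' or 'indices'")

    data = property_table.astype(float).copy()
    subs: list[tuple[str, str, float, str]] = []
    if missing_policy == "drop-criterion":
        complete = data.columns[data.notna().all(axis=0)]
        dropped = [c for c in data.columns if c not in complete]
        logger.info("drop-criterion policy dropped columns %s", dropped)
        data = data[complete]
    elif missing_policy in ("mean", "predicted"):
        predictions: dict[str, pd.Series] = {}
        if missing_policy == "predicted":
            from .qspr import fit_mlr, predict

            specs = fixtures.load_model_specs()
            by_response = {s.response: s for s in specs.values()}
            for col in data.columns[data.isna().any(axis=0)]:
                fit = fit_mlr(property_table, index_table, by_response[col])
                predictions[col] = predict(fit, index_table)
        for col in data.columns:
            for row in data.index[data[col].isna()]:
                if col in predictions:
                    value, how = float(predictions[col][row]), "model prediction"
                else:
                    value, how = float(data[col].mean()), "column mean"
                data.loc[row, col] = value
                subs.append((row, col, value, how))
                logger.info("substituted %s/%s = %.4g (%s)", row, col, value, how)
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    if data.isna().any().any():
        raise ValueError("missing-value policy left unresolved cells")
    return DecisionMatrix(data, substitutions=tuple(subs))


def equal_weights(n_criteria: int) -> np.ndarray:
    """Uniform weight vector ``w_i = 1/n``."""
    if n_criteria < 1:
        raise ValueError("need at least one criterion")
    return np.full(n_criteria, 1.0 / n_criteria)


def ratio_weights(scores: Iterable[float]) -> np.ndarray:
    """Weights proportional to nonnegative importance scores, ``w_i = s_i / sum s``."""
    s = np.asarray(list(scores), dtype=float)
    if (s < 0).any():
        raise ValueError("ratio scores must be nonnegative")
    total = s.sum()
    if total <= 0:
        raise ValueError("ratio scores must not all be zero")
    return s / total


def correlation_ratio_weights(
    target_property: str,
    property_table: pd.DataFrame,
    index_table: pd.DataFrame,
) -> pd.Series:
    """Ratio weights over the index criteria: proportional to the absolute
    Pearson correlation of each index with ``target_property``."""
    from .qspr import correlation_table

    r = correlation_table(index_table, property_table).r.loc[target_property]
    return pd.Series(ratio_weights(r.abs().values), index=index_table.columns)


def _as_weight_array(w, criteria) -> np.ndarray:
    if isinstance(w, pd.Series):
        w = w.reindex(criteria).values
    w = np.asarray(w, dtype=float)
    if len(w) != len(criteria):
        raise ValueError("weight vector length does not match the criteria")
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def _ranks(scores: pd.Series, ascending: bool) -> pd.Series:
    """Ranks 1..m, ties broken deterministically by alternative name."""
    order = scores.sort_index().sort_values(ascending=ascending, kind="stable")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return ranks.reindex(scores.index)


@dataclass(frozen=True)
class TopsisResult:
    weighted: pd.DataFrame
    ideal: pd.Series
    anti_ideal: pd.Series
    d_plus: pd.Series
    d_minus: pd.Series
    closeness: pd.Series
    ranks: pd.Series


def topsis(matrix: DecisionMatrix, weights) -> TopsisResult:
    """Rank alternatives by relative closeness to the ideal point."""
    D = matrix.data.astype(float)
    w = _as_weight_array(weights, matrix.criteria)
    X = D.values * matrix.directions.values  # cost criteria flip sign
    R = X / np.sqrt((X**2).sum(axis=0))
    V = pd.DataFrame(R * w, index=D.index, columns=D.columns)
    ideal = V.max(axis=0)
    anti = V.min(axis=0)
    d_plus = np.sqrt(((V - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    if (denom == 0).any():
        raise ValueError("all alternatives identical: D+ + D- = 0")
    closeness = d_minus / denom
    return TopsisResult(
        weighted=V,
        ideal=ideal,
        anti_ideal=anti,
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=closeness,
        ranks=_ranks(closeness, ascending=False),
    )


@dataclass(frozen=True)
class VikorResult:
    f_star: pd.Series
    f_minus: pd.Series
    S: pd.Series
    R: pd.Series
    Q: pd.Series
    ranks: pd.Series
    v: float
    acceptable_advantage: bool
    acceptable_stability: bool


def vikor(matrix: DecisionMatrix, weights, v: float = 0.5) -> VikorResult:
    """Compromise ranking by group utility S, individual regret R and blend Q."""
    if not 0.0 <= v <= 1.0:
        raise ValueError("v must be in [0, 1]")
    D = matrix.data.astype(float)
    w = _as_weight_array(weights, matrix.criteria)
    X = D.values * matrix.directions.values
    f_star = X.max(axis=0)
    f_minus = X.min(axis=0)
    spread = f_star - f_minus
    safe = np.where(spread > 0, spread, 1.0)  # degenerate criterion: term is 0
    terms = w * (f_star - X) / safe
    S = pd.Series(terms.sum(axis=1), index=D.index)
    R = pd.Series(terms.max(axis=1), index=D.index)

    def _scaled(col: pd.Series) -> pd.Series:
        lo, hi = col.min(), col.max()
        if hi == lo:
            import warnings

            warnings.warn("all alternatives tie; Q term defined as 0", stacklevel=3)
            return col * 0.0
        return (col - lo) / (hi - lo)

    Q = v * _scaled(S) + (1.0 - v) * _scaled(R)
    ranks = _ranks(Q, ascending=True)
    ordered = Q.sort_values(kind="stable")
    m = len(Q)
    dq = 1.0 / (m - 1)
    advantage = bool(m >= 2 and (ordered.iloc[1] - ordered.iloc[0]) >= dq)
    best = ordered.index[0]
    stability = bool(
        _ranks(S, ascending=True)[best] == 1 or _ranks(R, ascending=True)[best] == 1
    )
    return VikorResult(
        f_star=pd.Series(f_star, index=D.columns),
        f_minus=pd.Series(f_minus, index=D.columns),
        S=S,
        R=R,
        Q=Q,
        ranks=ranks,
        v=v,
        acceptable_advantage=advantage,
        acceptable_stability=stability,
    )


def rank_report(results: dict[str, TopsisResult | VikorResult]) -> pd.DataFrame:
    """Side-by-side rank columns for several runs plus agreement statistics.

    Returns a frame with one rank column per run and attrs
    ``n_identical_rank`` (alternatives keeping the same rank in every run).
    """
    if not results:
        raise ValueError("no results to report")
    cols = {}
    index = None
    for name, res in results.items():
        ranks = res.ranks
        if index is None:
            index = ranks.index
        elif set(index) != set(ranks.index):
            raise ValueError("results do not share the alternative set")
        cols[name] = ranks.reindex(index)
    report = pd.DataFrame(cols, index=index)
    identical = (report.nunique(axis=1) == 1)
    report.attrs["n_identical_rank"] = int(identical.sum())
    report.attrs["identical_rank_alternatives"] = list(report.index[identical])
    return report
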