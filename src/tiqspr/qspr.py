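"""QSPR layer: correlation screening, enter-method multiple linear regression
and property prediction.

Physicochemical properties are regressed on topological indices with ordinary
least squares in which *all* chosen regressors enter simultaneously (the
"enter" method -- no stepwise selection).  Missing data are handled by
listwise deletion on the response only; the index table is complete, so each
model's sample size is 22 minus the number of drugs missing that property.

Fit-statistic conventions
-------------------------
The published statistics are reproduced with::

    SST  = sum (y - ybar)^2              SSE = sum residual^2
    R^2  = 1 - SSE/SST                   r   = +sqrt(R^2)
    SE   = sqrt(SSE / (n - k - 1))       RMSE = sqrt(SSE / n)
    F    = (R^2/k) / ((1 - R^2)/(n - k - 1))
    p    = upper tail of F at (k, n - k - 1) degrees of freedom

``RMSE = sqrt(SSE/n)`` (not ``/(n-k-1)``) is the only convention consistent
with the published (SE, RMSE, n) triples, e.g. ``2.057^2 * 10 / 21 = 1.419^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "FitStatistics",
    "CorrelationResult",
    "CorrelationTable",
    "pearson_correlation",
    "correlation_table",
    "fit_mlr",
    "fit_statistics",
    "predict",
    "reproduce_models",
]


@dataclass(frozen=True)
class ModelSpec:
    """A published regression model: response property, ordered regressor set,
    and the printed coefficients/statistics used as reference values."""

    model_id: int
    response: str
    regressors: tuple[str, ...]
    printed_intercept: float | None = None
    printed_coefficients: dict[str, float] = field(default_factory=dict)
    printed_stats: dict[str, float] = field(default_factory=dict)


class CorrelationResult(NamedTuple):
    r: float
    n: int


class CorrelationTable(NamedTuple):
    """Pairwise-deletion Pearson correlations (properties x indices) and the
    per-cell number of complete pairs."""

    r: pd.DataFrame
    n: pd.DataFrame


def pearson_correlation(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Sample Pearson correlation on pairwise-complete observations.

    Requires at least 3 complete pairs and nonzero variance in both columns.
    """
    mask = x.notna() & y.notna()
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"correlation undefined: only {n} complete pairs")
    xv = np.asarray(x[mask], dtype=float)
    yv = np.asarray(y[mask], dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined: a column has zero variance")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return CorrelationResult(r=r, n=n)


def correlation_table(index_table: pd.DataFrame, property_table: pd.DataFrame) -> CorrelationTable:
    """Correlation screen of every property against every index."""
    if not index_table.index.equals(property_table.index):
        raise ValueError("index and property tables must share row keys")
    r = pd.DataFrame(index=property_table.columns, columns=index_table.columns, dtype=float)
    n = pd.DataFrame(index=property_table.columns, columns=index_table.columns, dtype=int)
    for prop in property_table.columns:
        for idx in index_table.columns:
            res = pearson_correlation(index_table[idx], property_table[prop])
            r.loc[prop, idx] = res.r
            n.loc[prop, idx] = res.n
    return CorrelationTable(r=r, n=n)


@dataclass(frozen=True)
class RegressionFit:
    """An enter-method OLS fit of one property on a set of indices."""

    spec: ModelSpec
    intercept: float
    coefficients: pd.Series  # aligned with spec.regressors
    rows_used: tuple[str, ...]
    fitted: pd.Series
    residuals: pd.Series

    @property
    def n(self) -> int:
        return len(self.rows_used)

    @property
    def k(self) -> int:
        return len(self.spec.regressors)


@dataclass(frozen=True)
class FitStatistics:
    n: int
    r: float
    r_squared: float
    se: float
    f: float
    rmse: float
    p: float


def _design(index_table: pd.DataFrame, regressors: Sequence[str], rows) -> pd.DataFrame:
    X = index_table.loc[rows, list(regressors)].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_mlr(
    property_table: pd.DataFrame,
    index_table: pd.DataFrame,
    spec: ModelSpec,
) -> RegressionFit:
    """Fit ``Y = c + sum b_i I_i`` by OLS on the complete-case rows.

    Rows missing the response are dropped; every regressor named in the spec
    is retained regardless of significance (enter method).
    """
    missing = [r for r in spec.regressors if r not in index_table.columns]
    if missing:
        raise ValueError(f"regressors absent from index table: {missing}")
    if spec.response not in property_table.columns:
        raise ValueError(f"response {spec.response!r} absent from property table")

    y = property_table[spec.response]
    rows = y[y.notna()].index
    n, k = len(rows), len(spec.regressors)
    if n <= k + 1:
        raise ValueError(f"n={n} rows is not enough to fit {k} regressors with an intercept")

    X = _design(index_table, spec.regressors, rows)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name the columns involved in the collinearity for a usable error
        corr = np.abs(np.corrcoef(X.values[:, 1:], rowvar=False))
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        cols = (spec.regressors[i], spec.regressors[j])
        raise ValueError(f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); most collinear columns: {cols}")

    res = sm.OLS(y.loc[rows].astype(float), X).fit()
    params = res.params
    return RegressionFit(
        spec=spec,
        intercept=float(params["const"]),
        coefficients=params.drop("const").reindex(list(spec.regressors)),
        rows_used=tuple(rows),
        fitted=res.fittedvalues,
        residuals=res.resid,
    )


def fit_statistics(fit: RegressionFit) -> FitStatistics:
    """Summary statistics of a fit, under the conventions in the module docs."""
    n, k = fit.n, fit.k
    if n <= k + 1:
        raise ValueError("fit statistics undefined for n <= k + 1")
    resid = np.asarray(fit.residuals, dtype=float)
    y = np.asarray(fit.fitted, dtype=float) + resid
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    dof = n - k - 1
    f = (r2 / k) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
    p = float(scipy.stats.f.sf(f, k, dof)) if np.isfinite(f) else 0.0
    return FitStatistics(
        n=n,
        r=float(np.sqrt(r2)),
        r_squared=float(r2),
        se=float(np.sqrt(sse / dof)),
        f=float(f),
        rmse=float(np.sqrt(sse / n)),
        p=p,
    )


def predict(fit: RegressionFit, index_table: pd.DataFrame) -> pd.Series:
    """Predicted response ``c + sum b_i I_i`` for every row of the index table.

    Uses the full-precision refit coefficients (not the 3-decimal published
    ones).  Predictions are produced for all drugs, including those excluded
    from fitting because their measured response is missing -- the regressor
    table is complete, so the prediction is well defined.
    """
    X = index_table[list(fit.spec.regressors)].astype(float)
    return (X @ fit.coefficients.values) + fit.intercept


def reproduce_models(
    property_table: pd.DataFrame | None = None,
    index_table: pd.DataFrame | None = None,
    specs: dict[int, ModelSpec] | None = None,
) -> tuple[dict[int, tuple[RegressionFit, FitStatistics]], pd.DataFrame]:
    """Refit all published models and compare statistics with the printed ones.

    Returns the fits plus a tidy comparison report with one row per
    (model, statistic): recomputed value, printed value and absolute deviation.
    Printed p-values are rounded upper bounds, so they are compared as bounds
    (deviation 0 when the recomputed p is at or below the printed value).
    """
    if property_table is None or index_table is None or specs is None:
        from . import fixtures

        property_table = fixtures.load_property_table() if property_table is None else property_table
        index_table = fixtures.load_index_table() if index_table is None else index_table
        specs = fixtures.load_model_specs() if specs is None else specs

    results: dict[int, tuple[RegressionFit, FitStatistics]] = {}
    rows = []
    stat_names = {"n": "n", "r": "r", "R2": "r_squared", "SE": "se", "F": "f", "RMSE": "rmse", "p": "p"}
    for mid, spec in sorted(specs.items()):
        fit = fit_mlr(property_table, index_table, spec)
        stats = fit_statistics(fit)
        results[mid] = (fit, stats)
        for printed_name, attr in stat_names.items():
            recomputed = getattr(stats, attr)
            printed = spec.printed_stats.get(printed_name)
            if printed is None:
                continue
            if printed_name == "p":
                deviation = max(0.0, recomputed - printed)
            else:
                deviation = abs(recomputed - printed)
            rows.append(
                {
                    "model": mid,
                    "response": spec.response,
                    "statistic": printed_name,
                    "recomputed": recomputed,
                    "printed": printed,
                    "abs_deviation": deviation,
                }
            )
    report = pd.DataFrame(rows)
    return results, report
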