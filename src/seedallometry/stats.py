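"""Univariate allometry statistics.

Per-analyte (and per-element) ordinary least-squares regressions on seed
weight, family-wise error control by Bonferroni, volcano-table
construction combining univariate p-values with multivariate loadings,
and exhaustive best-subset multiple regression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when a regression input carries no usable variation."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a response on a single predictor."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple linear regression with a two-sided slope F-test p-value.

    Requires at least three points and non-constant x.  For a single
    predictor the slope F-test and t-test coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points for inference, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateInputError("predictor has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy == 0:
        raise DegenerateInputError("response has zero variance")
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_reg = slope * sxy
    ss_res = max(syy - ss_reg, 0.0)
    r2 = ss_reg / syy
    r2 = min(max(r2, 0.0), 1.0)
    if ss_res == 0.0:
        p = np.finfo(float).tiny if r2 > 0 else 1.0
    else:
        f = ss_reg / (ss_res / (n - 2))
        p = float(sps.f.sf(f, 1, n - 2))
    return RegressionResult(slope=float(slope), intercept=intercept,
                            r_squared=float(r2), p_value=max(p, np.finfo(float).tiny), n=n)


def slope_confidence_interval(result: RegressionResult, x: np.ndarray, y: np.ndarray,
                              level: float = 0.95) -> tuple[float, float]:
    """Two-sided confidence interval for the slope of a fitted regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = result.n
    resid = y - (result.intercept + result.slope * x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    se = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, n - 2))
    return result.slope - tcrit * se, result.slope + tcrit * se


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise error threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if m < 1:
        raise ValueError(f"number of tests m={m} must be >= 1")
    return alpha / m


def univariate_screen(matrix: pd.DataFrame, weights: np.ndarray) -> pd.DataFrame:
    """Regress every analyte column on seed weight.

    ``matrix`` rows must align with ``weights``.  Constant columns are
    flagged degenerate (NaN statistics) and later excluded from the
    volcano with a logged warning; analyte order is preserved.
    """
    w = np.asarray(weights, dtype=float)
    if len(matrix) != w.size:
        raise ValueError(f"matrix has {len(matrix)} rows but {w.size} weights")
    rows = []
    for analyte in matrix.columns:
        y = matrix[analyte].to_numpy(dtype=float)
        try:
            res = fit_linear(w, y)
            rows.append((analyte, res.slope, res.intercept, res.r_squared, res.p_value, res.n, False))
        except DegenerateInputError:
            logger.warning("analyte %s is degenerate (constant); excluded from volcano", analyte)
            rows.append((analyte, np.nan, np.nan, np.nan, np.nan, w.size, True))
    return pd.DataFrame(
        rows, columns=["analyte", "slope", "intercept", "r_squared", "p_value", "n", "degenerate"]
    )


def volcano_table(
    screen: pd.DataFrame,
    loadings: pd.DataFrame,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Merge the univariate screen with multivariate predictive loadings.

    ``loadings`` must provide columns ``analyte`` and ``loading_pq1``
    covering every non-degenerate screened analyte.  The Bonferroni flag
    uses strict inequality p < alpha/m (m defaults to the number of
    tested analytes).  Rows are sorted by −log10 p, descending.
    """
    usable = screen.loc[~screen["degenerate"]]
    missing = set(usable["analyte"]) - set(loadings["analyte"])
    if missing:
        raise KeyError(f"no loading for analytes: {sorted(missing)[:10]}")
    m = m if m is not None else len(usable)
    threshold = bonferroni_threshold(alpha, m)
    merged = usable.merge(loadings[["analyte", "loading_pq1"]], on="analyte", how="left")
    merged["neg_log10_p"] = -np.log10(merged["p_value"])
    merged["passes_bonferroni"] = merged["p_value"] < threshold
    merged = merged.sort_values("neg_log10_p", ascending=False, kind="stable").reset_index(drop=True)
    return merged[["analyte", "loading_pq1", "neg_log10_p", "p_value", "passes_bonferroni"]]


# ---------------------------------------------------------------------------
# Exhaustive best-subset regression
# ---------------------------------------------------------------------------

MAX_EXHAUSTIVE_PREDICTORS = 25


@dataclass(frozen=True)
class SubsetModel:
    """One retained subset: its variables, size and R²."""

    variables: tuple[str, ...]
    size: int
    r_squared: float
    rank: int  # 1 = best within its size class


def _subset_r2(gram: np.ndarray, xy: np.ndarray, tss: float, idx: tuple[int, ...]) -> float:
    """R² of the OLS fit on the centred predictor subset ``idx``."""
    sub = np.ix_(idx, idx)
    try:
        beta = np.linalg.solve(gram[sub], xy[list(idx)])
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(gram[sub], xy[list(idx)], rcond=None)[0]
    ss_reg = float(xy[list(idx)] @ beta)
    return min(max(ss_reg / tss, 0.0), 1.0)


def best_subset(
    X: pd.DataFrame,
    y: np.ndarray,
    nvmax: int = 5,
    nbest: int = 100,
) -> tuple[list[SubsetModel], pd.DataFrame]:
    """Exhaustive best-subset regression, `regsubsets`-style.

    For every model size 1..nvmax, enumerates all predictor subsets and
    keeps the ``nbest`` with highest R².  Also returns the per-variable
    score: the maximum R² of any retained model containing that variable
    (the ordinate of the variable-importance plot).  Refuses more than
    25 candidate predictors — pre-filter first (see
    :func:`prefilter_top_univariate`).  Ties are broken by column order,
    so results are deterministic even with duplicated columns.
    """
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p > MAX_EXHAUSTIVE_PREDICTORS:
        raise ValueError(
            f"{p} candidate predictors exceed the exhaustive-search guard "
            f"({MAX_EXHAUSTIVE_PREDICTORS}); pre-filter first"
        )
    if nvmax > p:
        raise ValueError(f"nvmax={nvmax} exceeds {p} predictors")
    Xc = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise DegenerateInputError("response has zero variance")
    gram = Xc.T @ Xc
    xy = Xc.T @ yc
    cols = list(X.columns)

    retained: list[SubsetModel] = []
    best_per_var = {c: 0.0 for c in cols}
    for size in range(1, nvmax + 1):
        scored = []
        for idx in itertools.combinations(range(p), size):
            scored.append((idx, _subset_r2(gram, xy, tss, idx)))
        # stable sort: ties resolved by enumeration (column) order
        scored.sort(key=lambda t: -t[1])
        for rank, (idx, r2) in enumerate(scored[:nbest], start=1):
            names = tuple(cols[i] for i in idx)
            retained.append(SubsetModel(variables=names, size=size, r_squared=r2, rank=rank))
            for name in names:
                best_per_var[name] = max(best_per_var[name], r2)

    per_var = pd.DataFrame(
        {"variable": cols, "best_model_r2": [best_per_var[c] for c in cols]}
    )
    return retained, per_var


def prefilter_top_univariate(matrix: pd.DataFrame, weights: np.ndarray, k: int = 20) -> list[str]:
    """Top-k analytes by univariate R² on weight, for best-subset candidates."""
    screen = univariate_screen(matrix, weights)
    usable = screen.loc[~screen["degenerate"]]
    return usable.sort_values("r_squared", ascending=False, kind="stable")["analyte"].head(k).tolist()


def subsets_to_frame(models: list[SubsetModel]) -> pd.DataFrame:
    """Flatten retained subset models into an exportable table."""
    return pd.DataFrame(
        {
            "size": [m.size for m in models],
            "rank": [m.rank for m in models],
            "r_squared": [m.r_squared for m in models],
            "variables": ["+".join(m.variables) for m in models],
        }
    )
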