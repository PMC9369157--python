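"""Multivariate machinery: scaling, PCA with Hotelling screen, OPLS.

The supervised model is OPLS with a single continuous response (seed
weight): X-variation orthogonal to y is stripped by NIPALS-style
deflation, then one predictive PLS component is fitted on the filtered
matrix.  Predictive power is quantified by the cross-validated Q² and
model significance by a CV-ANOVA-style comparison of cross-validated
residuals against the mean-only model.  Hierarchical clustering on the
model scores groups seeds by weight class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage


class ModelInputError(ValueError):
    """Raised for structurally invalid model inputs."""


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingModel:
    """Column means/SDs for unit-variance scaling; constant columns dropped."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.columns) - set(X.columns)
        if missing:
            raise ModelInputError(f"columns missing from input: {sorted(missing)[:10]}")
        Z = (X[self.columns].to_numpy(dtype=float) - self.mean) / self.sd
        return pd.DataFrame(Z, columns=self.columns, index=X.index)

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            Z[self.columns].to_numpy(dtype=float) * self.sd + self.mean,
            columns=self.columns, index=Z.index,
        )


def uv_scale(X: pd.DataFrame) -> tuple[pd.DataFrame, ScalingModel]:
    """Center each column and scale to unit variance (ddof=1).

    Constant columns carry no information for projection models and are
    dropped with a warning.
    """
    if len(X) < 2:
        raise ModelInputError("need at least 2 rows to scale")
    mean = X.to_numpy(dtype=float).mean(axis=0)
    sd = X.to_numpy(dtype=float).std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant column(s): {dropped[:5]}...", stacklevel=2)
    model = ScalingModel(
        columns=[c for c, k in zip(X.columns, keep) if k],
        mean=mean[keep], sd=sd[keep], dropped=dropped,
    )
    return model.transform(X), model


# ---------------------------------------------------------------------------
# PCA with Hotelling T² screen
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Principal components by SVD of the (pre-scaled) data matrix."""

    n_components: int
    scores: np.ndarray            # n x k
    loadings: np.ndarray          # p x k, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_fit(X: pd.DataFrame | np.ndarray, k: int) -> PcaModel:
    """Fit a k-component PCA by singular value decomposition."""
    A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    n, p = A.shape
    if not 1 <= k <= min(n - 1, p):
        raise ModelInputError(f"k={k} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    mean = A.mean(axis=0)
    Ac = A - mean
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    scores = U[:, :k] * s[:k]
    ev = s**2 / (n - 1)
    return PcaModel(
        n_components=k,
        scores=scores,
        loadings=Vt[:k].T,
        explained_variance=ev[:k],
        explained_variance_ratio=ev[:k] / ev.sum(),
        mean=mean,
    )


def hotelling_t2(model: PcaModel) -> np.ndarray:
    """Hotelling T² of each training sample in the score space."""
    lam = model.scores.var(axis=0, ddof=1)
    return (model.scores**2 / lam).sum(axis=1)


def hotelling_outliers(model: PcaModel, level: float = 0.99) -> np.ndarray:
    """Boolean flags for samples outside the Hotelling confidence region.

    Uses the conventional F-distribution critical value
    T²_crit = k (n² − 1) / (n (n − k)) · F_level(k, n − k).
    """
    if not 0 < level < 1:
        raise ModelInputError(f"level={level} outside (0, 1)")
    n = model.scores.shape[0]
    k = model.n_components
    crit = k * (n**2 - 1) / (n * (n - k)) * sps.f.ppf(level, k, n - k)
    return hotelling_t2(model) > crit


# ---------------------------------------------------------------------------
# OPLS with a single continuous response
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted OPLS-1 model: one predictive + n_ortho orthogonal components.

    ``loading_pred`` is the predictive X-loading per analyte (the pq1
    loading exported to the volcano plot); ``y_loading`` is the scalar
    q.  Cross-validation attributes are populated when the model is fit
    with ``cross_validate=True``.
    """

    columns: list[str]
    x_mean: np.ndarray
    y_mean: float
    weights_pred: np.ndarray      # w, unit norm
    loading_pred: np.ndarray      # p (pq1)
    y_loading: float              # q
    scores_pred: np.ndarray       # t
    ortho_weights: np.ndarray     # p_x x n_ortho
    ortho_loadings: np.ndarray
    ortho_scores: np.ndarray
    r_squared: float              # R2Y on training data
    q_squared: float | None = None
    p_cv_anova: float | None = None
    folds: int | None = None
    cv_predictions: np.ndarray | None = None
    # training data kept for CV-ANOVA randomization and diagnostics
    X_train: np.ndarray | None = None
    y_train: np.ndarray | None = None
    cv_seed: int | None = None

    @property
    def n_ortho(self) -> int:
        return self.ortho_scores.shape[1]

    def loadings_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"analyte": self.columns, "loading_pq1": self.loading_pred})
        for j in range(self.n_ortho):
            out[f"loading_ortho{j + 1}"] = self.ortho_loadings[:, j]
        return out


def _opls_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
    """NIPALS-style OPLS-1 on centred data.

    Removes ``n_ortho`` y-orthogonal components, then fits one
    predictive PLS component on the filtered matrix.  Deterministic: for
    a single y, each component is a closed-form projection (no power
    iteration is needed).
    """
    norm_xty = np.linalg.norm(Xc.T @ yc)
    if norm_xty == 0:
        raise ModelInputError("X carries no covariance with y; OPLS undefined")
    w = (Xc.T @ yc) / norm_xty
    Xf = Xc.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no y-orthogonal variation left
        w_o /= n_wo
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o); T_o.append(t_o); P_o.append(p_o)
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    p_x = Xc.shape[1]
    stack = lambda L: np.column_stack(L) if L else np.zeros((p_x, 0))
    T_stack = np.column_stack(T_o) if T_o else np.zeros((Xc.shape[0], 0))
    return w, p, q, t, stack(W_o), T_stack, stack(P_o)


def _opls_predict_centred(Xc: np.ndarray, w, q, W_o, P_o) -> np.ndarray:
    Xf = Xc.copy()
    for j in range(W_o.shape[1]):
        t_o = Xf @ W_o[:, j]
        Xf = Xf - np.outer(t_o, P_o[:, j])
    return (Xf @ w) * q


def opls_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    n_ortho: int = 1,
    cross_validate: bool = True,
    folds: int = 7,
    cv_seed: int = 0,
) -> OplsModel:
    """Fit an OPLS-1 model of a continuous response on (scaled) X.

    ``X`` is expected unit-variance scaled (see :func:`uv_scale`); X and
    y are centred internally.  With ``cross_validate=True`` the model
    also carries Q², deterministic-fold CV predictions and the CV-ANOVA
    p-value (F method).
    """
    if n_ortho < 0:
        raise ModelInputError("n_ortho must be >= 0")
    A = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(A) != y.size:
        raise ModelInputError(f"X has {len(A)} rows but y has {y.size}")
    x_mean = A.mean(axis=0)
    y_mean = float(y.mean())
    Xc, yc = A - x_mean, y - y_mean
    w, p, q, t, W_o, T_o, P_o = _opls_core(Xc, yc, n_ortho)
    fitted = t * q
    tss = float(yc @ yc)
    r2 = 1.0 - float((yc - fitted) @ (yc - fitted)) / tss if tss > 0 else 0.0
    model = OplsModel(
        columns=list(X.columns), x_mean=x_mean, y_mean=y_mean,
        weights_pred=w, loading_pred=p, y_loading=q, scores_pred=t,
        ortho_weights=W_o, ortho_scores=T_o, ortho_loadings=P_o,
        r_squared=max(r2, 0.0), X_train=A, y_train=y, cv_seed=cv_seed,
    )
    if cross_validate:
        press, cv_pred = _cv_press(A, y, folds=folds, n_ortho=n_ortho, seed=cv_seed)
        model.q_squared = 1.0 - press / tss
        model.cv_predictions = cv_pred
        model.folds = folds
        model.p_cv_anova = cv_anova(model)
    return model


def opls_predict(model: OplsModel, X_new: pd.DataFrame) -> np.ndarray:
    """Predict the response for new samples on the original y scale."""
    missing = set(model.columns) - set(X_new.columns)
    if missing:
        raise ModelInputError(f"prediction input missing columns: {sorted(missing)[:10]}")
    A = X_new[model.columns].to_numpy(dtype=float)
    return _opls_predict_centred(A - model.x_mean, model.weights_pred,
                                 model.y_loading, model.ortho_weights,
                                 model.ortho_loadings) + model.y_mean


# ---------------------------------------------------------------------------
# Cross-validation, Q² and CV-ANOVA
# ---------------------------------------------------------------------------

def _fold_bounds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic fold assignment: seeded permutation, contiguous blocks."""
    if folds < 2:
        raise ModelInputError("need >= 2 folds")
    if n < 2 * folds:
        raise ModelInputError(f"{n} samples leave a fold with < 2 samples at {folds} folds")
    idx = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(idx, folds)]


def _cv_press(X: np.ndarray, y: np.ndarray, folds: int, n_ortho: int, seed: int,
              fold_sets: list[np.ndarray] | None = None) -> tuple[float, np.ndarray]:
    n = len(y)
    fold_sets = fold_sets or _fold_bounds(n, folds, seed)
    pred = np.empty(n)
    for test in fold_sets:
        train = np.setdiff1d(np.arange(n), test)
        xm = X[train].mean(axis=0)
        ym = y[train].mean()
        w, p, q, t, W_o, T_o, P_o = _opls_core(X[train] - xm, y[train] - ym, n_ortho)
        pred[test] = _opls_predict_centred(X[test] - xm, w, q, W_o, P_o) + ym
    press = float(np.sum((y - pred) ** 2))
    return press, pred


def q2_cross_validation(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    folds: int = 7,
    n_ortho: int = 1,
    seed: int = 0,
) -> float:
    """Cross-validated Q² = 1 − PRESS/TSS with deterministic folds.

    TSS is the total sum of squares of y about its overall mean
    (total-PRESS definition).
    """
    A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    press, _ = _cv_press(A, y, folds=folds, n_ortho=n_ortho, seed=seed)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def cv_anova(model: OplsModel, method: str = "f", n_rand: int = 199) -> float:
    """Significance of the cross-validated model against the mean-only null.

    ``method='f'`` (default) follows the published CV-ANOVA recipe: the
    total sum of squares of y is split into (TSS − PRESS) explained by
    cross-validated prediction and PRESS left over, compared by an F
    ratio with component-count/residual-count degrees of freedom.  This
    test is conservative when the model has no real predictive power
    (PRESS then typically exceeds TSS, giving p = 1).

    ``method='randomization'`` instead compares the observed PRESS with
    the PRESS of models refit (same fold structure) on random
    mean-plus-noise responses obtained by permuting y — an exactly
    calibrated Monte-Carlo version of the same comparison, uniform under
    the null but with resolution limited to 1/(n_rand + 1).
    """
    if model.cv_predictions is None:
        raise ModelInputError("model was fit without cross-validation")
    y = model.y_train
    press = float(np.sum((y - model.cv_predictions) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        warnings.warn("degenerate response: zero variance; p set to 1", stacklevel=2)
        return 1.0
    if method == "f":
        k = 1 + model.n_ortho
        n = len(y)
        df2 = n - 1 - k
        if df2 <= 0:
            warnings.warn("too few residual degrees of freedom; p set to 1", stacklevel=2)
            return 1.0
        if press == 0:
            return float(np.finfo(float).tiny)
        f_stat = ((tss - press) / k) / (press / df2)
        if f_stat <= 0:
            return 1.0
        return float(sps.f.sf(f_stat, k, df2))
    if method == "randomization":
        rng = np.random.default_rng(model.cv_seed)
        fold_sets = _fold_bounds(len(y), model.folds, model.cv_seed)
        hits = 0
        for _ in range(n_rand):
            y_rand = rng.permutation(y)
            press_b, _ = _cv_press(model.X_train, y_rand, folds=model.folds,
                                   n_ortho=model.n_ortho, seed=model.cv_seed,
                                   fold_sets=fold_sets)
            if press_b <= press:
                hits += 1
        return (1 + hits) / (n_rand + 1)
    raise ValueError(f"unknown cv_anova method {method!r}")


# ---------------------------------------------------------------------------
# Clustering on model scores
# ---------------------------------------------------------------------------

def cluster_scores(scores: np.ndarray, k: int | None = None,
                   distance_threshold: float | None = None) -> np.ndarray:
    """Agglomerative (Ward, Euclidean) clustering of sample scores.

    Provide either ``k`` clusters or a cophenetic ``distance_threshold``.
    Deterministic labels starting at 1.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if len(S) < 2:
        raise ModelInputError("need >= 2 samples to cluster")
    Z = linkage(S, method="ward")
    if k is not None:
        return fcluster(Z, t=k, criterion="maxclust")
    if distance_threshold is not None:
        return fcluster(Z, t=distance_threshold, criterion="distance")
    raise ValueError("provide k or distance_threshold")
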