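"""Orthogonal partial least squares regression (O-PLS) for a single outcome.

O-PLS splits predictor variation into one component predictive of y and
``n_ortho`` components orthogonal to y (structured noise), yielding more
interpretable single-component models than plain PLS when predictors carry
strong y-unrelated variation.  Fitting follows the classical NIPALS-style
orthogonal filtering for a single y:

1. center X and y; scale to unit variance (or Pareto, √SD).
2. w ∝ Xᵀy (normalized y-predictive weight direction).
3. for each orthogonal component: p = Xᵀt/(tᵀt) for the current predictive
   scores t = Xw; the orthogonal weight is p minus its projection on w,
   normalized; its scores/loadings deflate X.
4. the single predictive component (w, t, p, q) is fit on the filtered X.

Model quality: R²X (explained X-variance of all components), R²Y (explained
y-variance), and Q²Y = 1 − PRESS/TSS from seeded, y-stratified 7-fold
cross-validation with *all* preprocessing re-estimated inside each training
fold.  Significance is assessed by permuting y, refitting and re-cross-
validating, with the add-one p-value (1 + #{null ≥ observed})/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OPLSRModel", "PermutationResult", "fit_oplsr", "predict",
           "cross_validate", "permutation_test"]


@dataclass
class OPLSRModel:
    predictive_weights: np.ndarray      # w  (p,)
    predictive_loadings: np.ndarray     # p  (p,)
    predictive_scores: np.ndarray       # t  (n,)
    ortho_weights: np.ndarray           # (n_ortho, p)
    ortho_loadings: np.ndarray          # (n_ortho, p)
    ortho_scores: np.ndarray            # (n_ortho, n)
    y_loading: float                    # q
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    n_ortho: int
    r2x: float
    r2y: float
    columns: list[str] | None = None
    scaling: str = "uv"
    q2y: float | None = None


@dataclass
class PermutationResult:
    observed_q2y: float
    observed_r2y: float
    null_q2y: list[float] = field(default_factory=list)
    null_r2y: list[float] = field(default_factory=list)
    n_perm: int = 0
    p_q2y: float = 1.0


def _prepare(X, y, scaling: str):
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance predictor column(s) at index {bad}")
    if scaling == "uv":
        x_scale = sd
    elif scaling == "pareto":
        x_scale = np.sqrt(sd)
    else:
        raise ValueError("scaling must be 'uv' or 'pareto'")
    y_mean = y.mean()
    y_scale = y.std(ddof=1)
    if y_scale == 0:
        raise ValueError("outcome has zero variance")
    return ((X - x_mean) / x_scale, (y - y_mean) / y_scale,
            x_mean, x_scale, y_mean, y_scale)


def fit_oplsr(X, y, n_ortho: int = 1, columns=None,
              scaling: str = "uv") -> OPLSRModel:
    """Fit 1 predictive + ``n_ortho`` orthogonal components.

    Stores every artifact needed for out-of-sample prediction.  Raises on
    zero-variance columns and on n_ortho ≥ rank(X).
    """
    Xs, ys, x_mean, x_scale, y_mean, y_scale = _prepare(X, y, scaling)
    n, p = Xs.shape
    if n < 10:
        raise ValueError("need at least 10 samples")
    if p < 2:
        raise ValueError("need at least 2 predictor columns")
    rank = np.linalg.matrix_rank(Xs)
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} must be < rank(X)={rank}")

    ss_x_total = (Xs ** 2).sum()
    Xd = Xs.copy()
    w = Xd.T @ ys
    w /= np.linalg.norm(w)

    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            raise ValueError("orthogonal weight collapsed: X carries no "
                             "y-orthogonal structured variation to remove")
        w_o /= nrm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    # predictive component on the filtered X
    w = Xd.T @ ys
    w /= np.linalg.norm(w)
    t = Xd @ w
    p_load = Xd.T @ t / (t @ t)
    q = float(ys @ t / (t @ t))

    X_resid = Xd - np.outer(t, p_load)
    r2x = float(1.0 - (X_resid ** 2).sum() / ss_x_total)
    y_hat = q * t
    r2y = float(1.0 - ((ys - y_hat) ** 2).sum() / (ys ** 2).sum())

    return OPLSRModel(
        predictive_weights=w, predictive_loadings=p_load, predictive_scores=t,
        ortho_weights=np.array(W_o).reshape(n_ortho, -1) if W_o else np.empty((0, p)),
        ortho_loadings=np.array(P_o).reshape(n_ortho, -1) if P_o else np.empty((0, p)),
        ortho_scores=np.array(T_o).reshape(n_ortho, -1) if T_o else np.empty((0, n)),
        y_loading=q, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        y_scale=y_scale, n_ortho=n_ortho, r2x=r2x, r2y=r2y,
        columns=list(columns) if columns is not None else None, scaling=scaling)


def predict(model: OPLSRModel, X_new) -> np.ndarray:
    """Filter orthogonal variation from new rows, project, back-transform."""
    X_new = np.asarray(X_new, float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != len(model.x_mean):
        raise ValueError(f"column mismatch: model has {len(model.x_mean)} "
                         f"predictors, input has {X_new.shape[1]}")
    Xs = (X_new - model.x_mean) / model.x_scale
    for w_o, p_o in zip(model.ortho_weights, model.ortho_loadings):
        t_o = Xs @ w_o
        Xs = Xs - np.outer(t_o, p_o)
    t = Xs @ model.predictive_weights
    return model.y_mean + model.y_scale * model.y_loading * t


def _stratified_folds(y, folds: int, rng) -> np.ndarray:
    """Fold labels stratified on y quantiles (balanced outcome per fold)."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    fold = np.empty(n, int)
    for block_start in range(0, n, folds):
        block = order[block_start:block_start + folds]
        fold[block] = rng.permutation(folds)[:len(block)]
    return fold


def cross_validate(X, y, n_ortho: int = 1, folds: int = 7,
                   seed: int | None = 0, scaling: str = "uv") -> float:
    """Q²Y = 1 − PRESS/TSS with per-fold refit (no preprocessing leakage)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if len(y) < folds:
        raise ValueError("need n >= folds")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, folds, rng)
    press = 0.0
    for k in range(folds):
        test = fold == k
        if (~test).sum() < 2 or test.sum() < 1:
            raise ValueError(f"fold {k} too small")
        model = fit_oplsr(X[~test], y[~test], n_ortho=n_ortho, scaling=scaling)
        press += float(((y[test] - predict(model, X[test])) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_test(X, y, n_ortho: int = 1, n_perm: int = 999,
                     seed: int | None = 0, folds: int = 7,
                     scaling: str = "uv") -> PermutationResult:
    """Permutation null for Q²Y/R²Y: shuffle y, refit + re-cross-validate."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    obs_model = fit_oplsr(X, y, n_ortho=n_ortho, scaling=scaling)
    obs_q2 = cross_validate(X, y, n_ortho=n_ortho, folds=folds,
                            seed=rng.integers(2**31), scaling=scaling)
    null_q2, null_r2 = [], []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        m = fit_oplsr(X, y_perm, n_ortho=n_ortho, scaling=scaling)
        q2 = cross_validate(X, y_perm, n_ortho=n_ortho, folds=folds,
                            seed=rng.integers(2**31), scaling=scaling)
        null_q2.append(q2)
        null_r2.append(m.r2y)
    p = (1 + sum(q >= obs_q2 for q in null_q2)) / (n_perm + 1)
    return PermutationResult(observed_q2y=obs_q2, observed_r2y=obs_model.r2y,
                             null_q2y=null_q2, null_r2y=null_r2,
                             n_perm=n_perm, p_q2y=p)
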