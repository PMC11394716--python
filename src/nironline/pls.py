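"""Partial least squares regression for a single response.

Two routes to the same regression vector are provided: classical NIPALS on
the (auto-scaled) data matrix, and a kernel-style extraction that needs only
the cross-products XᵀX and Xᵀy.  The second form is what the recursive
online model updates, so their agreement is the core correctness check of
the whole stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel",
    "pls_fit",
    "pls_predict",
    "pls_from_crossproducts",
    "select_n_lv",
    "kfold_indices",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted PLS regression model.

    ``coefficients`` act on the standardized scale: a prediction is
    y_mean + y_std * ((x - x_mean)/x_std) @ coefficients.  ``feature_indices``
    records which columns of the full wavelength grid the model consumes
    (None means the model was fit on an already-sliced matrix).
    """

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    coefficients: np.ndarray
    n_lv: int
    feature_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.x_std = np.asarray(self.x_std, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(self.x_std <= 0):
            raise ValueError("x_std entries must be positive")
        if self.n_lv < 1:
            raise ValueError("n_lv must be at least 1")
        if self.feature_indices is not None:
            self.feature_indices = np.asarray(self.feature_indices, dtype=int)


def _autoscale(X: np.ndarray, y: np.ndarray, scale: bool):
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        x_std = X.std(axis=0, ddof=1)
        y_std = float(y.std(ddof=1))
        zero = np.flatnonzero(X.max(axis=0) == X.min(axis=0))
        if zero.size:
            raise ValueError(f"zero-variance feature at column(s) {zero.tolist()}")
        if np.all(y == y[0]):
            raise ValueError("response has zero variance")
    else:
        x_std = np.ones(X.shape[1])
        y_std = 1.0
    Xs = (X - x_mean) / x_std
    ys = (y - y_mean) / y_std
    return Xs, ys, x_mean, x_std, y_mean, y_std


def _nipals(Xs: np.ndarray, ys: np.ndarray, n_lv: int):
    """NIPALS component extraction on centered/scaled data.

    Returns (coefficients, scores) on the standardized scale.  Extraction
    stops early if the residual X weight vanishes (rank exhausted).
    """
    n, p = Xs.shape
    X = Xs.copy()
    y = ys.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    a = 0
    for _ in range(n_lv):
        u = y
        w = np.zeros(p)
        t = np.zeros(n)
        # with a single response the u-loop converges after one pass; the
        # loop is kept in its general form with an explicit tolerance
        for _ in range(_NIPALS_MAX_ITER):
            w_new = X.T @ u
            norm = np.linalg.norm(w_new)
            if norm < _NIPALS_TOL:
                break
            w_new = w_new / norm
            t_new = X @ w_new
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(1.0, np.linalg.norm(t_new)):
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
        tt = float(t @ t)
        if tt == 0.0 or np.linalg.norm(w) == 0.0:
            break
        p_load = X.T @ t / tt
        q_load = float(y @ t / tt)
        X = X - np.outer(t, p_load)
        y = y - q_load * t
        W[:, a] = w
        P[:, a] = p_load
        q[a] = q_load
        T[:, a] = t
        a += 1
    if a == 0:
        return np.zeros(p), T[:, :0]
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, T


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scale: bool = True,
    feature_indices: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS regression of y on X with ``n_lv`` latent variables.

    X and y are centered and (by default) scaled to unit variance before
    NIPALS extraction.  ``scale=False`` switches to mean-centering only,
    needed when deliberately tiny columns (the UVE noise block) must stay
    tiny.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    if n_lv > min(n - 1, p):
        raise ValueError(
            f"n_lv={n_lv} exceeds min(samples-1, features)={min(n - 1, p)}"
        )
    Xs, ys, x_mean, x_std, y_mean, y_std = _autoscale(X, y, scale)
    coef, _ = _nipals(Xs, ys, n_lv)
    return PLSModel(
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        coefficients=coef, n_lv=n_lv, feature_indices=feature_indices,
    )


def pls_scores(X: np.ndarray, y: np.ndarray, n_lv: int, scale: bool = True) -> np.ndarray:
    """Score matrix T of the NIPALS extraction (for orthogonality checks)."""
    Xs, ys, *_ = _autoscale(np.asarray(X, float), np.asarray(y, float).ravel(), scale)
    _, T = _nipals(Xs, ys, n_lv)
    return T


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict the response for new rows on the model's feature columns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coefficients.size:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.coefficients.size}"
        )
    Xs = (X - model.x_mean) / model.x_std
    return model.y_mean + model.y_std * (Xs @ model.coefficients)


def pls_from_crossproducts(XtX: np.ndarray, Xty: np.ndarray, n_lv: int,
                           sym_tol: float = 1e-8) -> np.ndarray:
    """Standardized-scale PLS coefficients from XᵀX and Xᵀy alone.

    Kernel-style extraction (no data matrix needed): for each component the
    weight is the current deflated Xᵀy direction, loadings come from XᵀX,
    and only Xᵀy is deflated.  For cross-products of an autoscaled matrix
    this reproduces the NIPALS coefficients.
    """
    XtX = np.asarray(XtX, dtype=float)
    Xty = np.asarray(Xty, dtype=float).ravel()
    p = Xty.size
    if XtX.shape != (p, p):
        raise ValueError("XtX and Xty dimensions are inconsistent")
    scale = max(1.0, float(np.max(np.abs(XtX))))
    if np.max(np.abs(XtX - XtX.T)) > sym_tol * scale:
        raise ValueError("XtX is not symmetric within tolerance")

    s = Xty.copy()
    R = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    P = np.zeros((p, n_lv))
    a = 0
    for _ in range(n_lv):
        norm = np.linalg.norm(s)
        if norm < _NIPALS_TOL:
            break
        w = s / norm
        r = w.copy()
        for j in range(a):
            r -= float(P[:, j] @ w) * R[:, j]
        tt = float(r @ XtX @ r)
        if tt <= 0.0:
            break
        p_load = XtX @ r / tt
        q_load = float(r @ s) / tt
        s = s - p_load * (q_load * tt)
        R[:, a] = r
        P[:, a] = p_load
        q[a] = q_load
        a += 1
    if a == 0:
        return np.zeros(p)
    return R[:, :a] @ q[:a]


def kfold_indices(n: int, folds: int, seed: int | None = None) -> list[np.ndarray]:
    """Shuffled, near-equal k-fold partition of range(n).

    ``seed=None`` gives the unshuffled contiguous partition (useful when a
    test must pin the fold assignment).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError("more folds than samples")
    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)
    return [fold for fold in np.array_split(order, folds)]


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: int = 10,
    seed: int | None = 0,
    scale: bool = True,
    rel_tol: float = 0.02,
) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by k-fold RMSECV.

    Returns (best n_lv, RMSECV curve over 1..max_lv).  Ties go to the
    smaller count: the smallest n_lv whose RMSECV is within ``rel_tol``
    (relative) of the curve minimum is selected, so extra components that
    buy no practical accuracy are not kept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    fold_list = kfold_indices(n, folds, seed)
    max_train = min(len(np.setdiff1d(np.arange(n), f)) - 1 for f in fold_list)
    if max_lv > min(max_train, p):
        raise ValueError(
            f"max_lv={max_lv} infeasible for {n} samples / {p} features "
            f"with {folds} folds"
        )
    sq_err = np.zeros(max_lv)
    for test_idx in fold_list:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        for lv in range(1, max_lv + 1):
            model = pls_fit(X[train_idx], y[train_idx], lv, scale=scale)
            resid = y[test_idx] - pls_predict(model, X[test_idx])
            sq_err[lv - 1] += float(resid @ resid)
    curve = np.sqrt(sq_err / n)
    # near-zero floor keeps the tie rule meaningful when RMSECV is ~0
    threshold = curve.min() * (1.0 + rel_tol) + 1e-8 * float(np.std(y))
    best = int(np.argmax(curve <= threshold)) + 1
    return best, curve
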