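"""Wavelength selection by uninformative-variable elimination (UVE).

UVE appends a block of deliberately tiny random-noise columns to the
spectral matrix, fits a PLS model on every cross-validation fold, and scores
each column by the stability statistic C = mean(b)/std(b) of its regression
coefficient across folds.  Real wavelengths whose |C| cannot beat the noise
columns carry no usable information.  Here selection is by a fixed top-k on
|C| (k=70 offline, expanded to k=100 online); the classic max|C_noise|
cutoff is still computable from the returned noise stabilities.

The online model additionally monitors which selected bands dominate the
current cross-product matrix: its eigendecomposition XᵀX = ΓᵀΛΓ ranks bands
by eigenvalue-weighted squared loadings on the leading eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .pls import kfold_indices, pls_fit

__all__ = [
    "UVEResult",
    "FeatureMonitorReport",
    "uve_stability",
    "uve_select",
    "monitor_top_features",
    "DEFAULT_K_OFFLINE",
    "DEFAULT_K_ONLINE",
    "DEFAULT_MONITOR_M",
]

DEFAULT_K_OFFLINE = 70
DEFAULT_K_ONLINE = 100
DEFAULT_MONITOR_M = 30

#: Classic UVE convention: noise columns are ~1e-10 of the signal magnitude,
#: so with mean-centred (unscaled) PLS they cannot perturb the fit.
DEFAULT_NOISE_FACTOR = 1e-10


@dataclass
class UVEResult:
    """Stability statistics and (optionally) a top-k selection."""

    stability: np.ndarray
    noise_stability: np.ndarray
    selected: np.ndarray | None = None
    k: int | None = None

    @property
    def noise_cutoff(self) -> float:
        """The classic UVE threshold max|C_noise| (diagnostic)."""
        return float(np.max(np.abs(self.noise_stability)))


@dataclass
class FeatureMonitorReport:
    """Leading eigenvalues of XᵀX and the bands that carry them."""

    eigenvalues: np.ndarray
    flagged_bands: np.ndarray
    band_scores: np.ndarray


def uve_stability(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    noise_scale: float | None = None,
    folds: int | None = None,
    seed: int = 0,
    fold_assignment: list | None = None,
) -> UVEResult:
    """Per-wavelength stability C = mean(b)/std(b) across CV folds.

    A uniform-random noise block with as many columns as X (scaled to
    ``noise_scale``, default 1e-10 × mean|X|) is appended, a mean-centred
    PLS model is fit on each training fold of a k-fold split (default
    leave-one-out), and the per-fold coefficient vectors are stacked into B.
    Returns real-variable and noise-variable stabilities separately;
    deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    if noise_scale is None:
        noise_scale = DEFAULT_NOISE_FACTOR * float(np.mean(np.abs(X)))
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")

    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, 1.0, size=(n, p)) * noise_scale
    Xa = np.hstack([X, noise])

    if fold_assignment is None:
        if folds is None:
            folds = n  # leave-one-out
        if folds > n:
            raise ValueError("more folds than samples")
        fold_assignment = kfold_indices(n, folds, seed=None)

    B = []
    for test_idx in fold_assignment:
        train_idx = np.setdiff1d(np.arange(n), np.asarray(test_idx))
        model = pls_fit(Xa[train_idx], y[train_idx], n_lv, scale=False)
        B.append(model.coefficients)
    B = np.asarray(B)

    mean_b = B.mean(axis=0)
    std_b = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = mean_b / std_b
    degenerate = std_b == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} column(s) had zero coefficient spread "
            "across folds; stability set to signed infinity",
            RuntimeWarning,
        )
        C[degenerate] = np.sign(mean_b[degenerate]) * np.inf
        C[degenerate & (mean_b == 0)] = 0.0
    return UVEResult(stability=C[:p], noise_stability=C[p:])


def uve_select(result: UVEResult, k: int) -> UVEResult:
    """Top-k real wavelengths by |C|, ties broken toward the lower index."""
    p = result.stability.size
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range [1, {p}]")
    # stable sort on -|C| keeps original (ascending-index) order within ties
    order = np.argsort(-np.abs(result.stability), kind="stable")
    selected = np.sort(order[:k])
    return replace(result, selected=selected, k=k)


def monitor_top_features(
    XtX: np.ndarray,
    m: int = DEFAULT_MONITOR_M,
    sym_tol: float = 1e-8,
) -> FeatureMonitorReport:
    """Rank current bands by weight on the leading eigenvectors of XᵀX.

    The symmetric eigendecomposition XᵀX = ΓᵀΛΓ is taken, eigenvalues
    sorted descending, and each band i scored by Σ_{j≤m} λ_j Γ_{ij}².  The
    m top-scoring bands are flagged (ties toward the lower index).
    """
    XtX = np.asarray(XtX, dtype=float)
    p = XtX.shape[0]
    if XtX.shape != (p, p):
        raise ValueError("cross-product matrix must be square")
    scale = max(1.0, float(np.max(np.abs(XtX))))
    if np.max(np.abs(XtX - XtX.T)) > sym_tol * scale:
        raise ValueError("cross-product matrix is not symmetric within tolerance")
    if not 1 <= m <= p:
        raise ValueError(f"m={m} out of range [1, {p}]")
    evals, evecs = np.linalg.eigh((XtX + XtX.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scores = (evecs[:, :m] ** 2) @ evals[:m]
    ranked = np.argsort(-scores, kind="stable")
    return FeatureMonitorReport(
        eigenvalues=evals[:m],
        flagged_bands=ranked[:m],
        band_scores=scores,
    )
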