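"""Recursive PLS: cross-product updates with a forgetting factor.

The online model never revisits raw calibration data.  It carries the
cross-products XᵀX(t), Xᵀy(t) of standardized feature data together with
running moments (mean and standard deviation of x and y) and a sample
count N.  Each incoming sample updates the moments recursively, is
standardized with the *updated* moments, and is folded into the
cross-products discounted by the forgetting factor λ:

    XᵀX(t) = λ·XᵀX(t-1) + x̂(t)ᵀx̂(t)
    Xᵀy(t) = λ·Xᵀy(t-1) + x̂(t)ᵀŷ(t)

Regression coefficients are re-extracted from the cross-products on demand
(kernel PLS), so an update costs O(p²) and a refresh O(p²·n_lv).

Two printed-form subtleties are preserved deliberately: the variance
recursion uses the squared deviation from the *previous* mean (an
``exact_variance`` flag switches to the exact Welford product form), and
history is not re-standardized when the moments move.  A ``freeze_moments``
test mode pins the moments so the recursion can be checked exactly against
batch cross-products.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import DEFAULT_MONITOR_M, FeatureMonitorReport, monitor_top_features
from .metrics import r2 as _r2
from .metrics import rmse as _rmse
from .pls import PLSModel, pls_from_crossproducts, pls_predict
from .preprocess import (
    OnlineScatterCorrector,
    ReferenceSpectrum,
    SpectraSet,
    msc_correct,
    sg_smooth,
)

__all__ = [
    "RPLSState",
    "SessionRecord",
    "SessionReport",
    "rpls_init",
    "rpls_update",
    "rpls_coefficients",
    "run_online_session",
]


@dataclass
class RPLSState:
    """All state the online model needs; no raw spectra retained."""

    XtX: np.ndarray
    Xty: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    N: int
    lam: float
    n_lv: int
    feature_indices: np.ndarray | None = None
    exact_variance: bool = False
    freeze_moments: bool = False
    update_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("forgetting factor must lie in (0, 1]")
        if np.any(self.x_std <= 0) or self.y_std <= 0:
            raise ValueError("standard deviations must be positive")


def rpls_init(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    n_lv: int,
    lam: float = 1.0,
    feature_indices: np.ndarray | None = None,
    exact_variance: bool = False,
) -> RPLSState:
    """Initial state from the (already feature-selected) calibration data.

    Moments are the calibration sample mean/std (ddof=1) and XᵀX(0), Xᵀy(0)
    are the cross-products of the autoscaled calibration matrix, so the
    zero-update coefficients reproduce the offline PLS model.
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    if X.size == 0 or y.size == 0:
        raise ValueError("calibration data must be nonempty")
    if X.shape[0] != y.size:
        raise ValueError("X_cal and y_cal disagree on sample count")
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(X.max(axis=0) == X.min(axis=0))
    if zero.size:
        raise ValueError(f"zero-variance feature at column(s) {zero.tolist()}")
    y_mean = float(y.mean())
    y_std = float(y.std(ddof=1))
    if np.all(y == y[0]):
        raise ValueError("calibration response has zero variance")
    Xs = (X - x_mean) / x_std
    ys = (y - y_mean) / y_std
    return RPLSState(
        XtX=Xs.T @ Xs,
        Xty=Xs.T @ ys,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        N=X.shape[0],
        lam=lam,
        n_lv=n_lv,
        feature_indices=(None if feature_indices is None
                         else np.asarray(feature_indices, dtype=int)),
        exact_variance=exact_variance,
    )


def rpls_update(state: RPLSState, x_t: np.ndarray, y_t: float) -> RPLSState:
    """Fold one standardized sample into the state; returns a new state."""
    x_t = np.asarray(x_t, dtype=float).ravel()
    if x_t.size != state.Xty.size:
        raise ValueError("x_t length does not match the feature subset")
    if not (np.all(np.isfinite(x_t)) and np.isfinite(y_t)):
        raise ValueError("non-finite input sample")
    y_t = float(y_t)
    N = state.N + 1

    if state.freeze_moments:
        x_mean, x_std = state.x_mean, state.x_std
        y_mean, y_std = state.y_mean, state.y_std
    else:
        x_mean = (N - 1) / N * state.x_mean + x_t / N
        y_mean = (N - 1) / N * state.y_mean + y_t / N
        if state.exact_variance:
            # Welford product form: exact running sample variance
            x_var = ((N - 2) * state.x_std**2
                     + (x_t - state.x_mean) * (x_t - x_mean)) / (N - 1)
            y_var = ((N - 2) * state.y_std**2
                     + (y_t - state.y_mean) * (y_t - y_mean)) / (N - 1)
        else:
            # printed recursion: squared deviation from the previous mean
            x_var = ((N - 2) * state.x_std**2
                     + (x_t - state.x_mean) ** 2) / (N - 1)
            y_var = ((N - 2) * state.y_std**2
                     + (y_t - state.y_mean) ** 2) / (N - 1)
        x_std = np.sqrt(x_var)
        y_std = float(np.sqrt(y_var))
        if np.any(x_std == 0):
            raise ValueError("a feature's running standard deviation hit zero")
        if y_std == 0:
            raise ValueError("the response's running standard deviation hit zero")

    x_hat = (x_t - x_mean) / x_std
    y_hat = (y_t - y_mean) / y_std
    XtX = state.lam * state.XtX + np.outer(x_hat, x_hat)
    Xty = state.lam * state.Xty + x_hat * y_hat

    new_state = replace(
        state,
        XtX=XtX, Xty=Xty,
        x_mean=np.asarray(x_mean, float), x_std=np.asarray(x_std, float),
        y_mean=float(y_mean), y_std=float(y_std),
        N=N,
        update_log=state.update_log + [{"N": N, "lam": state.lam}],
    )
    return new_state


def rpls_coefficients(state: RPLSState) -> PLSModel:
    """Predict-ready PLS model extracted from the current cross-products."""
    coef = pls_from_crossproducts(state.XtX, state.Xty, state.n_lv)
    return PLSModel(
        x_mean=state.x_mean.copy(),
        x_std=state.x_std.copy(),
        y_mean=state.y_mean,
        y_std=state.y_std,
        coefficients=coef,
        n_lv=state.n_lv,
        feature_indices=state.feature_indices,
    )


@dataclass
class SessionRecord:
    iteration: int
    n_processed: int
    rmsep: float
    r2: float
    r2_paper: float
    flagged_bands: np.ndarray


@dataclass
class SessionReport:
    records: list[SessionRecord]
    final_model: PLSModel
    reference: ReferenceSpectrum
    monitor_reports: list[FeatureMonitorReport]

    @property
    def rmsep_curve(self) -> np.ndarray:
        return np.array([r.rmsep for r in self.records])

    @property
    def r2_curve(self) -> np.ndarray:
        return np.array([r.r2 for r in self.records])


def _prepare_prediction(
    prediction_set: SpectraSet,
    reference: ReferenceSpectrum,
    sg_window: int,
    sg_polyorder: int,
    feature_indices: np.ndarray | None,
) -> np.ndarray:
    corrected, _ = msc_correct(prediction_set, reference)
    smoothed = sg_smooth(corrected, sg_window, sg_polyorder)
    X = smoothed.absorbance
    if feature_indices is not None:
        X = X[:, feature_indices]
    return X


def run_online_session(
    state: RPLSState,
    stream: SpectraSet,
    prediction_set: SpectraSet,
    reference: ReferenceSpectrum,
    batch_size: int = 5,
    sg_window: int = 11,
    sg_polyorder: int = 2,
    monitor_m: int = DEFAULT_MONITOR_M,
    update_reference: bool = True,
    calibration_spectra: SpectraSet | None = None,
) -> SessionReport:
    """Stream samples batch-wise through preprocessing and RPLS updates.

    Each stream sample is scatter-corrected (against the dynamic reference
    when ``update_reference`` is True — the OMSC arm — or the frozen
    calibration reference otherwise — the MSC arm), smoothed, sliced to the
    state's feature subset and folded into the state.  After every batch the
    current model is evaluated on the prediction set, itself corrected with
    the *current* reference and smoothed, and the dominant bands of XᵀX are
    recorded.  Iteration 0 is the un-updated (offline) model's evaluation.

    stream.y must be present (the online samples arrive with their assayed
    reference values).
    """
    if stream.n_samples > 0 and stream.y is None:
        raise ValueError("stream must carry reference values")
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    if not np.array_equal(stream.wavelengths, prediction_set.wavelengths):
        raise ValueError("stream and prediction set grids differ")

    corrector = OnlineScatterCorrector(reference, calibration=calibration_spectra)
    records: list[SessionRecord] = []
    monitors: list[FeatureMonitorReport] = []

    def evaluate_iteration(it: int, n_proc: int, st: RPLSState,
                           ref: ReferenceSpectrum) -> None:
        model = rpls_coefficients(st)
        Xp = _prepare_prediction(prediction_set, ref, sg_window, sg_polyorder,
                                 st.feature_indices)
        y_hat = pls_predict(model, Xp)
        y_true = prediction_set.y
        report = monitor_top_features(st.XtX, m=min(monitor_m, st.Xty.size))
        monitors.append(report)
        records.append(SessionRecord(
            iteration=it,
            n_processed=n_proc,
            rmsep=_rmse(y_true, y_hat),
            r2=_r2(y_true, y_hat, "standard"),
            r2_paper=_r2(y_true, y_hat, "paper"),
            flagged_bands=report.flagged_bands,
        ))

    evaluate_iteration(0, 0, state, corrector.reference)

    n = stream.n_samples
    iteration = 0
    for start in range(0, n, batch_size):
        iteration += 1
        stop = min(start + batch_size, n)
        for i in range(start, stop):
            raw = stream.absorbance[i]
            if update_reference:
                corrected, _ = corrector.correct(raw)
            else:
                one = SpectraSet(stream.wavelengths, raw[None, :])
                corrected_set, _ = msc_correct(one, reference)
                corrected = corrected_set.absorbance[0]
            smoothed = sg_smooth(
                SpectraSet(stream.wavelengths, corrected[None, :]),
                sg_window, sg_polyorder,
            ).absorbance[0]
            x_feat = (smoothed if state.feature_indices is None
                      else smoothed[state.feature_indices])
            state = rpls_update(state, x_feat, float(stream.y[i]))
        current_ref = corrector.reference if update_reference else reference
        evaluate_iteration(iteration, stop, state, current_ref)

    final_ref = corrector.reference if update_reference else reference
    return SessionReport(
        records=records,
        final_model=rpls_coefficients(state),
        reference=final_ref,
        monitor_reports=monitors,
    )
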