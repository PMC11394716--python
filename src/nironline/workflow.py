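"""Pipeline glue: offline model building and the online benchmark protocol.

These functions wire the individual stages (split → scatter correction →
smoothing → band selection → PLS → recursive updates) into the two
workflows the package exists for: building a frozen offline calibration
and upgrading it to an online model that streams new batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (
    DEFAULT_K_OFFLINE,
    DEFAULT_K_ONLINE,
    DEFAULT_MONITOR_M,
    UVEResult,
    uve_select,
    uve_stability,
)
from .metrics import EvaluationReport, evaluate, split_calibration_prediction
from .pls import PLSModel, pls_fit, pls_predict, select_n_lv
from .preprocess import ReferenceSpectrum, SpectraSet, msc_correct, msc_fit, sg_smooth
from .rpls import RPLSState, SessionReport, rpls_init, run_online_session
from .simulate import SimConfig, SyntheticStudy, generate_study

__all__ = [
    "OfflineArtifacts",
    "fit_offline",
    "init_online_state",
    "DriftedBenchmark",
    "run_drifted_benchmark",
]


@dataclass
class OfflineArtifacts:
    """Everything the offline stage produces and the online stage reuses."""

    model: PLSModel
    uve: UVEResult
    reference: ReferenceSpectrum
    n_lv: int
    rmsecv: float
    rmsecv_curve: np.ndarray
    cal_idx: np.ndarray
    pred_idx: np.ndarray
    calibration_report: EvaluationReport
    prediction_report: EvaluationReport
    sg_window: int
    sg_polyorder: int
    # preprocessed calibration matrix on the full grid, kept so the online
    # state can be re-initialized at a different feature count
    X_cal: np.ndarray
    y_cal: np.ndarray
    calibration_spectra: SpectraSet


def _preprocess(spectra: SpectraSet, reference: ReferenceSpectrum,
                sg_window: int, sg_polyorder: int) -> np.ndarray:
    corrected, _ = msc_correct(spectra, reference)
    return sg_smooth(corrected, sg_window, sg_polyorder).absorbance


def fit_offline(
    spectra: SpectraSet,
    k: int = DEFAULT_K_OFFLINE,
    max_lv: int = 10,
    cv_folds: int = 10,
    uve_folds: int | None = None,
    noise_scale: float | None = None,
    sg_window: int = 11,
    sg_polyorder: int = 2,
    split_ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
) -> OfflineArtifacts:
    """Build the frozen offline calibration model.

    Steps: range-rule 2:1 split, MSC against the calibration mean,
    Savitzky–Golay smoothing, latent-variable count by k-fold RMSECV on the
    full spectrum, UVE stability scoring, top-k band selection, and a final
    PLS fit on the selected bands (latent count re-selected there).
    """
    if spectra.y is None:
        raise ValueError("offline spectra must carry reference values")
    cal_idx, pred_idx = split_calibration_prediction(spectra.y, split_ratio, seed)
    cal = SpectraSet(spectra.wavelengths, spectra.absorbance[cal_idx],
                     spectra.y[cal_idx])
    pred = SpectraSet(spectra.wavelengths, spectra.absorbance[pred_idx],
                      spectra.y[pred_idx])

    reference = msc_fit(cal)
    X_cal = _preprocess(cal, reference, sg_window, sg_polyorder)
    X_pred = _preprocess(pred, reference, sg_window, sg_polyorder)

    n_lv_full, _ = select_n_lv(X_cal, cal.y, max_lv, cv_folds, seed)
    uve = uve_stability(X_cal, cal.y, n_lv_full, noise_scale=noise_scale,
                        folds=uve_folds, seed=seed)
    uve = uve_select(uve, k)

    X_cal_sel = X_cal[:, uve.selected]
    max_lv_sel = min(max_lv, X_cal_sel.shape[1])
    n_lv, curve = select_n_lv(X_cal_sel, cal.y, max_lv_sel, cv_folds, seed)
    model = pls_fit(X_cal_sel, cal.y, n_lv, feature_indices=uve.selected)

    cal_report = evaluate(cal.y, pls_predict(model, X_cal_sel))
    pred_report = evaluate(pred.y, pls_predict(model, X_pred[:, uve.selected]))

    return OfflineArtifacts(
        model=model,
        uve=uve,
        reference=reference,
        n_lv=n_lv,
        rmsecv=float(curve[n_lv - 1]),
        rmsecv_curve=curve,
        cal_idx=cal_idx,
        pred_idx=pred_idx,
        calibration_report=cal_report,
        prediction_report=pred_report,
        sg_window=sg_window,
        sg_polyorder=sg_polyorder,
        X_cal=X_cal,
        y_cal=cal.y.copy(),
        calibration_spectra=cal,
    )


def init_online_state(
    artifacts: OfflineArtifacts,
    k_online: int = DEFAULT_K_ONLINE,
    lam: float = 1.0,
    max_lv: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    exact_variance: bool = False,
) -> tuple[RPLSState, UVEResult]:
    """Expand the band subset and rebuild the recursive state.

    The online model widens the UVE selection (default 70 → 100 bands) so
    bands whose importance rises with the new batches are already inside
    the feature subset.  The stability scores from the offline stage are
    reused — only the cut changes — and the recursive state is initialized
    fresh from the offline calibration data at the wider subset.
    """
    uve_online = uve_select(artifacts.uve, k_online)
    X_sel = artifacts.X_cal[:, uve_online.selected]
    max_lv_sel = min(max_lv, X_sel.shape[1], X_sel.shape[0] - 1)
    n_lv, _ = select_n_lv(X_sel, artifacts.y_cal, max_lv_sel, cv_folds, seed)
    state = rpls_init(
        X_sel, artifacts.y_cal, n_lv=n_lv, lam=lam,
        feature_indices=uve_online.selected, exact_variance=exact_variance,
    )
    return state, uve_online


@dataclass
class DriftedBenchmark:
    """Outcome of the full offline→online protocol on one synthetic study."""

    study: SyntheticStudy
    artifacts: OfflineArtifacts
    sessions: dict[str, SessionReport]  # arm name -> report
    stream_idx: np.ndarray
    pred_idx: np.ndarray


def run_drifted_benchmark(
    config: SimConfig | None = None,
    seed: int | None = None,
    arms: tuple[str, ...] = ("omsc-100", "msc-100"),
    batch_size: int = 5,
    lam: float = 0.85,
    k_offline: int = DEFAULT_K_OFFLINE,
    k_online: int = DEFAULT_K_ONLINE,
    monitor_m: int = DEFAULT_MONITOR_M,
    stream_size: int = 60,
) -> DriftedBenchmark:
    """Full study: simulate, fit offline, stream the drifted batch online.

    The online batch is split by the range rule into a stream (default 60
    samples, fed in batches of 5) and a held-out new-batch prediction set
    (the remaining 15) on which every iteration is scored.  Arms:

    - "omsc-100": dynamic reference, band subset widened to ``k_online``
    - "omsc-70": dynamic reference, offline subset kept
    - "msc-100": frozen calibration reference, widened subset
    """
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    study = generate_study(config)
    artifacts = fit_offline(study.offline, k=k_offline, seed=config.seed)

    online = study.online_stream
    n_pred = max(1, online.n_samples - stream_size)
    stream_idx, pred_idx = split_calibration_prediction(
        online.y, ratio=(stream_size, n_pred), seed=config.seed,
    )
    stream = SpectraSet(online.wavelengths, online.absorbance[stream_idx],
                        online.y[stream_idx])
    pred = SpectraSet(online.wavelengths, online.absorbance[pred_idx],
                      online.y[pred_idx])

    sessions: dict[str, SessionReport] = {}
    for arm in arms:
        dynamic = arm.startswith("omsc")
        k_arm = k_online if arm.endswith("100") else k_offline
        state, _ = init_online_state(artifacts, k_online=k_arm, lam=lam,
                                     seed=config.seed)
        sessions[arm] = run_online_session(
            state,
            stream,
            pred,
            reference=artifacts.reference,
            batch_size=batch_size,
            sg_window=artifacts.sg_window,
            sg_polyorder=artifacts.sg_polyorder,
            monitor_m=monitor_m,
            update_reference=dynamic,
            calibration_spectra=artifacts.calibration_spectra,
        )
    return DriftedBenchmark(
        study=study,
        artifacts=artifacts,
        sessions=sessions,
        stream_idx=stream_idx,
        pred_idx=pred_idx,
    )
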