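"""Model evaluation metrics and the calibration/prediction split rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvaluationReport", "rmse", "r2", "evaluate", "split_calibration_prediction"]


@dataclass
class EvaluationReport:
    rmse: float
    r2_standard: float
    r2_paper: float
    n: int


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValueError("empty vectors")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean square error, sqrt(mean((y - ŷ)²))."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r2(y_true, y_pred, variant: str = "standard") -> float:
    """Coefficient of determination.

    variant="standard": 1 - Σ(y-ŷ)²/Σ(y-ȳ)², the usual definition.
    variant="paper": Σ(ŷ-y)²/Σ(ŷ-ȳ)² — a nonstandard ratio kept for
    fidelity with a published formulation; note it evaluates to 0 for
    perfect predictions, so it is reported as a diagnostic only.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 2:
        raise ValueError("need at least 2 samples for R²")
    y_bar = y_true.mean()
    if np.all(y_true == y_true[0]):
        raise ValueError("y_true is constant; R² undefined")
    if variant == "standard":
        return float(1.0 - np.sum((y_true - y_pred) ** 2) / np.sum((y_true - y_bar) ** 2))
    if variant == "paper":
        denom = np.sum((y_pred - y_bar) ** 2)
        if denom == 0.0:
            return float("inf") if np.any(y_pred != y_true) else 0.0
        return float(np.sum((y_pred - y_true) ** 2) / denom)
    raise ValueError(f"unknown variant {variant!r}")


def evaluate(y_true, y_pred) -> EvaluationReport:
    """RMSE plus both R² variants in one report."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return EvaluationReport(
        rmse=rmse(y_true, y_pred),
        r2_standard=r2(y_true, y_pred, "standard"),
        r2_paper=r2(y_true, y_pred, "paper"),
        n=y_true.size,
    )


def split_calibration_prediction(
    y,
    ratio: tuple[int, int] = (2, 1),
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random calibration/prediction split with the range-coverage rule.

    The samples holding the minimum and maximum reference value are pinned
    to the calibration set before the remaining samples are assigned at
    random, so the calibration range always covers the prediction range.
    Returns (calibration indices, prediction indices), each sorted.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    cal_part, pred_part = ratio
    if cal_part <= 0 or pred_part <= 0:
        raise ValueError("ratio parts must be positive")
    n_cal = int(round(n * cal_part / (cal_part + pred_part)))
    n_cal = min(max(n_cal, 2), n - 1)  # room for both extremes and ≥1 prediction
    pinned = np.unique([int(np.argmin(y)), int(np.argmax(y))])
    if n_cal < pinned.size:
        raise ValueError("calibration share too small to hold the y extremes")
    rest = np.setdiff1d(np.arange(n), pinned)
    rng = np.random.default_rng(seed)
    rest = rng.permutation(rest)
    cal = np.sort(np.concatenate([pinned, rest[: n_cal - pinned.size]]))
    pred = np.sort(rest[n_cal - pinned.size:])
    return cal, pred
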