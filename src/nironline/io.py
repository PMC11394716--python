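"""File formats and run configuration.

Spectra travel as comma-separated text: an optional ``#`` comment header
naming units and the producing command, a header row of strictly
increasing wavelengths in nm (plus an optional final ``y`` column for the
reference value, % fat), and one row of absorbances per sample.  Models
and recursive states serialize to versioned JSON; run configuration is a
YAML file mirroring the library defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .pls import PLSModel
from .preprocess import ReferenceSpectrum, SpectraSet
from .rpls import RPLSState, SessionReport
from .simulate import BatchDrift, SimConfig

__all__ = [
    "read_spectra",
    "write_spectra",
    "write_table",
    "save_model_bundle",
    "load_model_bundle",
    "session_report_frame",
    "RunConfig",
    "load_config",
    "save_config",
]

logger = logging.getLogger("nironline")

_MODEL_FORMAT = "nironline-model-bundle"
_MODEL_VERSION = 1


def _header_comment(command: str, extra: str = "") -> str:
    base = (f"# nironline v{_pkg_version} :: {command} :: "
            "wavelengths nm, absorbance AU, y %fat")
    return base + (f" :: {extra}" if extra else "")


def write_spectra(spectra: SpectraSet, path: str | Path,
                  command: str = "write-spectra") -> None:
    """Write a SpectraSet as CSV (wavelength header, optional y column)."""
    path = Path(path)
    # repr gives the shortest exact round-trip decimal for the grid
    cols = [repr(float(w)) for w in spectra.wavelengths]
    data = spectra.absorbance
    if spectra.y is not None:
        cols = cols + ["y"]
        data = np.column_stack([data, spectra.y])
    frame = pd.DataFrame(data, columns=cols)
    with open(path, "w") as fh:
        fh.write(_header_comment(command) + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_spectra(path: str | Path) -> SpectraSet:
    """Read the CSV spectra dialect back into a SpectraSet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed spectra file: {exc}") from None
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected a wavelength header row")
    has_y = frame.columns[-1].strip().lower() == "y"
    wl_cols = frame.columns[:-1] if has_y else frame.columns
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength in header: {exc}") from None
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError(f"{path}: wavelength header is not strictly increasing")
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric cell at data row {row}, column {col!r}"
            )
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any().argmax()]
        row = int(frame[frame.isna().any(axis=1)].index[0])
        raise ValueError(f"{path}: missing value at data row {row}, column {col!r}")
    values = frame.to_numpy(dtype=float)
    y = values[:, -1] if has_y else None
    absorbance = values[:, :-1] if has_y else values
    return SpectraSet(wavelengths, absorbance, y)


def check_same_grid(a: SpectraSet, b: SpectraSet, name_a: str, name_b: str) -> None:
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise ValueError(
            f"wavelength grids of {name_a!r} and {name_b!r} differ"
        )


def write_table(frame: pd.DataFrame, path: str | Path,
                command: str, units: str = "") -> None:
    """Write a generic output table with the standard comment header."""
    with open(path, "w") as fh:
        fh.write(_header_comment(command, units) + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def session_report_frame(report: SessionReport) -> pd.DataFrame:
    """Iteration table (iteration, n_processed, RMSEP, R², printed-form R²)."""
    return pd.DataFrame(
        {
            "iteration": [r.iteration for r in report.records],
            "n_processed": [r.n_processed for r in report.records],
            "rmsep": [r.rmsep for r in report.records],
            "r2": [r.r2 for r in report.records],
            "r2_paper_variant": [r.r2_paper for r in report.records],
        }
    )


# --------------------------------------------------------------------------
# model bundle (offline PLS model + recursive state + reference spectrum)

def _model_to_dict(model: PLSModel) -> dict:
    return {
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "y_mean": model.y_mean,
        "y_std": model.y_std,
        "coefficients": model.coefficients.tolist(),
        "n_lv": model.n_lv,
        "feature_indices": (None if model.feature_indices is None
                            else model.feature_indices.tolist()),
    }


def _model_from_dict(d: dict) -> PLSModel:
    return PLSModel(
        x_mean=np.array(d["x_mean"]),
        x_std=np.array(d["x_std"]),
        y_mean=float(d["y_mean"]),
        y_std=float(d["y_std"]),
        coefficients=np.array(d["coefficients"]),
        n_lv=int(d["n_lv"]),
        feature_indices=(None if d["feature_indices"] is None
                         else np.array(d["feature_indices"], dtype=int)),
    )


def _state_to_dict(state: RPLSState) -> dict:
    return {
        "XtX": state.XtX.tolist(),
        "Xty": state.Xty.tolist(),
        "x_mean": state.x_mean.tolist(),
        "x_std": state.x_std.tolist(),
        "y_mean": state.y_mean,
        "y_std": state.y_std,
        "N": state.N,
        "lam": state.lam,
        "n_lv": state.n_lv,
        "feature_indices": (None if state.feature_indices is None
                            else state.feature_indices.tolist()),
        "exact_variance": state.exact_variance,
    }


def _state_from_dict(d: dict) -> RPLSState:
    return RPLSState(
        XtX=np.array(d["XtX"]),
        Xty=np.array(d["Xty"]),
        x_mean=np.array(d["x_mean"]),
        x_std=np.array(d["x_std"]),
        y_mean=float(d["y_mean"]),
        y_std=float(d["y_std"]),
        N=int(d["N"]),
        lam=float(d["lam"]),
        n_lv=int(d["n_lv"]),
        feature_indices=(None if d["feature_indices"] is None
                         else np.array(d["feature_indices"], dtype=int)),
        exact_variance=bool(d["exact_variance"]),
    )


def save_model_bundle(
    path: str | Path,
    model: PLSModel,
    state: RPLSState,
    reference: ReferenceSpectrum,
    wavelengths: np.ndarray,
    sg_window: int,
    sg_polyorder: int,
    meta: dict | None = None,
) -> None:
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "package_version": _pkg_version,
        "model": _model_to_dict(model),
        "state": _state_to_dict(state),
        "reference": {"mean_spectrum": reference.mean_spectrum.tolist(),
                      "n": reference.n},
        "wavelengths": np.asarray(wavelengths, float).tolist(),
        "sg_window": sg_window,
        "sg_polyorder": sg_polyorder,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model_bundle(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a nironline model bundle")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(f"{path}: unsupported bundle version {payload.get('version')}")
    return {
        "model": _model_from_dict(payload["model"]),
        "state": _state_from_dict(payload["state"]),
        "reference": ReferenceSpectrum(
            np.array(payload["reference"]["mean_spectrum"]),
            int(payload["reference"]["n"]),
        ),
        "wavelengths": np.array(payload["wavelengths"]),
        "sg_window": int(payload["sg_window"]),
        "sg_polyorder": int(payload["sg_polyorder"]),
        "meta": payload.get("meta", {}),
    }


# --------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Validated run configuration with the full default set.

    Numeric fields are checked against the preconditions of the stages
    that consume them as soon as the file is loaded, so a bad value fails
    at startup rather than mid-pipeline.
    """

    sg_window: int = 11
    sg_polyorder: int = 2
    omsc: bool = True
    k_offline: int = 70
    k_online: int = 100
    uve_folds: int | None = None      # None = leave-one-out
    uve_noise_scale: float | None = None
    max_lv: int = 10
    cv_folds: int = 10
    lam: float = 0.85
    batch_size: int = 5
    monitor_m: int = 30
    split_ratio: tuple[int, int] = (2, 1)
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")
        for name in ("k_offline", "k_online", "max_lv", "batch_size", "monitor_m"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")
        if self.split_ratio[0] < 1 or self.split_ratio[1] < 1:
            raise ValueError("split_ratio parts must be positive")
        if self.uve_noise_scale is not None and self.uve_noise_scale <= 0:
            raise ValueError("uve_noise_scale must be positive")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def _tupleize(seq, depth=1):
    if depth == 0 or not isinstance(seq, (list, tuple)):
        return seq
    return tuple(_tupleize(v, depth - 1) for v in seq)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sim_raw = raw.pop("sim", {}) or {}
    drift_raw = sim_raw.pop("batch_drift", None)
    sim_kwargs = dict(sim_raw)
    for key in ("peak_centers", "peak_widths", "peak_heights"):
        if key in sim_kwargs:
            sim_kwargs[key] = _tupleize(sim_kwargs[key], depth=2)
    for key in ("y_range", "other_conc_range", "baseline_coeffs"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    if drift_raw is not None:
        sim_kwargs["batch_drift"] = BatchDrift(**drift_raw)
    if "split_ratio" in raw:
        raw["split_ratio"] = tuple(raw["split_ratio"])
    try:
        return RunConfig(sim=SimConfig(**sim_kwargs), **raw)
    except TypeError as exc:
        raise ValueError(f"{path}: unknown configuration key: {exc}") from None
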