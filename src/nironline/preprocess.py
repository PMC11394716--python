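"""Scatter correction and smoothing for NIR absorbance spectra.

Multiplicative scatter correction (MSC) regresses each sample spectrum on a
reference (mean) spectrum and removes the fitted multiplicative/additive
component.  The online variant (OMSC) keeps a *dynamic* reference — a running
mean updated with every incoming spectrum — so new samples can be corrected
without access to the original calibration spectra.  Savitzky–Golay smoothing
removes high-frequency noise channel-wise, one sample at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "SpectraSet",
    "ReferenceSpectrum",
    "ScatterParams",
    "OMSCDiagnostics",
    "msc_fit",
    "msc_correct",
    "omsc_update",
    "sg_smooth",
    "DEFAULT_SLOPE_FLOOR",
]

#: Minimum |slope| accepted when inverting the per-sample scatter fit.
#: Below this the correction (x - b) / a would blow up, so the sample is
#: flagged and left uncorrected.
DEFAULT_SLOPE_FLOOR = 1e-6


@dataclass
class SpectraSet:
    """Absorbance spectra on a common wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray, shape (p,)
        Strictly increasing grid in nm.
    absorbance : ndarray, shape (n, p)
        One row per sample, absorbance units.
    y : ndarray, shape (n,), optional
        Reference values (e.g. fat content, % by mass).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {self.wavelengths.size} wavelengths"
            )
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.absorbance.shape[0],):
                raise ValueError("y length must equal the number of samples")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def replace_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same grid and y, new absorbance matrix."""
        return SpectraSet(self.wavelengths, absorbance, self.y)


@dataclass
class ReferenceSpectrum:
    """Running mean spectrum x̄ and the number of samples it summarizes."""

    mean_spectrum: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        if self.mean_spectrum.ndim != 1:
            raise ValueError("mean_spectrum must be one-dimensional")
        if self.n < 1:
            raise ValueError("reference must summarize at least one sample")


@dataclass
class ScatterParams:
    """Per-sample scatter fit x_i = a_i * reference + b_i.

    ``flagged`` marks samples whose |a_i| fell below the slope floor; their
    rows in the corrected matrix are left equal to the input.
    """

    slope: np.ndarray
    intercept: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        self.slope = np.atleast_1d(np.asarray(self.slope, dtype=float))
        self.intercept = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        self.flagged = np.atleast_1d(np.asarray(self.flagged, dtype=bool))


@dataclass
class OMSCDiagnostics:
    """Running diagnostics for the dynamic-reference update.

    ``E`` is the maximum absolute absorbance deviation between any two
    samples seen so far at any single wavelength.  Tracking the per-channel
    running min/max gives it exactly without retaining raw spectra:
    max_{i,j} |x_i(w) - x_j(w)| = max_i x_i(w) - min_i x_i(w).

    Every reference update obeys max|x̄_{n+1} - x̄_n| < E/(n+1) (with equality
    only in the degenerate all-identical stream); ``check_shift_bound``
    verifies the recorded history against E.
    """

    channel_min: np.ndarray | None = None
    channel_max: np.ndarray | None = None
    reference_shifts: list = field(default_factory=list)
    shift_denominators: list = field(default_factory=list)

    def observe(self, spectrum: np.ndarray) -> None:
        x = np.asarray(spectrum, dtype=float)
        if self.channel_min is None:
            self.channel_min = x.copy()
            self.channel_max = x.copy()
        else:
            np.minimum(self.channel_min, x, out=self.channel_min)
            np.maximum(self.channel_max, x, out=self.channel_max)

    @property
    def E(self) -> float:
        if self.channel_min is None:
            return 0.0
        return float(np.max(self.channel_max - self.channel_min))

    def record_shift(self, shift: float, n_plus_1: int) -> None:
        self.reference_shifts.append(float(shift))
        self.shift_denominators.append(int(n_plus_1))

    def check_shift_bound(self, rtol: float = 1e-12, atol: float = 1e-15) -> bool:
        """True when every recorded shift satisfies shift <= E/(n+1)."""
        E = self.E
        for shift, np1 in zip(self.reference_shifts, self.shift_denominators):
            bound = E / np1
            if shift > bound * (1.0 + rtol) + atol:
                return False
        return True


def _ols_on_reference(X: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope/intercept of each row of X on ref (x = a*ref + b)."""
    ref_mean = ref.mean()
    ref_centered = ref - ref_mean
    denom = float(ref_centered @ ref_centered)
    if denom <= 0.0:
        raise ValueError("reference spectrum is constant; scatter slope undefined")
    slope = (X - X.mean(axis=1, keepdims=True)) @ ref_centered / denom
    intercept = X.mean(axis=1) - slope * ref_mean
    return slope, intercept


def msc_fit(spectra: SpectraSet) -> ReferenceSpectrum:
    """Mean spectrum of a calibration set, the MSC reference."""
    if spectra.n_samples < 1:
        raise ValueError("cannot fit a reference on an empty set")
    return ReferenceSpectrum(spectra.absorbance.mean(axis=0), spectra.n_samples)


def msc_correct(
    spectra: SpectraSet,
    reference: ReferenceSpectrum,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
) -> tuple[SpectraSet, ScatterParams]:
    """Correct each spectrum against a fixed reference.

    For every sample the least-squares fit x_i = a_i * x̄ + b_i is computed
    and the corrected spectrum is (x_i - b_i) / a_i.  Samples with
    |a_i| < slope_floor are flagged and passed through unchanged.
    """
    if reference.mean_spectrum.size != spectra.n_channels:
        raise ValueError("reference and spectra grids differ in length")
    X = spectra.absorbance
    slope, intercept = _ols_on_reference(X, reference.mean_spectrum)
    flagged = np.abs(slope) < slope_floor
    safe_slope = np.where(flagged, 1.0, slope)
    corrected = (X - intercept[:, None]) / safe_slope[:, None]
    corrected[flagged] = X[flagged]
    return (
        spectra.replace_absorbance(corrected),
        ScatterParams(slope, intercept, flagged),
    )


def omsc_update(
    reference: ReferenceSpectrum,
    new_spectrum: np.ndarray,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
    diagnostics: OMSCDiagnostics | None = None,
) -> tuple[np.ndarray, ScatterParams, ReferenceSpectrum]:
    """Fold one new spectrum into the dynamic reference and correct it.

    The reference mean is updated first, x̄_{n+1} = (n·x̄_n + x)/(n+1), then
    the new spectrum is regressed on the *updated* reference and corrected
    as (x - b)/a.  Returns (corrected spectrum, scatter fit, new reference).
    """
    x = np.asarray(new_spectrum, dtype=float).ravel()
    if x.size != reference.mean_spectrum.size:
        raise ValueError("new spectrum length does not match the reference grid")
    if not np.all(np.isfinite(x)):
        raise ValueError("new spectrum contains non-finite values")
    n = reference.n
    new_mean = (reference.mean_spectrum * n + x) / (n + 1)
    updated = ReferenceSpectrum(new_mean, n + 1)
    shift = float(np.max(np.abs(new_mean - reference.mean_spectrum)))
    if diagnostics is not None:
        diagnostics.observe(x)
        diagnostics.record_shift(shift, n + 1)

    slope_arr, intercept_arr = _ols_on_reference(x[None, :], new_mean)
    a, b = float(slope_arr[0]), float(intercept_arr[0])
    flagged = abs(a) < slope_floor
    corrected = x.copy() if flagged else (x - b) / a
    params = ScatterParams([a], [b], [flagged])
    return corrected, params, updated


class OnlineScatterCorrector:
    """Stateful wrapper around :func:`omsc_update` for streaming sessions.

    Seeds diagnostics with the calibration min/max when the calibration
    spectra are supplied, so E covers every sample seen by the reference.
    """

    def __init__(
        self,
        reference: ReferenceSpectrum,
        calibration: SpectraSet | None = None,
        slope_floor: float = DEFAULT_SLOPE_FLOOR,
    ) -> None:
        self.reference = reference
        self.slope_floor = slope_floor
        self.diagnostics = OMSCDiagnostics()
        if calibration is not None:
            for row in calibration.absorbance:
                self.diagnostics.observe(row)

    def correct(self, new_spectrum: np.ndarray) -> tuple[np.ndarray, ScatterParams]:
        corrected, params, self.reference = omsc_update(
            self.reference,
            new_spectrum,
            slope_floor=self.slope_floor,
            diagnostics=self.diagnostics,
        )
        return corrected, params


def sg_smooth(spectra: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky–Golay smoothing, applied independently to every sample.

    ``window`` must be odd, larger than ``polyorder`` and no longer than the
    grid.  Edges are handled by fitting a polynomial over the terminal
    window; the interior is the contract-bearing region.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed the polynomial order")
    if window > spectra.n_channels:
        raise ValueError("window longer than the wavelength grid")
    smoothed = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        axis=1, mode="interp",
    )
    return spectra.replace_absorbance(smoothed)
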