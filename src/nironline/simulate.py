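"""Seeded synthetic NIR studies with known ground truth.

The generator emulates the statistical structure an online NIR calibration
must cope with: a 512-channel 900–1700 nm absorbance grid, analyte-driven
Gaussian absorption bands on a smooth polynomial baseline, per-sample
multiplicative/additive scatter, heteroscedastic high-frequency noise
concentrated toward the long-wavelength end, and a systematic batch drift
separating the "offline" calibration set from the "online" sample stream.

Component 0 is the designated fat analyte: its reference value y (% fat)
drives its concentration, and the channels inside its absorption bands are
recorded as the true informative bands, so band-selection and model-update
behaviour can be checked against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SpectraSet

__all__ = [
    "BatchDrift",
    "SimConfig",
    "BatchTruth",
    "SyntheticStudy",
    "generate_component_library",
    "informative_bands",
    "generate_batch",
    "generate_study",
]


@dataclass
class BatchDrift:
    """Systematic shift applied to the online stream's distributions.

    A flat additive shift and a mean shift of the per-sample scatter are,
    by construction, removed by the affine scatter correction, so drift
    that actually degrades a frozen calibration needs spectrally
    structured components: a wavelength-dependent baseline tilt, a shift
    in the non-analyte (moisture-like) concentration distribution, and a
    change in the analyte's spectral response — the kinds of change that
    storage conditions and origin differences produce.  Defaults are
    chosen so the frozen offline model visibly degrades on the drifted
    stream while the spectra remain plausible absorbances.
    """

    baseline_shift: float = 0.03      # flat additive absorbance on the ideal spectrum
    baseline_tilt: float = 0.015      # additive ramp, 0 at wl_min to this at wl_max
    slope_mean_shift: float = 0.05    # mean shift of the multiplicative scatter a_i
    offset_mean_shift: float = 0.02   # mean shift of the additive scatter b_i
    y_shift: float = -3.0             # shift of the analyte (% fat) distribution
    moisture_shift: float = 0.03      # shift of the non-analyte concentration range
    analyte_response_scale: float = 0.87  # scale on the analyte component's response

    def is_null(self) -> bool:
        return (self.baseline_shift == 0 and self.baseline_tilt == 0
                and self.slope_mean_shift == 0 and self.offset_mean_shift == 0
                and self.y_shift == 0 and self.moisture_shift == 0
                and self.analyte_response_scale == 1.0)


# Default pure-component bands (centers nm, 1-sigma widths nm, peak heights).
# Component 0 is the fat analyte (C–H overtone region bands); the others are
# stand-ins for water (O–H) and protein (N–H) absorbers with concentrations
# independent of y.  The analyte response is deliberately small relative to
# the water/protein/baseline structure: scatter correction estimates its
# per-sample affine fit from the whole spectrum and assumes that fit is
# analyte-independent, which holds only when the analyte bands contribute
# little to the full-spectrum variance — the regime real NIR spectra of
# high-moisture biological samples are in.
_DEFAULT_CENTERS = ((1210.0, 1370.0), (1460.0, 970.0), (1020.0, 1580.0))
_DEFAULT_WIDTHS = ((18.0, 20.0), (28.0, 30.0), (35.0, 40.0))
_DEFAULT_HEIGHTS = ((0.06, 0.042), (0.9, 0.5), (0.6, 0.3))


@dataclass
class SimConfig:
    """Everything the generator needs, seed included."""

    n_channels: int = 512
    wl_min: float = 900.0
    wl_max: float = 1700.0
    n_components: int = 3
    peak_centers: tuple = _DEFAULT_CENTERS
    peak_widths: tuple = _DEFAULT_WIDTHS
    peak_heights: tuple = _DEFAULT_HEIGHTS
    fat_component: int = 0
    y_range: tuple = (40.0, 75.0)
    other_conc_range: tuple = (0.10, 0.30)
    baseline_coeffs: tuple = (0.3, 0.15, -0.1)  # polynomial in (wl-wl_min)/(wl_max-wl_min)
    scatter_slope_sd: float = 0.03
    scatter_offset_sd: float = 0.015
    noise_sd_base: float = 0.003
    noise_sd_highband: float = 0.008
    noise_band_start: float = 1500.0
    batch_drift: BatchDrift = field(default_factory=BatchDrift)
    n_offline: int = 120
    n_online: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_min >= self.wl_max:
            raise ValueError("wl_min must be below wl_max")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.y_range[0] >= self.y_range[1]:
            raise ValueError("y_range low must be below high")
        for name in ("scatter_slope_sd", "scatter_offset_sd",
                     "noise_sd_base", "noise_sd_highband"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.fat_component < self.n_components:
            raise ValueError("fat_component out of range")
        if not (len(self.peak_centers) == len(self.peak_widths)
                == len(self.peak_heights) == self.n_components):
            raise ValueError("peak lists must have one entry per component")
        for centers, widths in zip(self.peak_centers, self.peak_widths):
            for c, w in zip(centers, widths):
                if not self.wl_min <= c <= self.wl_max:
                    raise ValueError(
                        f"peak center {c} nm outside grid [{self.wl_min}, {self.wl_max}] nm"
                    )
                if w <= 0:
                    raise ValueError(f"peak width must be positive, got {w}")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_channels)


@dataclass
class BatchTruth:
    """Ground truth for one generated batch."""

    slope: np.ndarray       # true multiplicative scatter a_i
    intercept: np.ndarray   # true additive scatter b_i
    y: np.ndarray
    concentrations: np.ndarray  # samples × components


@dataclass
class SyntheticStudy:
    offline: SpectraSet
    online_stream: SpectraSet
    offline_truth: BatchTruth
    online_truth: BatchTruth
    informative_bands: np.ndarray
    config: SimConfig


def generate_component_library(config: SimConfig) -> np.ndarray:
    """Pure-component spectra (n_components × n_channels), Gaussian bands."""
    wl = config.wavelengths
    lib = np.zeros((config.n_components, config.n_channels))
    for k in range(config.n_components):
        for c, w, h in zip(config.peak_centers[k], config.peak_widths[k],
                           config.peak_heights[k]):
            lib[k] += h * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return lib


def informative_bands(config: SimConfig, rel_height: float = 0.5) -> np.ndarray:
    """Channels inside the fat analyte's absorption bands.

    A channel is informative when the fat component's pure spectrum there
    exceeds ``rel_height`` of its global maximum (the FWHM region for the
    default 0.5).
    """
    fat = generate_component_library(config)[config.fat_component]
    return np.flatnonzero(fat >= rel_height * fat.max())


def _baseline(config: SimConfig) -> np.ndarray:
    t = (config.wavelengths - config.wl_min) / (config.wl_max - config.wl_min)
    return sum(c * t ** i for i, c in enumerate(config.baseline_coeffs))


def generate_batch(
    config: SimConfig,
    n: int,
    drift: BatchDrift | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[SpectraSet, BatchTruth]:
    """Draw one batch of n observed spectra with its ground truth.

    observed_i = a_i * ideal_i + b_i + noise, where ideal_i =
    concentrations_i @ library + baseline (plus, under drift, the flat
    baseline shift, the baseline tilt and the rescaled analyte response),
    a_i ~ 1 + drift + N(0, scatter_slope_sd), b_i ~ drift +
    N(0, scatter_offset_sd), and the noise sd is ``noise_sd_base`` below
    ``noise_band_start`` nm and ``noise_sd_highband`` at or above it.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    lib = generate_component_library(config)
    wl = config.wavelengths

    y_lo, y_hi = config.y_range
    y_shift = drift.y_shift if drift else 0.0
    y = rng.uniform(y_lo + y_shift, y_hi + y_shift, size=n)

    conc = np.empty((n, config.n_components))
    conc[:, config.fat_component] = y / 100.0
    others = [k for k in range(config.n_components) if k != config.fat_component]
    lo, hi = config.other_conc_range
    conc_shift = drift.moisture_shift if drift else 0.0
    for k in others:
        conc[:, k] = rng.uniform(lo + conc_shift, hi + conc_shift, size=n)

    if drift and drift.analyte_response_scale != 1.0:
        lib = lib.copy()
        lib[config.fat_component] *= drift.analyte_response_scale

    ideal = conc @ lib + _baseline(config)
    if drift:
        t = (wl - config.wl_min) / (config.wl_max - config.wl_min)
        ideal = ideal + drift.baseline_shift + drift.baseline_tilt * t

    slope_mu = 1.0 + (drift.slope_mean_shift if drift else 0.0)
    offset_mu = drift.offset_mean_shift if drift else 0.0
    a = slope_mu + rng.normal(0.0, config.scatter_slope_sd, size=n)
    b = offset_mu + rng.normal(0.0, config.scatter_offset_sd, size=n)

    noise_sd = np.where(wl >= config.noise_band_start,
                        config.noise_sd_highband, config.noise_sd_base)
    noise = rng.normal(0.0, 1.0, size=(n, config.n_channels)) * noise_sd

    observed = a[:, None] * ideal + b[:, None] + noise
    return SpectraSet(wl, observed, y=y), BatchTruth(a, b, y, conc)


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Offline set (no drift) plus drifted online stream, one shared grid.

    Defaults emulate a two-phase acquisition campaign: 120 offline samples
    for model building and 75 sequentially arriving online samples from
    later batches whose scatter, baseline and analyte distributions have
    drifted.  Fully deterministic given config.seed.
    """
    ss = np.random.SeedSequence(config.seed)
    off_seed, on_seed = ss.spawn(2)
    offline, off_truth = generate_batch(config, config.n_offline, None, off_seed)
    online, on_truth = generate_batch(
        config, config.n_online, config.batch_drift, on_seed
    )
    return SyntheticStudy(
        offline=offline,
        online_stream=online,
        offline_truth=off_truth,
        online_truth=on_truth,
        informative_bands=informative_bands(config),
        config=config,
    )
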