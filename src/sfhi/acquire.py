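"""Forward simulation of grid-modulated x-ray exposures.

The noise-free expectation at the detector is

    E[I](x, y) = fluence * exp(-A(x, y)) * [T_grid (*) G_sigma(x,y)](x, y)

i.e. the grid shadow blurred by the local small-angle-scatter kernel, then
attenuated by the object, then scaled by the open-beam fluence.  G_sigma is a
unit-mass isotropic Gaussian; the spatially varying convolution is realised by
linear blending between a bank of uniformly blurred grids at sigma levels
quantized to 0.1 px.  Blurring is performed in the Fourier domain with the
continuous Gaussian transfer function exp(-2 pi^2 sigma^2 |f|^2), which is
mass-preserving and makes the first-harmonic damping follow the closed form
exactly.  Counting noise, when enabled, is a seeded Poisson draw of the
expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, make_grid_image
from .phantom import Phantom

__all__ = [
    "Geometry",
    "AcquisitionSettings",
    "Exposure",
    "gaussian_blur_periodic",
    "simulate_acquisition",
    "simulate_reference",
]

#: quantization step for the blur bank, pixels
SIGMA_STEP = 0.1


@dataclass(frozen=True)
class Geometry:
    """Source-sample-detector geometry (the grid sits just after the source).

    Magnification = source_detector_m / sample_position_m is always derived,
    never stored.  In this 2-D model magnification only rescales the grid
    pitch as seen at the detector; cone-beam divergence is not simulated.
    """

    source_detector_m: float = 1.6
    sample_position_m: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.sample_position_m < self.source_detector_m):
            raise ValueError(
                "require 0 < sample_position_m < source_detector_m, got "
                f"{self.sample_position_m} vs {self.source_detector_m}"
            )
        m = self.source_detector_m / self.sample_position_m
        if not (1.0 <= m <= 10.0):
            raise ValueError(f"magnification {m:.3g} outside [1, 10]")

    @property
    def magnification(self) -> float:
        return self.source_detector_m / self.sample_position_m


@dataclass(frozen=True)
class AcquisitionSettings:
    """Photon budget and noise switches for one exposure."""

    fluence: float = 1.0e4  # mean photons per pixel in the open beam
    rng_seed: int = 0
    noise_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.fluence > 0:
            raise ValueError(f"fluence must be positive, got {self.fluence}")


@dataclass
class Exposure:
    """One recorded raster plus the provenance needed to reconstruct it."""

    pixels: np.ndarray
    grid: GridSpec
    geometry: Geometry | None = None
    settings: AcquisitionSettings | None = None
    kind: str = "sample"  # "sample" | "reference"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if np.any(self.pixels < 0):
            raise ValueError("exposure pixels must be nonnegative")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.pixels, dtype=dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def gaussian_blur_periodic(image: np.ndarray, sigma: float) -> np.ndarray:
    """Periodic convolution with a unit-mass isotropic Gaussian of RMS ``sigma``.

    Implemented as multiplication by exp(-2 pi^2 sigma^2 (fx^2 + fy^2)) in the
    2-D spectrum; the DC term is untouched, so total intensity is conserved.
    """
    if sigma == 0.0:
        return np.array(image, dtype=float, copy=True)
    fr = np.fft.fftfreq(image.shape[0])[:, None]
    fc = np.fft.fftfreq(image.shape[1])[None, :]
    transfer = np.exp(-2.0 * np.pi**2 * sigma**2 * (fr**2 + fc**2))
    return np.fft.ifft2(np.fft.fft2(image) * transfer).real


def _blurred_grid_bank(T: np.ndarray, sigma: np.ndarray, pitch_px: float) -> np.ndarray:
    """Spatially varying blur via linear blending over quantized sigma levels."""
    smax = float(sigma.max())
    if smax == 0.0:
        return np.array(T, copy=True)
    if smax > pitch_px:
        warnings.warn(
            f"max scatter blur sigma {smax:.2f} px exceeds grid pitch "
            f"{pitch_px} px: first harmonic fully damped, scatter unrecoverable",
            stacklevel=3,
        )
    idx = sigma / SIGMA_STEP
    lo = np.floor(idx).astype(int)
    frac = idx - lo
    levels = np.unique(np.concatenate([lo.ravel(), (lo + 1).ravel()]))
    bank = {int(L): gaussian_blur_periodic(T, float(L) * SIGMA_STEP) for L in levels}
    out = np.zeros_like(T)
    for L in levels:
        m = lo == L
        if m.any():
            out[m] += (1.0 - frac[m]) * bank[int(L)][m]
        m = (lo + 1) == L
        if m.any():
            out[m] += frac[m] * bank[int(L)][m]
    return out


def simulate_acquisition(
    phantom: Phantom,
    grid: GridSpec,
    geometry: Geometry | None = None,
    settings: AcquisitionSettings | None = None,
) -> Exposure:
    """Simulate one sample exposure of the phantom behind the grid."""
    settings = settings or AcquisitionSettings()
    T = make_grid_image(grid, phantom.shape)
    blurred = _blurred_grid_bank(T, phantom.sigma_map, grid.pitch_px)
    expectation = settings.fluence * np.exp(-phantom.optical_depth) * blurred
    pixels = _maybe_poisson(expectation, settings)
    return Exposure(pixels, grid, geometry, settings, kind="sample")


def simulate_reference(
    grid: GridSpec,
    shape: tuple[int, int],
    geometry: Geometry | None = None,
    settings: AcquisitionSettings | None = None,
) -> Exposure:
    """Simulate the grid-only flat-field exposure (no object in the beam)."""
    settings = settings or AcquisitionSettings()
    expectation = settings.fluence * make_grid_image(grid, shape)
    pixels = _maybe_poisson(expectation, settings)
    return Exposure(pixels, grid, geometry, settings, kind="reference")


def _maybe_poisson(expectation: np.ndarray, settings: AcquisitionSettings) -> np.ndarray:
    if not settings.noise_enabled:
        return expectation
    rng = np.random.default_rng(settings.rng_seed)
    return rng.poisson(expectation).astype(float)
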