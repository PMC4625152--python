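"""Fourier-harmonic demodulation of one grid-modulated exposure.

The periodic grid shadow places carrier peaks at (m, n)/pitch cycles/pixel in
the 2-D spectrum.  Small-angle scattering by the object damps the first-order
carriers, while absorption scales all orders together.  Demodulating the
zero-order band and the two first-order bands of a sample exposure against a
grid-only reference therefore separates, per pixel:

    absorption = -ln[ M00(sample) / M00(reference) ]
    scatter_h  = -ln[ (M0h(sample)/M00(sample)) / (M0h(reference)/M00(reference)) ]
    scatter_v  =  analogous, with the vertical-frequency carrier

where M is the magnitude of the complex band envelope.  ``scatter_h`` uses the
carrier that varies horizontally (column frequency 1/pitch), i.e. it responds
to horizontal beam deflections; ``scatter_v`` the row-frequency carrier.  For
a Gaussian angular blur of RMS sigma pixels at carrier frequency f0, the
scatter metric has the closed form S = 2 pi^2 sigma^2 f0^2, which
``scatter_to_sigma`` inverts.  The log ratio-of-ratios is used (rather than
1 - ratio) because it is exactly linear in sigma^2 and additive along the beam.

Quantitative statistics should exclude a margin of one grid period at the
image border (``ReconstructionResult.margin_px``, FFT wrap-around).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquire import Exposure

__all__ = [
    "HarmonicBand",
    "ReconstructionResult",
    "FlatFieldError",
    "NoGridError",
    "bands_for_pitch",
    "estimate_grid_frequency",
    "extract_harmonic",
    "reconstruct",
    "scatter_to_sigma",
    "interior",
]


class FlatFieldError(ValueError):
    """Reference exposure unusable for normalization."""


class NoGridError(ValueError):
    """No grid modulation detectable in the reference."""


@dataclass(frozen=True)
class HarmonicBand:
    """One rectangular spectral window around a carrier harmonic.

    ``order`` is the harmonic index (m, n) = (row multiple, col multiple);
    ``center_freq`` its centre in cycles/pixel; ``halfwidth_freq`` the
    half-open window half-width per axis.
    """

    order: tuple[int, int]
    center_freq: tuple[float, float]
    halfwidth_freq: float

    def __post_init__(self) -> None:
        if self.halfwidth_freq <= 0:
            raise ValueError("halfwidth_freq must be positive")
        for f in self.center_freq:
            if abs(f) > 0.5:
                raise ValueError(f"band centre {self.center_freq} beyond Nyquist")


def bands_for_pitch(pitch_px: tuple[float, float] | float) -> dict[tuple[int, int], HarmonicBand]:
    """Default band set: zero order plus the two first-order carriers.

    Half-width is 1/(2 pitch) per axis so adjacent bands touch but never
    overlap.  ``pitch_px`` may be a scalar or a (row, col) pair.
    """
    if np.isscalar(pitch_px):
        p_r = p_c = float(pitch_px)
    else:
        p_r, p_c = (float(p) for p in pitch_px)
    hw = 1.0 / (2.0 * max(p_r, p_c))
    return {
        (0, 0): HarmonicBand((0, 0), (0.0, 0.0), hw),
        (1, 0): HarmonicBand((1, 0), (1.0 / p_r, 0.0), hw),
        (0, 1): HarmonicBand((0, 1), (0.0, 1.0 / p_c), hw),
    }


def estimate_grid_frequency(reference: np.ndarray | Exposure) -> tuple[float, float]:
    """Locate the grid carriers from the reference spectrum alone.

    Returns the dominant non-DC peak frequency on each spectral axis
    (row frequency from the fc=0 column, column frequency from the fr=0 row),
    in cycles/pixel.  Ties break toward larger magnitude, then lower
    frequency.  Raises :class:`NoGridError` when no axis peak reaches 5x the
    spectral median.
    """
    img = np.asarray(reference, dtype=float)
    F = np.abs(np.fft.fft2(img))
    floor = 5.0 * np.median(F)

    def axis_peak(line: np.ndarray) -> float:
        n = line.size
        freqs = np.fft.fftfreq(n)
        mag = line.copy()
        mag[0] = 0.0  # exclude DC
        # tie-break: magnitude desc, then |frequency| asc
        order = np.lexsort((np.abs(freqs), -mag))
        best = order[0]
        if mag[best] <= floor:  # also catches the all-zero (uniform) spectrum
            raise NoGridError("no grid detected: no spectral peak >= 5x median")
        return abs(freqs[best])

    f_row = axis_peak(F[:, 0])
    f_col = axis_peak(F[0, :])
    return f_row, f_col


def extract_harmonic(image: np.ndarray | Exposure, band: HarmonicBand) -> np.ndarray:
    """Complex envelope of one spectral band at the original resolution.

    Crops the half-open square window [center - hw, center + hw) from the 2-D
    spectrum, re-centres it at DC (the remainder of the spectrum is
    zero-padded), and inverse-transforms.  The magnitude of the (0, 0) band is
    a plain low-pass of the image.
    """
    img = np.asarray(image, dtype=float)
    rows, cols = img.shape
    f_r, f_c = band.center_freq
    hw = band.halfwidth_freq
    if abs(f_r) + hw > 0.5 + 1e-12 or abs(f_c) + hw > 0.5 + 1e-12:
        raise ValueError(f"band {band.order} window extends beyond Nyquist")
    ci = int(round(f_r * rows))
    cj = int(round(f_c * cols))
    F = np.fft.fft2(img)
    F = np.roll(F, (-ci, -cj), axis=(0, 1))
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    mask = (fr >= -hw) & (fr < hw) & (fc >= -hw) & (fc < hw)
    return np.fft.ifft2(np.where(mask, F, 0.0))


@dataclass
class ReconstructionResult:
    """Absorption plus two directional scatter images from one exposure."""

    absorption: np.ndarray
    scatter_h: np.ndarray
    scatter_v: np.ndarray
    pitch_px: tuple[float, float]
    bands: dict[tuple[int, int], HarmonicBand] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorption.shape

    @property
    def margin_px(self) -> int:
        """Border width (one grid period) to exclude from statistics."""
        return int(np.ceil(max(self.pitch_px)))


def _resolve_pitch(
    sample: np.ndarray | Exposure,
    reference: np.ndarray | Exposure,
    pitch_px: float | tuple[float, float] | None,
    auto_pitch: bool,
) -> tuple[float, float]:
    if pitch_px is not None:
        return (pitch_px, pitch_px) if np.isscalar(pitch_px) else tuple(pitch_px)
    if auto_pitch:
        f_row, f_col = estimate_grid_frequency(reference)
        return 1.0 / f_row, 1.0 / f_col
    for exp in (sample, reference):
        if isinstance(exp, Exposure):
            return (exp.grid.pitch_px, exp.grid.pitch_px)
    raise ValueError("pitch_px not given and inputs carry no grid metadata "
                     "(pass pitch_px or auto_pitch=True)")


def reconstruct(
    sample: np.ndarray | Exposure,
    reference: np.ndarray | Exposure,
    pitch_px: float | tuple[float, float] | None = None,
    bands: dict[tuple[int, int], HarmonicBand] | None = None,
    auto_pitch: bool = False,
) -> ReconstructionResult:
    """Demodulate a sample exposure against a grid-only reference.

    Returns per-pixel absorption (-ln transmittance) and the horizontal and
    vertical scatter metrics.  The reference must show grid modulation
    (first-order envelope not vanishing) and a strictly positive zero-order
    envelope everywhere.
    """
    s = np.asarray(sample, dtype=float)
    r = np.asarray(reference, dtype=float)
    if s.shape != r.shape:
        raise ValueError(f"sample shape {s.shape} != reference shape {r.shape}")
    p = _resolve_pitch(sample, reference, pitch_px, auto_pitch)
    if bands is None:
        bands = bands_for_pitch(p)

    m00_r = np.abs(extract_harmonic(r, bands[(0, 0)]))
    if np.any(m00_r <= 0):
        raise FlatFieldError("reference zero-order envelope vanishes; "
                             "flat-field normalization impossible")
    m00_s = np.abs(extract_harmonic(s, bands[(0, 0)]))
    if np.any(m00_s <= 0):
        raise FlatFieldError("sample zero-order envelope vanishes")

    mv_r = np.abs(extract_harmonic(r, bands[(1, 0)]))  # row-frequency carrier
    mh_r = np.abs(extract_harmonic(r, bands[(0, 1)]))  # col-frequency carrier
    floor = 1e-6 * np.median(m00_r)
    if np.median(mv_r) < floor or np.median(mh_r) < floor:
        raise NoGridError("reference shows no first-harmonic modulation "
                          "(degenerate grid?)")
    mv_s = np.abs(extract_harmonic(s, bands[(1, 0)]))
    mh_s = np.abs(extract_harmonic(s, bands[(0, 1)]))

    with np.errstate(divide="ignore"):
        absorption = -np.log(m00_s / m00_r)
        scatter_h = -np.log((mh_s / m00_s) / (mh_r / m00_r))
        scatter_v = -np.log((mv_s / m00_s) / (mv_r / m00_r))
    return ReconstructionResult(
        absorption=absorption,
        scatter_h=scatter_h,
        scatter_v=scatter_v,
        pitch_px=p,
        bands=bands,
        meta={"auto_pitch": auto_pitch},
    )


def scatter_to_sigma(S: np.ndarray | float, f0: float) -> np.ndarray | float:
    """Invert the Gaussian damping model: sigma = sqrt(S / (2 pi^2 f0^2)).

    Negative scatter values (noise) are clipped to zero; a warning reports
    how many pixels were clipped.
    """
    arr = np.asarray(S, dtype=float)
    n_neg = int(np.sum(arr < 0))
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative scatter values to 0", stacklevel=2)
    clipped = np.clip(arr, 0.0, None)
    sigma = np.sqrt(clipped / (2.0 * np.pi**2 * f0**2))
    return float(sigma) if np.isscalar(S) else sigma


def interior(image: np.ndarray, margin_px: int) -> np.ndarray:
    """View of the image with the wrap-around border stripped."""
    m = int(margin_px)
    if m <= 0:
        return image
    if 2 * m >= min(image.shape):
        raise ValueError(f"margin {m} px leaves no interior for shape {image.shape}")
    return image[m:-m, m:-m]
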