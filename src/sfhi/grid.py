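"""Absorption-grid model: the crossed wire mesh that imprints spatial-frequency
carriers on the x-ray beam.

The mesh is an ideal binary crossed grid: wire bands of width ``duty * pitch_px``
run along both detector axes, centred on integer multiples of the pitch.  A ray
through an open cell is transmitted with ``open_transmission``; a ray through a
wire (one axis or both) is transmitted with ``wire_transmission``.  Pixels are
rendered with exact fractional wire coverage so sub-pixel wire widths do not
alias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "GridError", "make_grid_image"]


class GridError(ValueError):
    """Invalid grid parameters or a grid unusable for harmonic analysis."""


@dataclass(frozen=True)
class GridSpec:
    """Crossed absorption mesh, in detector-pixel units.

    Parameters
    ----------
    pitch_px:
        Grid period in detector pixels (at the detector plane, i.e. after
        geometric magnification). Must be >= 4 so the first harmonics lie
        below Nyquist.
    duty:
        Fraction of each period occupied by wire, per axis. ``0`` is the
        degenerate no-wire grid (useful for null tests); must be < 1.
    open_transmission:
        Transmission of open cells, in (0, 1].
    wire_transmission:
        Transmission under a wire, in (0, open_transmission).
    orientation_deg:
        Rotation of the mesh axes relative to detector rows. Default 0.
    """

    pitch_px: float = 8.0
    duty: float = 0.05
    open_transmission: float = 0.95
    wire_transmission: float = 0.05
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.pitch_px >= 4.0:
            raise GridError(
                f"pitch_px={self.pitch_px}: first harmonic above Nyquist "
                "(pitch must be >= 4 pixels)"
            )
        if not (0.0 <= self.duty < 1.0):
            raise GridError(f"duty={self.duty} outside [0, 1)")
        if not (0.0 < self.open_transmission <= 1.0):
            raise GridError(f"open_transmission={self.open_transmission} outside (0, 1]")
        if not (0.0 < self.wire_transmission < self.open_transmission):
            raise GridError(
                "require 0 < wire_transmission < open_transmission, got "
                f"{self.wire_transmission} vs {self.open_transmission}"
            )

    @property
    def fundamental_freq(self) -> float:
        """Carrier frequency 1/pitch, in cycles/pixel."""
        return 1.0 / self.pitch_px

    @property
    def mean_transmission(self) -> float:
        """Duty-weighted mix: wire + (open - wire) * (1 - duty)^2.

        The open-cell area fraction of a crossed mesh is (1 - duty) per axis,
        squared for the two axes.
        """
        o, w, d = self.open_transmission, self.wire_transmission, self.duty
        return w + (o - w) * (1.0 - d) ** 2


def _wire_coverage(coords: np.ndarray, pitch: float, width: float) -> np.ndarray:
    """Fraction of each unit pixel [c, c+1) covered by wire bands.

    Bands of the given width are centred on integer multiples of the pitch.
    Exact (analytic) coverage, valid for sub-pixel widths and real pitches.
    """
    if width <= 0.0:
        return np.zeros_like(coords, dtype=float)

    def cum(x: np.ndarray) -> np.ndarray:
        # total wire length in [band-aligned origin, x)
        n, r = np.divmod(x, pitch)
        return n * width + np.clip(r, 0.0, width)

    half = width / 2.0
    return cum(coords + 1.0 + half) - cum(coords + half)


def make_grid_image(grid: GridSpec, shape: tuple[int, int]) -> np.ndarray:
    """Noise-free transmission field T(x, y) of the grid alone.

    Values lie in [wire_transmission, open_transmission]; the spatial mean over
    an integer number of periods equals ``grid.mean_transmission``.  The 2-D
    spectrum carries its dominant non-DC peaks at +-1/pitch_px cycles/pixel on
    each mesh axis.
    """
    rows, cols = shape
    if rows < 4 * grid.pitch_px or cols < 4 * grid.pitch_px:
        raise GridError(
            f"shape {shape} smaller than 4 grid periods (pitch {grid.pitch_px} px)"
        )
    o, w = grid.open_transmission, grid.wire_transmission
    width = grid.duty * grid.pitch_px

    if grid.orientation_deg % 360.0 == 0.0:
        cov_r = _wire_coverage(np.arange(rows, dtype=float), grid.pitch_px, width)
        cov_c = _wire_coverage(np.arange(cols, dtype=float), grid.pitch_px, width)
        open_frac = np.outer(1.0 - cov_r, 1.0 - cov_c)
        return w + (o - w) * open_frac

    # rotated mesh: 3x3 supersampled binary indicator (coverage is no longer
    # separable in detector coordinates)
    theta = np.deg2rad(grid.orientation_deg)
    ss = 3
    offs = (np.arange(ss) + 0.5) / ss
    acc = np.zeros(shape, dtype=float)
    half = width / 2.0
    rr = np.arange(rows, dtype=float)[:, None]
    cc = np.arange(cols, dtype=float)[None, :]
    for dr in offs:
        for dc in offs:
            y = rr + dr
            x = cc + dc
            u = x * np.cos(theta) + y * np.sin(theta)
            v = -x * np.sin(theta) + y * np.cos(theta)
            wire_u = np.mod(u + half, grid.pitch_px) < width
            wire_v = np.mod(v + half, grid.pitch_px) < width
            acc += np.where(wire_u | wire_v, w, o)
    return acc / (ss * ss)
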