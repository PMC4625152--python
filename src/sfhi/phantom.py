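"""Digital tissue phantoms: per-pixel attenuation and gold-concentration maps.

A phantom is a pair of rasters over the detector grid: the attenuation optical
depth A(x, y) (Beer-Lambert line integral, dimensionless) and the local gold
concentration c(x, y) in ug/cm^3.  Small-angle scattering by gold nanoparticles
blurs the grid shadow; the blur variance is taken linear in concentration,
sigma^2(x, y) = k * c(x, y), with k the scatter coupling in px^2 per ug/cm^3.
Phantoms are built from named elliptical regions (body, liver, tumors) whose
optical-depth contributions add where they overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

__all__ = ["EllipseRegion", "Phantom", "PhantomError", "make_mouse_phantom", "demo_mouse"]

#: default blur-variance per unit gold concentration, px^2 per (ug/cm^3);
#: puts the 18-26 ug/cm^3 range of tumor labelling at sigma ~ 0.9-1.1 px.
DEFAULT_SCATTER_COUPLING = 0.05


class PhantomError(ValueError):
    """Invalid phantom description."""


@dataclass(frozen=True)
class EllipseRegion:
    """Named elliptical region with its physics contributions.

    center/axes are (row, col) pixel coordinates; ``optical_depth`` is the
    additive attenuation contribution inside the ellipse and ``gold_ugcm3``
    the gold concentration assigned there.
    """

    name: str
    center: tuple[float, float]
    axes: tuple[float, float]
    angle_deg: float = 0.0
    optical_depth: float = 0.0
    gold_ugcm3: float = 0.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = _draw_ellipse(
            self.center[0],
            self.center[1],
            self.axes[0],
            self.axes[1],
            shape=shape,
            rotation=np.deg2rad(self.angle_deg),
        )
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center"] = list(self.center)
        d["axes"] = list(self.axes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseRegion":
        return cls(
            name=d["name"],
            center=tuple(d["center"]),
            axes=tuple(d["axes"]),
            angle_deg=float(d.get("angle_deg", 0.0)),
            optical_depth=float(d.get("optical_depth", 0.0)),
            gold_ugcm3=float(d.get("gold_ugcm3", 0.0)),
        )


@dataclass
class Phantom:
    """Per-pixel optical depth and gold map plus region bookkeeping."""

    optical_depth: np.ndarray
    gold_map: np.ndarray
    scatter_coupling: float = DEFAULT_SCATTER_COUPLING
    regions: dict[str, EllipseRegion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.optical_depth = np.asarray(self.optical_depth, dtype=float)
        self.gold_map = np.asarray(self.gold_map, dtype=float)
        if self.optical_depth.shape != self.gold_map.shape:
            raise PhantomError("optical_depth and gold_map shapes differ")
        if np.any(self.optical_depth < 0):
            raise PhantomError("optical_depth must be nonnegative")
        if np.any(self.gold_map < 0):
            raise PhantomError("gold_map must be nonnegative")
        if not self.scatter_coupling >= 0:
            raise PhantomError("scatter_coupling must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.optical_depth.shape

    @property
    def sigma_map(self) -> np.ndarray:
        """Scatter blur RMS width sigma(x, y) = sqrt(k * c(x, y)), pixels."""
        return np.sqrt(self.scatter_coupling * self.gold_map)


def make_mouse_phantom(
    shape: tuple[int, int],
    regions: list[EllipseRegion],
    scatter_coupling: float = DEFAULT_SCATTER_COUPLING,
    edge_sigma_px: float = 0.0,
) -> Phantom:
    """Build a phantom by stacking elliptical regions on an empty canvas.

    Optical depth is the sum of overlapping ellipse contributions; the gold
    map likewise accumulates per-region concentrations, so it is nonzero only
    inside designated regions.  Every ellipse must lie fully inside the canvas.

    ``edge_sigma_px`` optionally softens tissue boundaries with a Gaussian of
    that width.  Pixel-sharp steps are below the resolution of grid-based
    scatter imaging and their broadband spectra leak into the carrier bands,
    producing ringing artifacts in the reconstructions; a few pixels of edge
    softening emulates the finite sharpness of real tissue boundaries.
    With the default 0 the maps are exact indicator sums (region maxima equal
    the configured concentrations).
    """
    rows, cols = shape
    od = np.zeros(shape, dtype=float)
    gold = np.zeros(shape, dtype=float)
    named: dict[str, EllipseRegion] = {}
    for reg in regions:
        if reg.gold_ugcm3 < 0:
            raise PhantomError(f"region {reg.name!r}: negative gold concentration")
        if reg.optical_depth < 0:
            raise PhantomError(f"region {reg.name!r}: negative optical depth")
        r0, c0 = reg.center
        ar, ac = reg.axes
        extent = max(ar, ac)  # conservative bound for rotated ellipses
        if r0 - extent < 0 or r0 + extent > rows - 1 or c0 - extent < 0 or c0 + extent > cols - 1:
            raise PhantomError(f"region {reg.name!r} extends outside the canvas")
        m = reg.mask(shape)
        if not m.any():
            raise PhantomError(f"region {reg.name!r} rasterizes to zero pixels")
        od[m] += reg.optical_depth
        gold[m] += reg.gold_ugcm3
        named[reg.name] = reg
    if edge_sigma_px > 0:
        od = gaussian_filter(od, edge_sigma_px)
        gold = gaussian_filter(gold, edge_sigma_px)
    return Phantom(od, gold, scatter_coupling=scatter_coupling, regions=named)


def demo_mouse(shape: tuple[int, int] = (256, 256),
               scatter_coupling: float = DEFAULT_SCATTER_COUPLING) -> Phantom:
    """Small nanoparticle-labelled mouse stand-in used by examples and the demo
    pipeline: a soft-tissue body, a liver with background uptake, and two
    subcutaneous tumors at the concentrations typical of targeted labelling."""
    regions = [
        EllipseRegion("body", center=(128, 128), axes=(110, 85), optical_depth=0.4),
        EllipseRegion("liver", center=(100, 100), axes=(28, 38),
                      optical_depth=0.2, gold_ugcm3=8.0),
        EllipseRegion("tumor_1", center=(170, 160), axes=(14, 14),
                      optical_depth=0.05, gold_ugcm3=26.0),
        EllipseRegion("tumor_2", center=(90, 175), axes=(12, 12),
                      optical_depth=0.05, gold_ugcm3=18.0),
    ]
    if shape != (256, 256):
        sr, sc = shape[0] / 256.0, shape[1] / 256.0
        regions = [
            EllipseRegion(r.name, (r.center[0] * sr, r.center[1] * sc),
                          (r.axes[0] * sr, r.axes[1] * sc), r.angle_deg,
                          r.optical_depth, r.gold_ugcm3)
            for r in regions
        ]
    return make_mouse_phantom(shape, regions, scatter_coupling=scatter_coupling,
                              edge_sigma_px=2.0)
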