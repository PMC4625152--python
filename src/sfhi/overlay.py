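"""Dual-modality rendering: color-mapped scatter over grayscale absorption.

Scatter pixels at or below the transparency threshold show the plain
grayscale absorption image; above it, the color-mapped scatter value is
alpha-blended in.  The grayscale channel is min-max normalized per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

__all__ = ["OverlaySpec", "overlay"]


@dataclass(frozen=True)
class OverlaySpec:
    colormap: str = "magma"  # perceptually uniform sequential default
    scatter_range: tuple[float, float] | None = None  # (lo, hi); None -> min/max
    alpha: float = 0.5
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha {self.alpha} outside [0, 1]")
        if self.scatter_range is not None and not self.scatter_range[0] < self.scatter_range[1]:
            raise ValueError(f"scatter_range {self.scatter_range}: need lo < hi")


def _normalize(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def overlay(absorption: np.ndarray, scatter: np.ndarray, spec: OverlaySpec = OverlaySpec()) -> np.ndarray:
    """RGB composite, channels in [0, 1], same height/width as the inputs."""
    a = np.asarray(absorption, dtype=float)
    s = np.asarray(scatter, dtype=float)
    if a.shape != s.shape:
        raise ValueError(f"absorption shape {a.shape} != scatter shape {s.shape}")

    gray = _normalize(a, a.min(), a.max())
    rgb = np.stack([gray, gray, gray], axis=-1)

    lo, hi = spec.scatter_range if spec.scatter_range is not None else (s.min(), s.max())
    cmap = matplotlib.colormaps[spec.colormap]
    colored = cmap(_normalize(s, lo, hi))[..., :3]

    mask = s > spec.threshold
    out = rgb.copy()
    out[mask] = (1.0 - spec.alpha) * rgb[mask] + spec.alpha * colored[mask]
    return np.clip(out, 0.0, 1.0)
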