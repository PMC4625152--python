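"""ROI statistics and contrast-agent uptake arithmetic.

Covers the figures of merit used to report nanoparticle labelling: percent
signal enhancement of a target region over a control, integrated optical
density (IOD) of stain channels with its enhancement factor, ratio tables of
gold masses/concentrations against a reference entry, and per-organ
biodistribution summaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "ROI",
    "RoiStats",
    "EnhancementResult",
    "RatioTable",
    "roi_stats",
    "signal_enhancement",
    "iod",
    "enhancement_factor",
    "report_factor",
    "ratio_table",
    "biodistribution_summary",
]


@dataclass(frozen=True)
class ROI:
    """Region of interest: a (possibly rotated) ellipse or an explicit mask.

    ``role`` distinguishes the measured target from its control; which tissue
    serves as control is a per-image choice and therefore user-specified.
    """

    name: str
    center: tuple[float, float] | None = None  # (row, col)
    axes: tuple[float, float] | None = None
    angle_deg: float = 0.0
    pixel_mask: np.ndarray | None = None
    role: str = "target"  # "target" | "control"

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.pixel_mask is not None:
            m = np.asarray(self.pixel_mask, dtype=bool)
            if m.shape != shape:
                raise ValueError(f"ROI {self.name!r} mask shape {m.shape} != {shape}")
            return m
        if self.center is None or self.axes is None:
            raise ValueError(f"ROI {self.name!r}: neither ellipse nor mask given")
        rr, cc = _draw_ellipse(
            self.center[0], self.center[1], self.axes[0], self.axes[1],
            shape=shape, rotation=np.deg2rad(self.angle_deg),
        )
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        kind = d.get("type", "ellipse")
        if kind == "ellipse":
            return cls(
                name=d["name"],
                center=tuple(d["center"]),
                axes=tuple(d["axes"]),
                angle_deg=float(d.get("angle_deg", 0.0)),
                role=d.get("role", "target"),
            )
        if kind == "mask":
            return cls(
                name=d["name"],
                pixel_mask=np.asarray(d["mask"], dtype=bool),
                role=d.get("role", "target"),
            )
        raise ValueError(f"unknown ROI type {kind!r}")

    @classmethod
    def list_from_json(cls, path) -> list["ROI"]:
        with open(path) as fh:
            return [cls.from_dict(d) for d in json.load(fh)]


@dataclass(frozen=True)
class RoiStats:
    mean: float
    sd: float
    n: int


def roi_stats(image: np.ndarray, roi: ROI) -> RoiStats:
    """Arithmetic mean and sample SD (ddof=1) over the rasterized ROI."""
    img = np.asarray(image, dtype=float)
    m = roi.mask(img.shape)
    n = int(m.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.name!r} is empty after rasterization")
    vals = img[m]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RoiStats(mean=float(vals.mean()), sd=sd, n=n)


@dataclass(frozen=True)
class EnhancementResult:
    """Percent signal enhancement of a target ROI over a control ROI."""

    target_mean: float
    control_mean: float
    enhancement_pct: float
    target_sd: float
    control_sd: float
    n_target: int
    n_control: int


def signal_enhancement(image: np.ndarray, target: ROI, control: ROI) -> EnhancementResult:
    """enhancement_pct = 100 * (target_mean - control_mean) / control_mean."""
    t = roi_stats(image, target)
    c = roi_stats(image, control)
    if abs(c.mean) < 1e-12:
        raise ZeroDivisionError(
            f"control ROI {control.name!r} mean ~ 0: enhancement undefined"
        )
    pct = 100.0 * (t.mean - c.mean) / c.mean
    return EnhancementResult(
        target_mean=t.mean, control_mean=c.mean, enhancement_pct=pct,
        target_sd=t.sd, control_sd=c.sd, n_target=t.n, n_control=c.n,
    )


def iod(micrograph: np.ndarray, threshold: float = 0.0) -> float:
    """Integrated optical density: sum of (I - threshold) over pixels I > threshold.

    The background-subtracted sum captures both the stained area and its
    brightness; it is nondecreasing in either and nonincreasing in the
    threshold.  An empty above-threshold set gives 0.
    """
    img = np.asarray(micrograph, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    excess = img - threshold
    return float(excess[excess > 0].sum())


def enhancement_factor(target_iod: float, control_iods: list[float]) -> float:
    """Target IOD over the mean of the control IODs."""
    if not control_iods:
        raise ValueError("need at least one control IOD")
    if any(c <= 0 for c in control_iods):
        raise ValueError("control IODs must be positive")
    return float(target_iod) / (sum(control_iods) / len(control_iods))


def report_factor(factor: float) -> int:
    """Round a factor to the nearest integer for reporting."""
    return int(round(factor))


@dataclass
class RatioTable:
    """Measurements normalized to a reference entry.

    Ratios are kept at full precision; :meth:`display` rounds to 2 decimals.
    Uncertainties, when given, propagate in quadrature on the relative scale.
    If a paired second compartment is supplied (e.g. the liver matching each
    tumor), per-item cross-compartment ratios are computed as well.
    """

    labels: list[str]
    values: dict[str, float]
    reference: str
    sds: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    ratio_sds: dict[str, float] = field(default_factory=dict)
    paired_values: dict[str, float] = field(default_factory=dict)
    cross_ratios: dict[str, float] = field(default_factory=dict)

    def display(self) -> dict[str, float]:
        return {k: round(v, 2) for k, v in self.ratios.items()}

    def display_cross(self) -> dict[str, float]:
        return {k: round(v, 2) for k, v in self.cross_ratios.items()}


def ratio_table(
    measurements: dict[str, float],
    reference_label: str,
    sds: dict[str, float] | None = None,
    paired_compartment: dict[str, float] | None = None,
) -> RatioTable:
    """Build a ratio table against a named reference measurement."""
    if reference_label not in measurements:
        raise KeyError(f"reference label {reference_label!r} not in measurements")
    if any(v <= 0 for v in measurements.values()):
        raise ValueError("all measurements must be positive")
    sds = sds or {}
    ref = measurements[reference_label]
    ref_sd = sds.get(reference_label, 0.0)
    ratios = {k: v / ref for k, v in measurements.items()}
    ratio_sds = {}
    for k, v in measurements.items():
        s = sds.get(k, 0.0)
        ratio_sds[k] = ratios[k] * math.hypot(s / v, ref_sd / ref)
    cross = {}
    paired = dict(paired_compartment or {})
    for k, pv in paired.items():
        if k in measurements:
            if pv <= 0:
                raise ValueError(f"paired value for {k!r} must be positive")
            cross[k] = measurements[k] / pv
    return RatioTable(
        labels=list(measurements),
        values=dict(measurements),
        reference=reference_label,
        sds=dict(sds),
        ratios=ratios,
        ratio_sds=ratio_sds,
        paired_values=paired,
        cross_ratios=cross,
    )


def biodistribution_summary(
    per_organ_masses: dict[str, list[float]],
    reference_organ: str = "liver",
) -> dict:
    """Per-organ mean uptake and reference-organ-to-organ factors.

    Means are taken across the injected animals for each organ; factors are
    reference mean / organ mean, reported raw and rounded.  A zero organ mean
    yields an infinity marker rather than an exception.
    """
    if len(per_organ_masses) < 2:
        raise ValueError("need at least two organs")
    if reference_organ not in per_organ_masses:
        raise KeyError(f"reference organ {reference_organ!r} missing")
    means = {k: float(np.mean(v)) for k, v in per_organ_masses.items()}
    ref = means[reference_organ]
    factors = {}
    factors_rounded = {}
    for k, m in means.items():
        if m == 0.0:
            factors[k] = math.inf
            factors_rounded[k] = math.inf
        else:
            factors[k] = ref / m
            factors_rounded[k] = int(round(ref / m))
    return {"means": means, "factors": factors, "factors_rounded": factors_rounded,
            "reference": reference_organ}
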