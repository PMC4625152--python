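"""YAML run configuration: grid, geometry, acquisition, phantom regions, ROIs.

The serialized config plus its seed fully determines every output byte of a
simulate/reconstruct run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquire import AcquisitionSettings, Geometry
from .grid import GridSpec
from .overlay import OverlaySpec
from .phantom import DEFAULT_SCATTER_COUPLING, EllipseRegion
from .quantify import ROI

__all__ = ["RunConfig", "ConfigError", "load_config", "parse_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    image_shape: tuple[int, int]
    grid: GridSpec
    geometry: Geometry
    acquisition: AcquisitionSettings
    regions: list[EllipseRegion] = field(default_factory=list)
    scatter_coupling: float = DEFAULT_SCATTER_COUPLING
    edge_sigma_px: float = 0.0
    rois: list[ROI] = field(default_factory=list)
    overlay: OverlaySpec = field(default_factory=OverlaySpec)
    raw: dict = field(default_factory=dict)


_KNOWN_TOP = {"image_shape", "grid", "geometry", "acquisition", "phantom", "rois", "overlay"}


def _section(data: dict, name: str) -> dict:
    sec = data.get(name, {})
    if not isinstance(sec, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    return sec


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    shape = data.get("image_shape", [256, 256])
    if len(shape) != 2 or any(int(s) <= 0 for s in shape):
        raise ConfigError(f"image_shape must be two positive ints, got {shape}")
    shape = (int(shape[0]), int(shape[1]))

    try:
        grid = GridSpec(**_section(data, "grid"))
        geometry = Geometry(**_section(data, "geometry"))
        acq_sec = _section(data, "acquisition")
        acquisition = AcquisitionSettings(
            fluence=float(acq_sec.get("fluence", 1.0e4)),
            rng_seed=int(acq_sec.get("seed", 0)),
            noise_enabled=bool(acq_sec.get("noise", True)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    phant = _section(data, "phantom")
    regions = [EllipseRegion.from_dict(d) for d in phant.get("regions", [])]
    coupling = float(phant.get("scatter_coupling", DEFAULT_SCATTER_COUPLING))
    edge_sigma = float(phant.get("edge_sigma_px", 0.0))

    rois = [ROI.from_dict(d) for d in data.get("rois", [])]
    ov_sec = _section(data, "overlay")
    ov_kwargs = {}
    if "colormap" in ov_sec:
        ov_kwargs["colormap"] = str(ov_sec["colormap"])
    if "alpha" in ov_sec:
        ov_kwargs["alpha"] = float(ov_sec["alpha"])
    if "threshold" in ov_sec:
        ov_kwargs["threshold"] = float(ov_sec["threshold"])
    if "scatter_range" in ov_sec:
        ov_kwargs["scatter_range"] = tuple(ov_sec["scatter_range"])
    overlay_spec = OverlaySpec(**ov_kwargs)

    return RunConfig(
        image_shape=shape,
        grid=grid,
        geometry=geometry,
        acquisition=acquisition,
        regions=regions,
        scatter_coupling=coupling,
        edge_sigma_px=edge_sigma,
        rois=rois,
        overlay=overlay_spec,
        raw=data,
    )


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data or {})
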