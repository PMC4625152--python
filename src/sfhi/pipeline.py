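"""End-to-end run: simulate -> reconstruct -> quantify -> overlay.

All randomness flows from the single config seed; re-running an identical
config reproduces every output byte, which the manifest records as SHA-256
hashes.  Artifacts of a failing stage are removed; earlier stages' outputs
are preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .acquire import AcquisitionSettings, simulate_acquisition, simulate_reference
from .config import RunConfig
from .demodulate import reconstruct
from .imgio import write_image, sidecar_path
from .overlay import overlay as render_overlay
from .phantom import make_mouse_phantom
from .quantify import signal_enhancement

log = logging.getLogger("sfhi.pipeline")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_all(paths: list[Path]) -> dict[str, str]:
    out = {}
    for p in paths:
        out[p.name] = _sha256(p)
        sc = sidecar_path(p)
        if sc.exists():
            out[sc.name] = _sha256(sc)
    return out


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> Path:
    """Run the full pipeline into ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = config.acquisition
    if seed is not None:
        acq = AcquisitionSettings(acq.fluence, int(seed), acq.noise_enabled)

    written: list[Path] = []

    def emit(arr: np.ndarray, name: str) -> Path:
        p = write_image(arr, out / name)
        written.append(p)
        return p

    stage = "simulate"
    stage_start = 0
    try:
        phantom = make_mouse_phantom(config.image_shape, config.regions,
                                     scatter_coupling=config.scatter_coupling,
                                     edge_sigma_px=config.edge_sigma_px)
        reference = simulate_reference(config.grid, config.image_shape,
                                       config.geometry, acq)
        sample = simulate_acquisition(phantom, config.grid, config.geometry, acq)
        emit(reference.pixels, "reference.tiff")
        emit(sample.pixels, "sample.tiff")
        log.info("simulate: shape=%s fluence=%g seed=%d noise=%s",
                 config.image_shape, acq.fluence, acq.rng_seed, acq.noise_enabled)

        stage, stage_start = "reconstruct", len(written)
        recon = reconstruct(sample, reference)
        emit(recon.absorption, "absorption.tiff")
        emit(recon.scatter_h, "scatter_h.tiff")
        emit(recon.scatter_v, "scatter_v.tiff")
        log.info("reconstruct: pitch_px=%s margin_px=%d", recon.pitch_px, recon.margin_px)

        stage, stage_start = "quantify", len(written)
        quant: dict = {}
        targets = [r for r in config.rois if r.role == "target"]
        controls = [r for r in config.rois if r.role == "control"]
        if targets and controls:
            control = controls[0]
            for roi in targets:
                quant[roi.name] = {
                    img_name: dataclasses.asdict(
                        signal_enhancement(img, roi, control))
                    for img_name, img in (
                        ("absorption", recon.absorption),
                        ("scatter_h", recon.scatter_h),
                        ("scatter_v", recon.scatter_v),
                    )
                }
            log.info("quantify: %d target ROI(s) vs control %r",
                     len(targets), control.name)
        qpath = out / "quantify.json"
        qpath.write_text(json.dumps(quant, indent=2))
        written.append(qpath)

        stage, stage_start = "overlay", len(written)
        rgb = render_overlay(recon.absorption, recon.scatter_h, config.overlay)
        opath = out / "overlay.png"
        from imageio.v3 import imwrite
        imwrite(opath, (rgb * 255).astype(np.uint8))
        written.append(opath)
        log.info("overlay: colormap=%s alpha=%g threshold=%g",
                 config.overlay.colormap, config.overlay.alpha, config.overlay.threshold)
    except Exception:
        # drop partial outputs of the failing stage; keep earlier stages'
        for p in written[stage_start:]:
            p.unlink(missing_ok=True)
            sidecar_path(p).unlink(missing_ok=True)
        log.error("pipeline failed during stage %r", stage)
        raise

    manifest = {
        "version": __version__,
        "seed": acq.rng_seed,
        "config": config.raw,
        "hashes": _hash_all(written),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath
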