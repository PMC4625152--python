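"""Raster I/O: 16-bit grayscale TIFF/PNG with a JSON sidecar for float data.

Integer rasters that fit in 16 bits round-trip exactly under scale "none".
Float rasters (reconstructions, scatter maps) are affinely quantized to
uint16; the scale and offset are recorded in ``<path>.json`` so reading
restores physical values to within half a quantization step.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["write_image", "read_image", "sidecar_path", "UnsupportedFormatError"]

_TIFF = {".tif", ".tiff"}
_PNG = {".png"}


class UnsupportedFormatError(ValueError):
    pass


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_raster(arr: np.ndarray, path: Path) -> None:
    if path.suffix.lower() in _TIFF:
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() in _PNG:
        iio.imwrite(path, arr)
    else:
        raise UnsupportedFormatError(
            f"unsupported image format {path.suffix!r} (use TIFF or PNG)"
        )


def write_image(raster: np.ndarray, path, scale: str = "auto") -> Path:
    """Write a 2-D raster as 16-bit grayscale with a JSON sidecar.

    scale="none" requires integer-valued data in [0, 65535] and stores it
    bit-exactly.  scale="auto" does the same when possible and otherwise
    applies an affine uint16 quantization recorded in the sidecar.
    """
    path = Path(path)
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {arr.shape}")

    integral = np.issubdtype(arr.dtype, np.integer) or np.all(arr == np.round(arr))
    fits = arr.size > 0 and arr.min() >= 0 and arr.max() <= 65535

    if scale == "none":
        if not (integral and fits):
            raise ValueError('scale="none" requires integer values in [0, 65535]')
        meta = {"scale": 1.0, "offset": 0.0, "lossless": True}
        _write_raster(arr.astype(np.uint16), path)
    elif scale == "auto":
        if integral and fits:
            meta = {"scale": 1.0, "offset": 0.0, "lossless": True}
            _write_raster(arr.astype(np.uint16), path)
        else:
            offset = float(arr.min())
            span = float(arr.max()) - offset
            factor = span / 65535.0 if span > 0 else 1.0
            quant = np.round((arr - offset) / factor).astype(np.uint16)
            meta = {"scale": factor, "offset": offset, "lossless": False}
            _write_raster(quant, path)
    else:
        raise ValueError(f"unknown scale policy {scale!r}")

    meta["shape"] = list(arr.shape)
    sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_image(path, require_sidecar: bool = False) -> tuple[np.ndarray, dict]:
    """Read a raster written by :func:`write_image`.

    Returns (array, sidecar metadata).  With a sidecar, physical values are
    restored as raw * scale + offset; lossless writes come back as the stored
    integers.  ``require_sidecar=True`` raises if the sidecar is missing
    (mandatory when reading float data whose scale cannot be guessed).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF:
        raw = tifffile.imread(path)
    elif suffix in _PNG:
        raw = iio.imread(path)
    else:
        raise UnsupportedFormatError(
            f"unsupported image format {path.suffix!r} (use TIFF or PNG)"
        )

    sc = sidecar_path(path)
    if not sc.exists():
        if require_sidecar:
            raise FileNotFoundError(
                f"missing sidecar {sc}: cannot restore float scale for {path}"
            )
        return raw, {}
    meta = json.loads(sc.read_text())
    if meta.get("lossless", False):
        return raw, meta
    return raw.astype(float) * meta["scale"] + meta["offset"], meta
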