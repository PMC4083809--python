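"""Image, mask, trace and config I/O.

Conventions: images load as float64 in [0, 1] (integers divided by their
dtype max; floats validated or min-max rescaled with a warning; RGB reduced
to luminance with a warning).  Masks are 8-bit PNGs with values {0, 255};
level-set fields and phantom images are float32 TIFFs; energy traces are
CSVs with header ``iteration,total,global,local_printed,local_residual,length``.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError
from .evolve import EnergyRecord

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "save_phi",
    "load_phi",
    "save_trace",
    "load_config",
]

TRACE_COLUMNS = ("iteration", "total", "global", "local_printed", "local_residual", "length")


def load_image(path) -> np.ndarray:
    """Load a grayscale image as float64 in [0, 1]."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ConfigurationError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ConfigurationError(f"image {path} is empty")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: RGB input converted to luminance")
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if arr.ndim != 2:
        raise ConfigurationError(f"image {path} is not 2-D (shape {arr.shape})")
    lo, hi = float(arr.min()), float(arr.max())
    if lo < 0.0 or hi > 1.0:
        warnings.warn(f"{path.name}: float values outside [0,1]; min-max rescaled")
        arr = (arr - lo) / max(hi - lo, 1e-12)
    if hi == lo:
        warnings.warn(f"{path.name}: zero-variance image")
    return arr


def save_image(path, image: np.ndarray) -> None:
    """Write a float image as float32 TIFF (or 8-bit PNG by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        iio.imwrite(path, np.clip(np.asarray(image) * 255, 0, 255).astype(np.uint8))


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (np.iinfo(arr.dtype).max // 2 if np.issubdtype(arr.dtype, np.integer) else 0.5)


def save_phi(path, phi: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(phi, dtype=np.float32))


def load_phi(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.float64)


def save_trace(path, records: list[EnergyRecord]) -> None:
    with open(Path(path), "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=TRACE_COLUMNS)
        w.writeheader()
        for rec in records:
            w.writerow(rec.as_dict())


def load_config(path) -> dict:
    """Read a YAML parameter mapping (CLI override file)."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return cfg
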