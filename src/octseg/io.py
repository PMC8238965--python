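"""Raster I/O helpers.

All images are handled internally as float64 arrays in [0, 1] (grayscale)
or {0, 1} (masks). On disk, images and masks are 8-bit grayscale PNG/TIFF
(mask convention: 0 = background, 255 = edema); probability maps are
32-bit float TIFF with one channel per class plus a JSON sidecar recording
the class order.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

CLASS_ORDER = ["background", "edema"]


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale image as float in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) by luminance-free mean
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr /= 255.0 if arr.max() <= 255 else 65535.0
    return np.clip(arr, 0.0, 1.0)


def write_gray(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (np.round(arr * 255.0)).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (0 background / 255 edema) as a {0,1} uint8 array."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask) > 0, 255, 0).astype(np.uint8))


def write_proba(path: str | Path, proba: np.ndarray) -> None:
    """Write an (H, W, C) probability map as float32 TIFF + class-order sidecar."""
    proba = np.asarray(proba, dtype=np.float32)
    if proba.ndim != 3:
        raise ValueError(f"probability map must be (H, W, C), got {proba.shape}")
    tifffile.imwrite(path, proba)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    sidecar.write_text(json.dumps({"classes": CLASS_ORDER[: proba.shape[-1]]}))


def read_proba(path: str | Path) -> np.ndarray:
    proba = tifffile.imread(path).astype(np.float64)
    if proba.ndim != 3:
        raise ValueError(f"probability map must be (H, W, C), got {proba.shape}")
    return proba
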