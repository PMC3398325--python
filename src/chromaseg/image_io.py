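"""Raster input/output with explicit mask-encoding conventions.

Images are plain :class:`numpy.ndarray` objects throughout the package:

* RGB image — ``(H, W, 3)`` array of ``uint8``;
* intensity channel — ``(H, W)`` array of ``uint8``;
* binary mask — ``(H, W)`` array of ``bool``, ``True`` = foreground.

Coordinates are row-major with the origin at the top-left, 0-based.
Masks are written losslessly (PNG or TIFF, never JPEG) because the
downstream evaluation is per-pixel.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ImageReadError, ImageWriteError

__all__ = ["read_rgb_image", "read_mask", "write_mask"]

_LOSSLESS_SUFFIXES = {".png", ".tif", ".tiff"}


def _read_array(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    return np.asarray(arr)


def _to_uint8(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr >> 8).astype(np.uint8)
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    raise ImageReadError(f"unsupported pixel type {arr.dtype} in {path}")


def read_rgb_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as an 8-bit RGB array.

    Grayscale files are replicated to three channels; an alpha channel,
    if present, is dropped.

    Parameters
    ----------
    path
        Image file (JPEG, PNG or TIFF).

    Returns
    -------
    numpy.ndarray
        ``(H, W, 3)`` array of ``uint8``.

    Raises
    ------
    ImageReadError
        If the file is missing, truncated or otherwise undecodable.
    """
    arr = _to_uint8(_read_array(path), Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ImageReadError(f"unexpected image shape {arr.shape} in {path}")
    return np.ascontiguousarray(arr)


def read_mask(path: str | os.PathLike, threshold: int = 128) -> np.ndarray:
    """Read a ground-truth or prediction mask.

    Multi-channel files are averaged across channels before
    thresholding; a pixel is foreground iff its (averaged) value is
    ``>= threshold``.  The default of 128 binarizes anti-aliased scans
    of hand-drawn delineations sensibly.

    Returns
    -------
    numpy.ndarray
        ``(H, W)`` boolean array, ``True`` = foreground.
    """
    arr = _to_uint8(_read_array(path), Path(path))
    if arr.ndim == 3:
        mean = arr.astype(np.float64).mean(axis=2)
    else:
        mean = arr.astype(np.float64)
    return mean >= threshold


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as an 8-bit single-channel image.

    Foreground is written as 255, background as 0.  Only lossless
    formats (PNG, TIFF) are accepted; the round trip
    ``read_mask(write_mask(m)) == m`` holds exactly.
    """
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS_SUFFIXES:
        raise ImageWriteError(
            f"masks must be written as PNG or TIFF, not {path.suffix!r} "
            "(lossy compression would corrupt pixel-level evaluation)"
        )
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise ValueError("mask must be a 2-D boolean array")
    try:
        iio.imwrite(path, mask.astype(np.uint8) * 255)
    except Exception as exc:
        raise ImageWriteError(f"cannot write mask {path}: {exc}") from exc
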