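"""Mask repair: outlier-removal median filtering and binary closing.

The repair sequence is bright-outlier removal, binary closing, then
dark-outlier removal.  Outlier removal treats the mask as a 0/255 image:
a pixel whose deviation from the median of its circular neighbourhood
exceeds the threshold is replaced by that median, which for a binary
image makes the operation a small-speck (bright mode) or small-hole
(dark mode) killer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MorphologyParams", "remove_outliers", "binary_close", "repair_mask"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of the three-stage mask repair.

    The reference values used by the original macro are not published;
    these defaults are provisional and fully configurable.
    """

    bright_radius: int = 2
    bright_deviation: int = 50
    dark_radius: int = 2
    dark_deviation: int = 50
    close_se_halfwidth: int = 1
    close_iterations: int = 1

    def __post_init__(self) -> None:
        if self.bright_radius < 1 or self.dark_radius < 1:
            raise ValueError("outlier radii must be >= 1")
        if not (0 <= self.bright_deviation <= 255 and 0 <= self.dark_deviation <= 255):
            raise ValueError("deviations must be in [0, 255]")
        if self.close_se_halfwidth < 1 or self.close_iterations < 1:
            raise ValueError("closing parameters must be >= 1")


def _disk_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def remove_outliers(mask: np.ndarray, radius: int, deviation: int, mode: str) -> np.ndarray:
    """Median-replace pixels that deviate from their neighbourhood.

    The neighbourhood is the set of pixels at Euclidean distance
    ``<= radius`` (truncated at image edges).  With foreground embedded
    as 255 and background as 0, bright mode replaces pixels with
    ``value - median > deviation`` and dark mode those with
    ``median - value > deviation``; the result is re-binarized
    (exactly 255 -> foreground).  For even-sized edge neighbourhoods an
    exact 50/50 split yields a median of 127.5, which binarizes to
    background.
    """
    if mode not in ("bright", "dark"):
        raise ValueError("mode must be 'bright' or 'dark'")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    fp = _disk_footprint(radius).astype(np.int64)
    fg_count = ndimage.correlate(mask.astype(np.int64), fp, mode="constant", cval=0)
    n = ndimage.correlate(np.ones(mask.shape, dtype=np.int64), fp, mode="constant", cval=0)
    median = np.where(2 * fg_count > n, 255.0, np.where(2 * fg_count < n, 0.0, 127.5))
    value = np.where(mask, 255.0, 0.0)
    if mode == "bright":
        replace = value - median > deviation
    else:
        replace = median - value > deviation
    out_value = np.where(replace, median, value)
    return out_value == 255.0


def binary_close(mask: np.ndarray, se_halfwidth: int, iterations: int) -> np.ndarray:
    """Binary closing with a square structuring element.

    ``iterations`` dilations followed by ``iterations`` erosions with a
    square element of side ``2 * se_halfwidth + 1``.  Pixels outside the
    image count as background for the dilation and foreground for the
    erosion, so closing never shrinks foreground at the border.
    Idempotent: applying it twice equals applying it once.
    """
    if se_halfwidth < 1 or iterations < 1:
        raise ValueError("se_halfwidth and iterations must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    se = np.ones((2 * se_halfwidth + 1,) * 2, dtype=bool)
    dilated = ndimage.binary_dilation(mask, structure=se, iterations=iterations, border_value=0)
    return ndimage.binary_erosion(dilated, structure=se, iterations=iterations, border_value=1)


def repair_mask(mask: np.ndarray, params: MorphologyParams) -> np.ndarray:
    """Run bright-outlier removal, closing, then dark-outlier removal.

    Per-stage pixel-change counts are logged at DEBUG level.
    """
    mask = np.asarray(mask, dtype=bool)
    stage1 = remove_outliers(mask, params.bright_radius, params.bright_deviation, "bright")
    stage2 = binary_close(stage1, params.close_se_halfwidth, params.close_iterations)
    stage3 = remove_outliers(stage2, params.dark_radius, params.dark_deviation, "dark")
    logger.debug(
        "repair_mask: bright pass changed %d px, closing changed %d px, dark pass changed %d px",
        int(np.sum(stage1 != mask)),
        int(np.sum(stage2 != stage1)),
        int(np.sum(stage3 != stage2)),
    )
    return stage3
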