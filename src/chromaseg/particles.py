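"""Connected-component ("particle") labeling and minimum-area filtering.

Components below the minimum tumour-nest area (default 750 pixels,
inclusive: area >= 750 is kept) are discarded; components touching the
image border are treated like any other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["LabeledComponents", "label_components", "filter_by_area", "particle_summary"]

DEFAULT_MIN_AREA = 750

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class LabeledComponents:
    """Connected foreground components of a mask.

    ``label_map`` holds 0 for background and ``1..count`` for the
    components, numbered in raster-scan order of first encounter;
    ``areas[k - 1]`` is the pixel count of component ``k``.
    """

    label_map: np.ndarray
    areas: np.ndarray
    count: int


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledComponents:
    """Label maximal connected foreground sets.

    Parameters
    ----------
    mask
        Boolean foreground mask.
    connectivity
        4 (edge-adjacent) or 8 (edge- or corner-adjacent, the default,
        matching the usual particle-analyzer convention).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    raw, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return LabeledComponents(label_map=raw, areas=np.zeros(0, dtype=np.int64), count=0)
    # renumber labels by first raster-scan occurrence
    flat = raw.ravel()
    labels, first_idx = np.unique(flat, return_index=True)
    nz = labels != 0
    order = np.argsort(first_idx[nz])
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[labels[nz][order]] = np.arange(1, n + 1)
    label_map = remap[raw]
    areas = np.bincount(label_map.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return LabeledComponents(label_map=label_map, areas=areas, count=n)


def filter_by_area(components: LabeledComponents, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Union of components with area ``>= min_area`` as a boolean mask.

    Only ever removes pixels, and is monotone in ``min_area``.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    keep = np.concatenate([[False], components.areas >= min_area])
    return keep[components.label_map]


def particle_summary(components: LabeledComponents, min_area: int = DEFAULT_MIN_AREA) -> pd.DataFrame:
    """Per-component report: label, area and whether the filter keeps it."""
    return pd.DataFrame(
        {
            "label": np.arange(1, components.count + 1),
            "area": components.areas,
            "kept": components.areas >= min_area,
        }
    )
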