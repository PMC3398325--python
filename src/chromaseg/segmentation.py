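"""Isodata (Ridler-Calvard intermeans) automatic thresholding.

The threshold is the fixed point of ``T <- floor((mu_low(T) + mu_high(T)) / 2)``
where ``mu_low`` is the mean of intensities ``<= T`` and ``mu_high`` the
mean of intensities ``> T``, started at the global mean.  Values equal
to the threshold belong to the low class, in the iteration and in the
binarization: foreground = stain-dense = dark.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateHistogramError

__all__ = ["histogram", "isodata_threshold", "binarize_dark"]

_MAX_ITER = 256
_VALUES = np.arange(256, dtype=np.float64)


def histogram(channel: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit channel."""
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("cannot histogram an empty channel")
    return np.bincount(channel.ravel(), minlength=256)


def isodata_threshold(hist: np.ndarray) -> int:
    """Isodata threshold of a 256-bin histogram.

    Returns the fixed point of the intermeans iteration, an integer in
    ``[0, 255]``.  The update is monotone on the integer lattice so the
    iteration terminates; it is nevertheless capped at 256 steps with a
    warning.  Scaling all counts by a positive constant leaves the
    result unchanged.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two intensity values are occupied (a uniform image
        has no meaningful threshold).
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two occupied values; image is uniform"
        )
    weighted = _VALUES * hist
    t = int((weighted.sum() / hist.sum()))  # start at the global mean
    for _ in range(_MAX_ITER):
        n_low = hist[: t + 1].sum()
        n_high = hist[t + 1 :].sum()
        mu_low = weighted[: t + 1].sum() / n_low
        mu_high = weighted[t + 1 :].sum() / n_high
        t_next = int((mu_low + mu_high) // 2)
        if t_next == t:
            return t
        t = t_next
    warnings.warn("isodata iteration did not converge; returning current threshold")
    return t  # pragma: no cover - unreachable for monotone updates


def binarize_dark(channel: np.ndarray, threshold: int) -> np.ndarray:
    """Binarize with dark (stain-dense) pixels as foreground.

    A pixel is foreground iff its value is ``<= threshold``.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return np.asarray(channel) <= threshold
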