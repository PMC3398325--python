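"""Optical-density transform and H&E stain separation.

The transmitted 8-bit intensity ``i`` of a channel relates to optical
density through ``od = -log10((i + 1) / 256)``, a total, bounded variant
of the Beer-Lambert transform (white maps to ~0.0017 OD rather than 0,
and black to log10(256) ~ 2.408 rather than infinity).

Stain separation inverts a 3x3 matrix whose rows are unit-length stain
OD vectors; the third row is the normalized cross product of the two
stain vectors and absorbs everything neither stain explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateBasisError

__all__ = [
    "DEFAULT_HE_VECTOR_H",
    "DEFAULT_HE_VECTOR_E",
    "StainBasis",
    "default_he_basis",
    "rgb_to_od",
    "deconvolve",
    "enhance_contrast",
    "rgb_to_gray",
]

# Widely used built-in H&E optical-density vectors (raw, un-normalized).
DEFAULT_HE_VECTOR_H = (0.644211, 0.716556, 0.266844)
DEFAULT_HE_VECTOR_E = (0.092789, 0.954111, 0.283111)

#: Standard luma weights, selectable for grayscale conversion.
ITU_GRAY_WEIGHTS = (0.299, 0.587, 0.114)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # deterministic .5 -> up rounding, independent of banker's rounding
    return np.floor(x + 0.5)


@dataclass(frozen=True)
class StainBasis:
    """Orthonormalized stain basis and its inverse mixing matrix.

    Attributes
    ----------
    v_h, v_e, v_residual
        Unit-length OD direction vectors; ``v_residual`` is orthogonal
        to both stain vectors.
    mixing_matrix
        3x3 matrix with the three vectors as rows.
    inverse_matrix
        Its inverse; ``mixing_matrix @ inverse_matrix`` is the identity
        to within 1e-10.
    """

    v_h: np.ndarray
    v_e: np.ndarray
    v_residual: np.ndarray
    mixing_matrix: np.ndarray = field(repr=False)
    inverse_matrix: np.ndarray = field(repr=False)


def build_stain_basis(v_h_raw, v_e_raw) -> StainBasis:
    """Normalize two raw stain vectors into a full :class:`StainBasis`.

    Parameters
    ----------
    v_h_raw, v_e_raw
        Non-zero, non-parallel 3-vectors with non-negative components
        (optical densities per unit stain concentration).

    Raises
    ------
    DegenerateBasisError
        If either vector is zero, has a negative component, or the two
        are parallel (singular mixing matrix).
    """
    v_h_raw = np.asarray(v_h_raw, dtype=np.float64)
    v_e_raw = np.asarray(v_e_raw, dtype=np.float64)
    for name, v in (("haematoxylin", v_h_raw), ("eosin", v_e_raw)):
        if v.shape != (3,):
            raise DegenerateBasisError(f"{name} vector must have 3 components")
        if np.any(v < 0):
            raise DegenerateBasisError(f"{name} vector has negative components")
        if not np.linalg.norm(v) > 0:
            raise DegenerateBasisError(f"{name} vector is zero")
    v_h = v_h_raw / np.linalg.norm(v_h_raw)
    v_e = v_e_raw / np.linalg.norm(v_e_raw)
    cross = np.cross(v_h, v_e)
    cross_norm = np.linalg.norm(cross)
    if cross_norm < 1e-8:
        raise DegenerateBasisError("stain vectors are parallel; basis is singular")
    v_r = cross / cross_norm
    m = np.vstack([v_h, v_e, v_r])
    inv = np.linalg.inv(m)
    if not np.allclose(m @ inv, np.eye(3), atol=1e-10):
        raise DegenerateBasisError("mixing matrix inversion failed")  # pragma: no cover
    return StainBasis(v_h=v_h, v_e=v_e, v_residual=v_r, mixing_matrix=m, inverse_matrix=inv)


def default_he_basis() -> StainBasis:
    """The built-in H&E basis."""
    return build_stain_basis(DEFAULT_HE_VECTOR_H, DEFAULT_HE_VECTOR_E)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit image to optical densities.

    ``od = -log10((i + 1) / 256)`` per channel.  Monotone decreasing in
    intensity, non-negative and finite everywhere.
    """
    image = np.asarray(image)
    return -np.log10((image.astype(np.float64) + 1.0) / 256.0)


def deconvolve(od: np.ndarray, basis: StainBasis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Separate an OD image into per-stain 8-bit channels.

    Per pixel the concentration vector is ``c = od_vec @ inverse_matrix``
    (clamped below at 0; pixels outside the stain simplex, e.g. marking
    dye, would otherwise yield transmittance > 255) and the 8-bit channel
    for stain ``s`` is ``clamp(round(255 * 10**(-c_s)), 0, 255)`` — dark
    means stain-dense.

    Returns
    -------
    tuple of numpy.ndarray
        ``(haematoxylin, eosin, residual)`` channels, each ``(H, W)``
        ``uint8``.
    """
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"OD image must be (H, W, 3), got {od.shape}")
    conc = od @ basis.inverse_matrix
    np.clip(conc, 0.0, None, out=conc)
    channels = np.clip(_round_half_up(255.0 * 10.0 ** (-conc)), 0, 255).astype(np.uint8)
    return channels[:, :, 0], channels[:, :, 1], channels[:, :, 2]


def concentrations(od: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Raw (unclamped) stain concentrations, ``(H, W, 3)`` float."""
    od = np.asarray(od, dtype=np.float64)
    return od @ basis.inverse_matrix


def enhance_contrast(channel: np.ndarray, saturation_fraction: float = 0.0035) -> np.ndarray:
    """Linear contrast stretch with tail saturation.

    The intensity values at the ``saturation_fraction / 2`` and
    ``1 - saturation_fraction / 2`` quantiles map to 0 and 255; values
    outside are clamped.  With ``saturation_fraction = 0`` the observed
    minimum and maximum map to 0 and 255.  A constant channel is
    returned unchanged.  The stretch is monotone: it never swaps the
    order of two pixel values.
    """
    if not 0 <= saturation_fraction < 0.5:
        raise ValueError("saturation_fraction must be in [0, 0.5)")
    channel = np.asarray(channel)
    counts = np.bincount(channel.ravel(), minlength=256)
    sat = channel.size * saturation_fraction / 2.0
    cum = np.cumsum(counts)
    low = int(np.argmax(cum > sat))
    cum_rev = np.cumsum(counts[::-1])
    high = 255 - int(np.argmax(cum_rev > sat))
    if high <= low:
        return channel.copy()
    stretched = (channel.astype(np.float64) - low) * (255.0 / (high - low))
    return np.clip(_round_half_up(stretched), 0, 255).astype(np.uint8)


def rgb_to_gray(image: np.ndarray, weights=(1.0 / 3, 1.0 / 3, 1.0 / 3)) -> np.ndarray:
    """Weighted 8-bit grayscale conversion.

    Defaults to the unweighted channel mean; pass ``ITU_GRAY_WEIGHTS``
    for luma weighting.  Weights must be non-negative and sum to 1.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be 3 non-negative values summing to 1")
    image = np.asarray(image)
    gray = image.astype(np.float64) @ w
    return np.clip(_round_half_up(gray), 0, 255).astype(np.uint8)
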