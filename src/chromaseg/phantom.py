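"""Synthetic H&E phantom images with exactly known ground truth.

Phantoms place haematoxylin-dominant "tumour nest" disks on an
eosin-dominant background, render them through the Beer-Lambert forward
model (the exact inverse of the OD transform used for analysis) and add
Gaussian sensor noise in intensity space.  Two confounder kinds exercise
the pipeline's failure modes:

* distractors — small haematoxylin-rich disks below the particle-area
  threshold, which survive thresholding and are removed only by the
  particle filter;
* eosin patches — large eosin-rich disks bright in the haematoxylin
  channel but dark in grayscale, which create false positives only when
  colour deconvolution is skipped.  None are generated by default.

Ground truth is the union of the nest disks only.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PlacementError
from .stains import StainBasis, _round_half_up, default_he_basis

__all__ = ["PhantomSpec", "PhantomResult", "render_stains", "generate_phantom", "generate_suite"]

#: Pseudo-subtype labels cycled through by :func:`generate_suite`.
SUITE_SUBTYPES = ("nodular-like", "superficial-like", "infiltrative-like")

_MAX_ATTEMPTS = 1000
_MIN_GAP = 5  # pixels between object boundaries, so closing cannot bridge them


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic image generator.

    Nest radii must give areas above the default 750-pixel particle
    threshold and distractor radii areas below it.  Concentrations are
    dimensionless stain amounts in the forward Beer-Lambert model.
    """

    width: int = 1072
    height: int = 902
    n_nests: int = 3
    nest_radius_range: tuple[int, int] = (25, 40)
    nest_h_concentration: float = 0.8
    nest_e_concentration: float = 0.3
    background_h_concentration: float = 0.05
    background_e_concentration: float = 0.4
    n_distractors: int = 0
    distractor_radius_range: tuple[int, int] = (4, 12)
    distractor_h_concentration: float = 0.8
    n_eosin_patches: int = 0
    patch_radius_range: tuple[int, int] = (20, 28)
    patch_h_concentration: float = 0.02
    patch_e_concentration: float = 1.3
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        for lo, hi in (self.nest_radius_range, self.distractor_radius_range, self.patch_radius_range):
            if lo < 1 or hi < lo:
                raise ValueError("radius ranges must satisfy 1 <= min <= max")
        for c in (
            self.nest_h_concentration,
            self.nest_e_concentration,
            self.background_h_concentration,
            self.background_e_concentration,
            self.distractor_h_concentration,
            self.patch_h_concentration,
            self.patch_e_concentration,
        ):
            if c < 0:
                raise ValueError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PhantomResult:
    """A rendered phantom with its exact ground truth and placement log."""

    image: np.ndarray
    truth: np.ndarray
    placements: list[dict] = field(repr=False)
    subtype: str | None = None
    seed: int | None = None


def render_stains(c_h: np.ndarray, c_e: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Render concentration fields to an 8-bit RGB image.

    Per pixel ``od = c_h * v_h + c_e * v_e`` and the channel intensity is
    ``clamp(round(256 * 10**(-od) - 1), 0, 255)`` — the exact inverse of
    the analysis-side OD convention, so render -> OD -> deconvolve
    recovers concentrations up to 8-bit quantization.
    """
    c_h = np.asarray(c_h, dtype=np.float64)
    c_e = np.asarray(c_e, dtype=np.float64)
    if c_h.shape != c_e.shape:
        raise ValueError(f"shape mismatch: c_h {c_h.shape} vs c_e {c_e.shape}")
    od = c_h[..., None] * basis.v_h + c_e[..., None] * basis.v_e
    intensity = 256.0 * 10.0 ** (-od) - 1.0
    return np.clip(_round_half_up(intensity), 0, 255).astype(np.uint8)


def _paint_disk(arr: np.ndarray, cy: int, cx: int, r: int, value: float) -> None:
    # disk = pixels with dy^2 + dx^2 <= r^2 + r: midpoint-style rounding,
    # whose boundary has no isolated single-pixel extremes (a lone extreme
    # pixel would be shaved off by any majority-median repair pass)
    y0, y1 = max(cy - r, 0), min(cy + r + 1, arr.shape[0])
    x0, x1 = max(cx - r, 0), min(cx + r + 1, arr.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r + r
    arr[y0:y1, x0:x1][inside] = value


def _place_objects(rng, spec, kind, n, radius_range, placed):
    """Rejection-sample non-overlapping disk placements, appending to *placed*."""
    lo, hi = radius_range
    for i in range(n):
        for _ in range(_MAX_ATTEMPTS):
            r = int(rng.integers(lo, hi + 1))
            cy = int(rng.integers(r, spec.height - r)) if spec.height > 2 * r else r
            cx = int(rng.integers(r, spec.width - r)) if spec.width > 2 * r else r
            if all(
                (cy - p["cy"]) ** 2 + (cx - p["cx"]) ** 2 >= (r + p["r"] + _MIN_GAP) ** 2
                for p in placed
            ):
                placed.append({"kind": kind, "cy": cy, "cx": cx, "r": r})
                break
        else:
            raise PlacementError(f"could not place {kind} {i + 1} of {n} without overlap")


def generate_phantom(spec: PhantomSpec, basis: StainBasis | None = None) -> PhantomResult:
    """Generate one phantom image with ground truth.

    Nests are placed first, then distractors, then eosin patches, all
    rejection-sampled so no two objects overlap (with a small gap so
    morphological closing cannot merge them); the ground truth is the
    union of the nest disks only.

    Raises
    ------
    PlacementError
        If an object cannot be placed after a bounded number of
        attempts.
    """
    if basis is None:
        basis = default_he_basis()
    rng = np.random.default_rng(spec.seed)
    placed: list[dict] = []
    _place_objects(rng, spec, "nest", spec.n_nests, spec.nest_radius_range, placed)
    _place_objects(rng, spec, "distractor", spec.n_distractors, spec.distractor_radius_range, placed)
    _place_objects(rng, spec, "patch", spec.n_eosin_patches, spec.patch_radius_range, placed)

    c_h = np.full((spec.height, spec.width), spec.background_h_concentration)
    c_e = np.full((spec.height, spec.width), spec.background_e_concentration)
    truth = np.zeros((spec.height, spec.width), dtype=bool)
    for p in placed:
        if p["kind"] == "nest":
            _paint_disk(c_h, p["cy"], p["cx"], p["r"], spec.nest_h_concentration)
            _paint_disk(c_e, p["cy"], p["cx"], p["r"], spec.nest_e_concentration)
            _paint_disk(truth, p["cy"], p["cx"], p["r"], True)
        elif p["kind"] == "distractor":
            _paint_disk(c_h, p["cy"], p["cx"], p["r"], spec.distractor_h_concentration)
            _paint_disk(c_e, p["cy"], p["cx"], p["r"], spec.background_e_concentration)
        else:
            _paint_disk(c_h, p["cy"], p["cx"], p["r"], spec.patch_h_concentration)
            _paint_disk(c_e, p["cy"], p["cx"], p["r"], spec.patch_e_concentration)

    image = render_stains(c_h, c_e, basis)
    if spec.noise_sd > 0:
        noisy = image.astype(np.float64) + rng.normal(0.0, spec.noise_sd, image.shape)
        image = np.clip(_round_half_up(noisy), 0, 255).astype(np.uint8)
    return PhantomResult(image=image, truth=truth, placements=placed, seed=spec.seed)


# per-subtype overrides applied on top of the base spec
_SUITE_PRESETS = {
    "nodular-like": dict(n_nests=3, nest_radius_range=(30, 42), n_distractors=2),
    "superficial-like": dict(n_nests=4, nest_radius_range=(17, 22), n_distractors=15),
    "infiltrative-like": dict(n_nests=8, nest_radius_range=(17, 24), n_distractors=6),
}


def generate_suite(n_images: int, base_spec: PhantomSpec | None = None, seed: int = 0) -> list[PhantomResult]:
    """Generate a labelled suite of phantoms cycling over three presets.

    Images are assigned pseudo-subtype labels round-robin; per-image
    seeds are spawned deterministically from the suite seed, so the same
    seed reproduces the suite bit for bit.  Fields of ``base_spec`` not
    overridden by a preset (noise, concentrations, eosin patches, size)
    apply to every image.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    child_seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n_images)]
    results = []
    for i in range(n_images):
        subtype = SUITE_SUBTYPES[i % len(SUITE_SUBTYPES)]
        spec = replace(base_spec, seed=child_seeds[i], **_SUITE_PRESETS[subtype])
        results.append(replace(generate_phantom(spec), subtype=subtype))
    return results
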