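"""End-to-end orchestration of the four-stage extraction algorithm.

Deconvolution mode: RGB -> OD -> stain separation -> haematoxylin
channel -> contrast stretch -> isodata threshold (dark = foreground) ->
mask repair -> particle filter.  Grayscale mode replaces the stain
separation with a weighted grayscale conversion; every later stage is
shared between the two modes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, image_io, morphology, particles, segmentation, stains
from .errors import ChromasegError
from .morphology import MorphologyParams

__all__ = ["PipelineConfig", "run_pipeline", "run_channel_pipeline", "run_batch"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved configuration of one pipeline run."""

    mode: str = "deconvolution"  # "deconvolution" | "grayscale"
    vector_h: tuple[float, float, float] = stains.DEFAULT_HE_VECTOR_H
    vector_e: tuple[float, float, float] = stains.DEFAULT_HE_VECTOR_E
    contrast_saturation: float = 0.0035
    gray_weights: tuple[float, float, float] = (1.0 / 3, 1.0 / 3, 1.0 / 3)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    min_area: int = particles.DEFAULT_MIN_AREA
    connectivity: int = 8
    threshold: int | str = "auto"  # "auto" or a manual integer override

    def __post_init__(self) -> None:
        if self.mode not in ("deconvolution", "grayscale"):
            raise ValueError("mode must be 'deconvolution' or 'grayscale'")
        if self.threshold != "auto" and not (
            isinstance(self.threshold, int) and 0 <= self.threshold <= 255
        ):
            raise ValueError("threshold must be 'auto' or an integer in [0, 255]")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        """Build a config from a (possibly partial) nested mapping."""
        kwargs: dict = {}
        if "mode" in cfg:
            kwargs["mode"] = cfg["mode"]
        st = cfg.get("stains", {})
        if "vector_h" in st:
            kwargs["vector_h"] = tuple(float(x) for x in st["vector_h"])
        if "vector_e" in st:
            kwargs["vector_e"] = tuple(float(x) for x in st["vector_e"])
        if "contrast_saturation" in st:
            kwargs["contrast_saturation"] = float(st["contrast_saturation"])
        gray = cfg.get("gray", {})
        if "weights" in gray:
            kwargs["gray_weights"] = tuple(float(x) for x in gray["weights"])
        morph = cfg.get("morphology", {})
        if morph:
            kwargs["morphology"] = MorphologyParams(**{k: int(v) for k, v in morph.items()})
        part = cfg.get("particles", {})
        if "min_area" in part:
            kwargs["min_area"] = int(part["min_area"])
        if "connectivity" in part:
            kwargs["connectivity"] = int(part["connectivity"])
        seg = cfg.get("segmentation", {})
        if "threshold" in seg:
            t = seg["threshold"]
            kwargs["threshold"] = t if t == "auto" else int(t)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML file."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_dict(cfg)

    def to_dict(self) -> dict:
        """Nested mapping mirroring the config-file layout."""
        return {
            "mode": self.mode,
            "stains": {
                "vector_h": list(self.vector_h),
                "vector_e": list(self.vector_e),
                "contrast_saturation": self.contrast_saturation,
            },
            "gray": {"weights": list(self.gray_weights)},
            "morphology": dataclasses.asdict(self.morphology),
            "particles": {"min_area": self.min_area, "connectivity": self.connectivity},
            "segmentation": {"threshold": self.threshold},
        }


def _extract_channel(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    if config.mode == "deconvolution":
        basis = stains.build_stain_basis(config.vector_h, config.vector_e)
        od = stains.rgb_to_od(image)
        h_channel, _, _ = stains.deconvolve(od, basis)
        return h_channel
    return stains.rgb_to_gray(image, config.gray_weights)


def run_channel_pipeline(channel: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Run every stage downstream of channel extraction.

    Both modes share this path verbatim: contrast stretch, isodata
    threshold, mask repair, particle filter.
    """
    enhanced = stains.enhance_contrast(channel, config.contrast_saturation)
    if config.threshold == "auto":
        threshold = segmentation.isodata_threshold(segmentation.histogram(enhanced))
    else:
        threshold = int(config.threshold)
    logger.info("threshold = %d", threshold)
    raw_mask = segmentation.binarize_dark(enhanced, threshold)
    repaired = morphology.repair_mask(raw_mask, config.morphology)
    components = particles.label_components(repaired, config.connectivity)
    filtered = particles.filter_by_area(components, config.min_area)
    logger.info(
        "raw foreground %d px, repaired %d px, %d components, kept %d px",
        int(raw_mask.sum()), int(repaired.sum()), components.count, int(filtered.sum()),
    )
    return filtered


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    debug_dir: str | Path | None = None,
    image_id: str = "image",
) -> np.ndarray:
    """Extract the chromatin-rich foreground mask from an RGB image.

    Deterministic: identical input and config always yield an identical
    mask.  When ``debug_dir`` is given, numbered per-stage PNGs are
    written there for auditing.
    """
    if config is None:
        config = PipelineConfig()
    channel = _extract_channel(image, config)
    if debug_dir is None:
        return run_channel_pipeline(channel, config)

    debug_dir = Path(debug_dir)
    debug_dir.mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    label = "haematoxylin" if config.mode == "deconvolution" else "grayscale"
    iio.imwrite(debug_dir / f"{image_id}_01_{label}.png", channel)
    enhanced = stains.enhance_contrast(channel, config.contrast_saturation)
    iio.imwrite(debug_dir / f"{image_id}_02_enhanced.png", enhanced)
    if config.threshold == "auto":
        threshold = segmentation.isodata_threshold(segmentation.histogram(enhanced))
    else:
        threshold = int(config.threshold)
    raw_mask = segmentation.binarize_dark(enhanced, threshold)
    image_io.write_mask(raw_mask, debug_dir / f"{image_id}_03_threshold.png")
    repaired = morphology.repair_mask(raw_mask, config.morphology)
    image_io.write_mask(repaired, debug_dir / f"{image_id}_04_morphology.png")
    components = particles.label_components(repaired, config.connectivity)
    filtered = particles.filter_by_area(components, config.min_area)
    image_io.write_mask(filtered, debug_dir / f"{image_id}_05_particles.png")
    return filtered


def run_batch(
    image_paths: list,
    truth_paths: list,
    subtype_map: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pipeline over paired image/truth files and evaluate.

    Per-image failures are recorded in the output with an error flag and
    do not abort the batch.

    Returns
    -------
    (per_image, summary)
        ``per_image`` has one row per image (counts, metrics, error);
        ``summary`` is the per-subtype + "All" macro-average table.
    """
    if len(image_paths) != len(truth_paths):
        raise ValueError("image and truth path lists must align")
    if config is None:
        config = PipelineConfig()
    subtype_map = subtype_map or {}
    rows = []
    records = []
    for img_path, truth_path in zip(image_paths, truth_paths):
        image_id = Path(img_path).stem
        subtype = subtype_map.get(image_id)
        row: dict = {"image_id": image_id, "subtype": subtype, "error": ""}
        try:
            image = image_io.read_rgb_image(img_path)
            truth = image_io.read_mask(truth_path)
            if truth.shape != image.shape[:2]:
                raise ChromasegError(
                    f"truth shape {truth.shape} does not match image {image.shape[:2]}"
                )
            pred = run_pipeline(image, config, image_id=image_id)
            counts = evaluation.confusion_counts(pred, truth)
            rec = evaluation.compute_metrics(counts, image_id=image_id, subtype=subtype)
            records.append(rec)
            row.update(tp=counts.tp, fp=counts.fp, fn=counts.fn, tn=counts.tn,
                       se=rec.se, sp=rec.sp, ppv=rec.ppv, npv=rec.npv)
        except Exception as exc:  # keep the batch alive
            logger.error("image %s failed: %s", image_id, exc)
            row["error"] = str(exc)
        rows.append(row)
    per_image = pd.DataFrame(rows)
    summary = evaluation.aggregate(records) if records else pd.DataFrame()
    return per_image, summary
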