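"""Pixel-wise confusion counts and SE/SP/PPV/NPV with macro-averaging.

Counts follow the mask-subtraction scheme: FN = truth minus prediction,
FP = prediction minus truth, TP = |prediction| - FP and
TN = total - |prediction| - FN.  TP so defined equals the directly
counted intersection |prediction AND truth|, and the four counts always
sum to the pixel total.

Aggregation is per-image macro-averaging (the unweighted mean of
per-image percentages), not pixel pooling; metrics whose denominator is
zero are undefined and excluded from means, with the inclusion count
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsRecord", "confusion_counts", "compute_metrics", "aggregate"]

_METRICS = ("se", "sp", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-image pixel counts; ``tp + fp + fn + tn == total`` always."""

    tp: int
    fp: int
    fn: int
    tn: int
    total: int


@dataclass(frozen=True)
class MetricsRecord:
    """Per-image metrics in percent; ``None`` marks a 0/0 denominator."""

    image_id: str
    subtype: str | None
    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts of a predicted mask against ground truth.

    Raises
    ------
    ValueError
        If the two masks differ in shape.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    total = pred.size
    fn = int(np.sum(truth & ~pred))
    fp = int(np.sum(pred & ~truth))
    n_pred = int(np.sum(pred))
    tp = n_pred - fp
    tn = total - n_pred - fn
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, total=total)
    assert counts.tp + counts.fp + counts.fn + counts.tn == total
    return counts


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts, image_id: str = "", subtype: str | None = None) -> MetricsRecord:
    """SE, SP, PPV and NPV (percent) from confusion counts.

    A zero denominator yields ``None`` for that metric, never an
    exception.
    """
    return MetricsRecord(
        image_id=image_id,
        subtype=subtype,
        se=_ratio(counts.tp, counts.tp + counts.fn),
        sp=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


def aggregate(records: list[MetricsRecord]) -> pd.DataFrame:
    """Macro-average metrics per subtype plus a pooled "All" row.

    Columns: ``group``, ``n`` (images in the group), and for each metric
    its mean over the images where it is defined together with the
    number of images included (``n_se`` etc.).
    """
    if not records:
        raise ValueError("no records to aggregate")
    groups: dict[str, list[MetricsRecord]] = {}
    for rec in records:
        groups.setdefault(rec.subtype if rec.subtype is not None else "other", []).append(rec)
    rows = []
    for name, members in list(groups.items()) + [("All", records)]:
        row: dict[str, object] = {"group": name, "n": len(members)}
        for metric in _METRICS:
            defined = [getattr(r, metric) for r in members if getattr(r, metric) is not None]
            row[metric] = float(np.mean(defined)) if defined else None
            row[f"n_{metric}"] = len(defined)
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_counts(counts_list: list[ConfusionCounts]) -> ConfusionCounts:
    """Pixel-pooled counts over several images (for sensitivity analyses)."""
    if not counts_list:
        raise ValueError("no counts to pool")
    return ConfusionCounts(
        tp=sum(c.tp for c in counts_list),
        fp=sum(c.fp for c in counts_list),
        fn=sum(c.fn for c in counts_list),
        tn=sum(c.tn for c in counts_list),
        total=sum(c.total for c in counts_list),
    )
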