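"""Pixel-level segmentation metrics and dataset aggregation.

All five scores are functions of the per-image confusion counts with the
white blood cell as the positive class: the Dice similarity measure (DSM),
pixel accuracy (PA), mean per-class pixel accuracy (MPA), the positive
class intersection-over-union (IU) and the class-mean IoU (MIU).

The MPA used here averages precision-style per-class ratios,
(TP/(TP+FP) + TN/(TN+FN)) / 2, rather than the recall-style denominators
(TP+FN, TN+FP) most packages use.  Both are reported side by side: pass
``conventional=True`` to get recall-style MPA for external comparison.
The class-mean IoU is identical under either reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion_counts",
    "dsm", "pa", "mpa", "iu", "miu", "evaluate_dataset",
    "METRIC_NAMES",
]

METRIC_NAMES = ("dsm", "pa", "mpa", "iu", "miu")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise tallies of a prediction against ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred_mask, truth_mask) -> ConfusionCounts:
    """Tally TP/FP/FN/TN pixels; label maps are binarized as any id > 0."""
    pred = np.asarray(pred_mask) > 0
    truth = np.asarray(truth_mask) > 0
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
    )


def dsm(counts: ConfusionCounts) -> float:
    """Dice similarity measure 2TP / (FP + FN + 2TP); 1.0 when both empty."""
    denom = counts.fp + counts.fn + 2 * counts.tp
    if denom == 0:
        return 1.0  # both masks empty: perfect agreement on emptiness
    return 2.0 * counts.tp / denom


def pa(counts: ConfusionCounts) -> float:
    """Pixel accuracy (TP + TN) / total."""
    if counts.total == 0:
        raise ValueError("pixel accuracy undefined for zero pixels")
    return (counts.tp + counts.tn) / counts.total


def mpa(counts: ConfusionCounts, conventional: bool = False) -> float:
    """Mean per-class pixel accuracy.

    Default form: (TP/(TP+FP) + TN/(TN+FN)) / 2.  With
    ``conventional=True``: (TP/(TP+FN) + TN/(TN+FP)) / 2.  When one class
    is absent the defined term alone is returned.
    """
    if conventional:
        pos_den, neg_den = counts.tp + counts.fn, counts.tn + counts.fp
    else:
        pos_den, neg_den = counts.tp + counts.fp, counts.tn + counts.fn
    terms = []
    if pos_den > 0:
        terms.append(counts.tp / pos_den)
    if neg_den > 0:
        terms.append(counts.tn / neg_den)
    if not terms:
        raise ValueError("mean pixel accuracy undefined: both classes empty")
    return float(np.mean(terms))


def iu(counts: ConfusionCounts) -> float:
    """Positive-class intersection over union TP / (TP + FP + FN)."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def miu(counts: ConfusionCounts) -> float:
    """Class-mean IoU (TP/(TP+FP+FN) + TN/(TN+FN+FP)) / 2."""
    pos_den = counts.tp + counts.fp + counts.fn
    neg_den = counts.tn + counts.fn + counts.fp
    terms = []
    if pos_den > 0:
        terms.append(counts.tp / pos_den)
    if neg_den > 0:
        terms.append(counts.tn / neg_den)
    if not terms:
        raise ValueError("mean IoU undefined: no pixels in either class")
    return float(np.mean(terms))


@dataclass
class MetricsReport:
    """Per-image metrics with dataset means and box-plot quartiles."""

    per_image: pd.DataFrame
    means: dict[str, float]
    quartiles: pd.DataFrame

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.per_image.to_csv(path, index=False)
        return path

    def save_boxplot(self, path) -> Path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        data = [self.per_image[m] for m in METRIC_NAMES]
        ax.boxplot(data, tick_labels=[m.upper() for m in METRIC_NAMES])
        ax.set_ylabel("score")
        ax.set_title("Segmentation accuracy")
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def evaluate_dataset(pred_label_maps, truth_masks,
                     conventional: bool = False,
                     image_ids=None) -> MetricsReport:
    """Score paired predictions and ground-truth masks.

    Label maps are binarized (any id > 0); per-image DSM/PA/MPA/IU/MIU are
    tabulated with dataset means and quartile summaries for box plots.
    """
    preds = list(pred_label_maps)
    truths = list(truth_masks)
    if not preds:
        raise ValueError("cannot evaluate an empty dataset")
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    if image_ids is None:
        image_ids = [f"image_{i:04d}" for i in range(len(preds))]
    rows = []
    for img_id, pred, truth in zip(image_ids, preds, truths):
        pred = getattr(pred, "pixels", pred)
        truth = getattr(truth, "pixels", truth)
        c = confusion_counts(pred, truth)
        rows.append({
            "image_id": img_id,
            "dsm": dsm(c),
            "pa": pa(c),
            "mpa": mpa(c, conventional=conventional),
            "iu": iu(c),
            "miu": miu(c),
        })
    per_image = pd.DataFrame(rows)
    means = {m: float(per_image[m].mean()) for m in METRIC_NAMES}
    quartiles = per_image[list(METRIC_NAMES)].quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    return MetricsReport(per_image=per_image, means=means, quartiles=quartiles)
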