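"""Segmentation-quality and lesion-detection metrics.

Two Dice variants are reported: the mean of per-acquisition Dice scores
(more affected by errors on acquisitions with few lesions) and a global
Dice pooling all acquisitions as one (more affected by errors on large
lesions).

Detection follows a 50 %-overlap component rule: a ground-truth lesion
is a true positive when at least half of it is covered by the pooled
prediction, otherwise a false negative; a predicted component is a false
positive when less than half of it overlaps the pooled ground truth.
Note the asymmetry: exactly 50 % GT coverage counts as detected, while
exactly 50 % prediction overlap is *not* a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biomarkers import label_lesions
from .io_core import BinaryMask


@dataclass
class DiceSummary:
    per_acquisition: list[float]
    mean: float
    sd: float
    global_dice: float


@dataclass
class DetectionResult:
    tp: int
    fn: int
    fp: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else float("nan")

    def __add__(self, other: "DetectionResult") -> "DetectionResult":
        return DetectionResult(self.tp + other.tp, self.fn + other.fn, self.fp + other.fp)


def dice(gt: BinaryMask, pred: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks give 1.0 (degenerate case)."""
    gt.require_same_lattice(pred, "ground truth vs prediction")
    a = int(np.count_nonzero(gt.values))
    b = int(np.count_nonzero(pred.values))
    if a + b == 0:
        return 1.0
    inter = int(np.count_nonzero(gt.values & pred.values))
    return 2.0 * inter / (a + b)


def dice_summary(pairs: list[tuple[BinaryMask, BinaryMask]]) -> DiceSummary:
    """Mean ± sd of per-acquisition Dice plus a pooled global Dice."""
    if not pairs:
        raise ValueError("dice_summary needs at least one (gt, pred) pair")
    scores = []
    inter_sum = 0
    size_sum = 0
    for gt, pred in pairs:
        scores.append(dice(gt, pred))
        inter_sum += int(np.count_nonzero(gt.values & pred.values))
        size_sum += int(np.count_nonzero(gt.values)) + int(np.count_nonzero(pred.values))
    global_dice = 1.0 if size_sum == 0 else 2.0 * inter_sum / size_sum
    arr = np.asarray(scores)
    return DiceSummary(
        per_acquisition=scores,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(scores) > 1 else 0.0,
        global_dice=global_dice,
    )


def detection_counts(
    gt: BinaryMask,
    pred: BinaryMask,
    threshold: float = 0.5,
    connectivity: int = 26,
) -> DetectionResult:
    """Component-wise TP/FN/FP counts under the 50 %-overlap detection rule.

    Each ground-truth component is compared against the pooled predicted
    mask (TP iff covered fraction ≥ ``threshold``); each predicted
    component against the pooled ground truth (FP iff overlap fraction
    < ``threshold``, measured against the predicted component's own
    volume).
    """
    gt.require_same_lattice(pred, "ground truth vs prediction")

    def _fractions(labels: np.ndarray, other: np.ndarray) -> np.ndarray:
        k = int(labels.max(initial=0))
        if k == 0:
            return np.zeros(0)
        counts = np.bincount(labels.ravel(), minlength=k + 1)[1:]
        overlap = np.bincount(labels[other], minlength=k + 1)[1:]
        return overlap / counts

    gt_frac = _fractions(label_lesions(gt, connectivity).labels, pred.values)
    pred_frac = _fractions(label_lesions(pred, connectivity).labels, gt.values)
    tp = int(np.count_nonzero(gt_frac >= threshold))
    fn = len(gt_frac) - tp
    fp = int(np.count_nonzero(pred_frac < threshold))
    return DetectionResult(tp=tp, fn=fn, fp=fp)
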