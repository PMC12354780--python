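"""Exact evaluation metrics for segmentation masks and classifiers.

Confusion-count metrics (accuracy, precision, recall/sensitivity, F1,
specificity, MCC), overlap measures (Dice, IoU), the exact symmetric Hausdorff
distance H(A,B) = max(h(A,B), h(B,A)) with h(A,B) = max_{a in A} min_{b in B}
||a - b|| in pixel units, and rank-based AUC.

Degenerate denominators (e.g. no predicted positives on an all-background
slice) yield a 0 metric plus a flag rather than an exception, because empty
masks are legal inputs here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from sklearn.metrics import matthews_corrcoef, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "scalar_metrics",
    "dice_iou",
    "hausdorff",
    "normalized_hausdorff",
    "auc",
    "evaluate_masks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    specificity: float = 0.0
    sensitivity: float = 0.0
    dice: float = 0.0
    iou: float = 0.0
    mcc: float = 0.0
    auc: float = 0.0
    hausdorff: float = 0.0
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "precision", "recall", "f1", "specificity",
                 "sensitivity", "dice", "iou", "mcc", "auc", "hausdorff")}


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    uniq = np.unique(arr)
    if not np.isin(uniq, [0, 1, False, True]).all():
        raise ValueError(f"{name} must be binary, found values {uniq[:5]}")
    return arr.astype(bool)


def confusion(pred: np.ndarray, target: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between two binary masks."""
    pred = _check_binary(pred, "pred")
    target = _check_binary(target, "target")
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    tp = int(np.count_nonzero(pred & target))
    fp = int(np.count_nonzero(pred & ~target))
    tn = int(np.count_nonzero(~pred & ~target))
    fn = int(np.count_nonzero(~pred & target))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def scalar_metrics(c: ConfusionCounts) -> MetricsReport:
    """Confusion-count metrics; zero denominators give 0 plus a flag."""
    rep = MetricsReport()

    def safe(num, den, flag):
        if den == 0:
            rep.flags.append(flag)
            return 0.0
        return num / den

    rep.accuracy = safe(c.tp + c.tn, c.total, "accuracy_undefined")
    rep.precision = safe(c.tp, c.tp + c.fp, "precision_undefined")
    rep.recall = safe(c.tp, c.tp + c.fn, "recall_undefined")
    rep.sensitivity = rep.recall
    rep.specificity = safe(c.tn, c.tn + c.fp, "specificity_undefined")
    rep.f1 = safe(2 * rep.precision * rep.recall, rep.precision + rep.recall,
                  "f1_undefined")
    mcc_den = np.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if mcc_den == 0:
        rep.flags.append("mcc_undefined")
        rep.mcc = 0.0
    else:
        rep.mcc = float((c.tp * c.tn - c.fp * c.fn) / mcc_den)
    return rep


def dice_iou(pred: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B|; both-empty -> (1, 1)."""
    pred = _check_binary(pred, "pred")
    target = _check_binary(target, "target")
    inter = int(np.count_nonzero(pred & target))
    a, b = int(np.count_nonzero(pred)), int(np.count_nonzero(target))
    if a + b == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (a + b)
    iou = inter / (a + b - inter)
    return dice, iou


def hausdorff(pred: np.ndarray, target: np.ndarray) -> tuple[float, list[str]]:
    """Exact symmetric Hausdorff distance between mask foregrounds, in pixels.

    Conventions: both empty -> 0; exactly one empty -> image diagonal.  Flags
    report which convention fired.
    """
    pred = _check_binary(pred, "pred")
    target = _check_binary(target, "target")
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    a = np.argwhere(pred).astype(np.float64)
    b = np.argwhere(target).astype(np.float64)
    if len(a) == 0 and len(b) == 0:
        return 0.0, ["both_empty"]
    if len(a) == 0 or len(b) == 0:
        return float(np.hypot(*pred.shape)), ["one_empty"]
    hab = directed_hausdorff(a, b)[0]
    hba = directed_hausdorff(b, a)[0]
    return float(max(hab, hba)), []


def normalized_hausdorff(pred: np.ndarray, target: np.ndarray) -> float:
    """Hausdorff divided by the image diagonal (scale-free, in [0, 1])."""
    hd, _ = hausdorff(pred, target)
    return hd / float(np.hypot(*np.asarray(pred).shape))


def auc(scores: np.ndarray, targets: np.ndarray) -> tuple[float, list[str]]:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    targets = np.asarray(targets).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(np.unique(targets)) < 2:
        return 0.0, ["auc_single_class"]
    return float(roc_auc_score(targets, scores)), []


def mcc_score(pred_labels: np.ndarray, targets: np.ndarray) -> float:
    """Sample-level MCC (cross-check path via scikit-learn)."""
    return float(matthews_corrcoef(targets, pred_labels))


def evaluate_masks(pred: np.ndarray, target: np.ndarray,
                   scores: np.ndarray | None = None,
                   auc_subsample: float = 0.01,
                   seed: int = 0) -> MetricsReport:
    """Full per-slice report for a predicted vs ground-truth binary mask.

    Pixel-level AUC uses a stratified subsample of pixels (default 1%) when
    probability scores are supplied, since a full-pixel ROC adds cost without
    statistical benefit.
    """
    counts = confusion(pred, target)
    rep = scalar_metrics(counts)
    rep.dice, rep.iou = dice_iou(pred, target)
    hd, hd_flags = hausdorff(pred, target)
    rep.hausdorff = hd
    rep.flags.extend(hd_flags)
    if scores is not None:
        s = np.asarray(scores).ravel()
        t = np.asarray(target).astype(int).ravel()
        rng = np.random.default_rng(seed)
        n_sub = max(int(len(s) * auc_subsample), 200)
        pos = np.flatnonzero(t == 1)
        neg = np.flatnonzero(t == 0)
        if len(pos) and len(neg):
            n_pos = max(1, min(len(pos), n_sub // 2))
            n_neg = max(1, min(len(neg), n_sub - n_pos))
            idx = np.concatenate([rng.choice(pos, n_pos, replace=False),
                                  rng.choice(neg, n_neg, replace=False)])
            rep.auc, auc_flags = auc(s[idx], t[idx])
            rep.flags.extend(auc_flags)
        else:
            rep.flags.append("auc_single_class")
    return rep
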