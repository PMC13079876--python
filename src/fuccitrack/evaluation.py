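"""Instance-segmentation and classification evaluation, plus SNR.

Metric conventions:

* masks are matched one-to-one by maximizing total IoU (optimal
  assignment), then pairs below the IoU threshold are discarded;
* accuracy (a.k.a. average precision at an IoU threshold) is
  ``TP / (TP + FN + FP)``, precision is ``TP / (TP + FP)``, and the
  false-positive ratio is ``FP / (TP + FP)`` (FP over predicted masks);
* the SNR of a movie is, per FUCCI channel, the background-corrected mean
  in-mask intensity divided by the in-mask standard deviation, and the
  final value is the maximum over the two channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix

from .errors import UndefinedMetricError
from .phases import PhaseLabel
from .track_io import ImageStack, LabelStack


# ---------------------------------------------------------------------------
# IoU and matching
# ---------------------------------------------------------------------------

def label_ids(image: np.ndarray) -> np.ndarray:
    """Sorted non-background instance ids of a label image."""
    ids = np.unique(image)
    return ids[ids > 0]


def iou_matrix(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union of ground-truth and predicted masks.

    Entry (g, p) is |gt_g ∩ pred_p| / |gt_g ∪ pred_p| with rows/columns
    ordered by sorted instance id; background (0) is excluded.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    gt_ids = label_ids(gt)
    pred_ids = label_ids(pred)
    if len(gt_ids) == 0 or len(pred_ids) == 0:
        return np.zeros((len(gt_ids), len(pred_ids)))
    n_gt = int(gt.max()) + 1
    n_pred = int(pred.max()) + 1
    inter = coo_matrix(
        (np.ones(gt.size), (gt.ravel(), pred.ravel())), shape=(n_gt, n_pred)
    ).toarray()
    gt_area = np.bincount(gt.ravel(), minlength=n_gt).astype(float)
    pred_area = np.bincount(pred.ravel(), minlength=n_pred).astype(float)
    union = gt_area[:, None] + pred_area[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou[np.ix_(gt_ids, pred_ids)]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one IoU matching of ground-truth and predicted masks."""

    iou: np.ndarray  # (n_gt, n_pred)
    matches: frozenset[tuple[int, int]]  # (gt_index, pred_index) row/col pairs
    tp: int
    fp: int
    fn: int


def match_masks(iou: np.ndarray, threshold: float = 0.5) -> MatchResult:
    """Optimal one-to-one matching of masks at an IoU threshold.

    Entries below the threshold are zeroed, then the assignment maximizing
    total IoU over all one-to-one matchings is taken (Hungarian algorithm)
    and sub-threshold pairs are discarded. TP is the number of surviving
    pairs, FP the unmatched predictions, FN the unmatched ground-truth
    masks. (At thresholds of 0.5 and above the matching is unambiguous:
    two masks cannot both overlap the same object that strongly.)
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    iou = np.asarray(iou, dtype=float)
    n_gt, n_pred = iou.shape
    matches: set[tuple[int, int]] = set()
    if n_gt and n_pred:
        gated = np.where(iou >= threshold, iou, 0.0)
        rows, cols = linear_sum_assignment(-gated)
        for g, p in zip(rows, cols):
            if iou[g, p] >= threshold:
                matches.add((int(g), int(p)))
    tp = len(matches)
    return MatchResult(
        iou=iou, matches=frozenset(matches), tp=tp, fp=n_pred - tp, fn=n_gt - tp
    )


def accuracy_at_iou(m: MatchResult) -> float:
    """TP / (TP + FN + FP)."""
    denom = m.tp + m.fn + m.fp
    if denom == 0:
        raise UndefinedMetricError("accuracy undefined: no objects in gt or pred")
    return m.tp / denom


def precision(m: MatchResult) -> float:
    """TP / (TP + FP)."""
    denom = m.tp + m.fp
    if denom == 0:
        raise UndefinedMetricError("precision undefined: no predicted objects")
    return m.tp / denom


def fp_ratio(m: MatchResult) -> float:
    """FP divided by the number of predicted masks."""
    denom = m.tp + m.fp
    if denom == 0:
        raise UndefinedMetricError("fp_ratio undefined: no predicted objects")
    return m.fp / denom


def accuracy_curve(
    gt: np.ndarray, pred: np.ndarray, thresholds: Sequence[float]
) -> list[tuple[float, float]]:
    """Accuracy as a function of the IoU threshold (non-increasing).

    The IoU matrix is computed once and re-matched per threshold.
    """
    iou = iou_matrix(gt, pred)
    return [(float(t), accuracy_at_iou(match_masks(iou, t))) for t in thresholds]


# ---------------------------------------------------------------------------
# Per-class confusion
# ---------------------------------------------------------------------------

#: Phase classes evaluated in the confusion matrices (DARK masks are skipped:
#: a near-dark nucleus carries no color information to classify).
CONFUSION_CLASSES = (PhaseLabel.G1, PhaseLabel.G1S, PhaseLabel.SG2M)


@dataclass
class ClassConfusion:
    """Per-class precision and accuracy matrices (predicted × ground truth).

    ``counts[p, g]`` is the number of IoU-matched mask pairs predicted as
    class p with ground-truth class g. ``fn_counts[g]`` counts unmatched
    ground-truth masks per class and ``fp_counts[p]`` unmatched predicted
    masks per class; they enter only the accuracy denominators, which is
    how segmentation errors propagate into the per-class accuracy.
    """

    counts: np.ndarray  # (3, 3) matched pairs
    fn_counts: np.ndarray  # (3,) unmatched gt per class
    fp_counts: np.ndarray  # (3,) unmatched pred per class
    classes: tuple[PhaseLabel, ...] = CONFUSION_CLASSES

    def __add__(self, other: "ClassConfusion") -> "ClassConfusion":
        return ClassConfusion(
            counts=self.counts + other.counts,
            fn_counts=self.fn_counts + other.fn_counts,
            fp_counts=self.fp_counts + other.fp_counts,
            classes=self.classes,
        )

    @property
    def precision_matrix(self) -> np.ndarray:
        """Entry (p, g): matched masks predicted p with gt g over all
        matched masks predicted p; rows with no matched prediction are NaN."""
        row_totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row_totals > 0, self.counts / row_totals, np.nan)

    @property
    def accuracy_matrix(self) -> np.ndarray:
        """Like precision, but the denominator additionally counts the
        unmatched ground-truth masks of the column's class (FN) and the
        unmatched predicted masks of the row's class (FP)."""
        out = np.full_like(self.counts, np.nan, dtype=float)
        row_totals = self.counts.sum(axis=1)
        for p in range(len(self.classes)):
            for g in range(len(self.classes)):
                denom = row_totals[p] + self.fn_counts[g] + self.fp_counts[p]
                if denom > 0:
                    out[p, g] = self.counts[p, g] / denom
        return out


def _phase_of(mapping: Mapping[int, PhaseLabel | str], label: int) -> PhaseLabel | None:
    value = mapping.get(label)
    if value is None:
        return None
    if isinstance(value, PhaseLabel):
        return value
    from .phases import parse_phase

    return parse_phase(value)


def class_confusion(
    gt: np.ndarray,
    gt_phases: Mapping[int, PhaseLabel | str],
    pred: np.ndarray,
    pred_phases: Mapping[int, PhaseLabel | str],
    iou_threshold: float = 0.5,
) -> ClassConfusion:
    """Phase confusion between matched ground-truth and predicted masks.

    Masks are matched at the IoU threshold first; matched pairs contribute
    to the count matrix by their (predicted, ground-truth) classes, while
    unmatched masks contribute to the FN/FP tallies of their own class.
    Masks labeled DARK (or missing from the phase mapping) are excluded.
    """
    gt_ids = label_ids(gt)
    pred_ids = label_ids(pred)
    result = match_masks(iou_matrix(gt, pred), iou_threshold)
    idx = {cls: i for i, cls in enumerate(CONFUSION_CLASSES)}

    counts = np.zeros((3, 3), dtype=float)
    fn_counts = np.zeros(3, dtype=float)
    fp_counts = np.zeros(3, dtype=float)
    matched_gt = {g for g, _ in result.matches}
    matched_pred = {p for _, p in result.matches}
    for g, p in result.matches:
        gt_cls = _phase_of(gt_phases, int(gt_ids[g]))
        pred_cls = _phase_of(pred_phases, int(pred_ids[p]))
        if gt_cls in idx and pred_cls in idx:
            counts[idx[pred_cls], idx[gt_cls]] += 1
    for g in range(len(gt_ids)):
        if g not in matched_gt:
            cls = _phase_of(gt_phases, int(gt_ids[g]))
            if cls in idx:
                fn_counts[idx[cls]] += 1
    for p in range(len(pred_ids)):
        if p not in matched_pred:
            cls = _phase_of(pred_phases, int(pred_ids[p]))
            if cls in idx:
                fp_counts[idx[cls]] += 1
    return ClassConfusion(counts=counts, fn_counts=fn_counts, fp_counts=fp_counts)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnrEstimate:
    """Per-channel and final signal-to-noise ratio of a movie."""

    per_channel_snr: dict[str, float]
    snr: float


def compute_snr(
    images: ImageStack,
    gt: LabelStack,
    channels: Sequence[str] = ("cyan", "magenta"),
) -> SnrEstimate:
    """SNR from ground-truth nuclear masks.

    Per channel: the mean signal inside the masks is corrected by the
    background (the mean outside the masks) and divided by the standard
    deviation inside the masks. The final SNR is the maximum over the
    channels — invariant under positive affine intensity transforms.
    """
    if images.data.shape[0] != gt.data.shape[0] or images.data.shape[2:] != gt.data.shape[1:]:
        raise ValueError("images and labels do not share (time, y, x) dimensions")
    inside = gt.data > 0
    if not inside.any():
        raise ValueError("label stack contains no masks")
    per_channel: dict[str, float] = {}
    for ch in channels:
        pixels = images.channel(ch).astype(float)
        in_mask = pixels[inside]
        out_mask = pixels[~inside]
        std_in = in_mask.std()
        if std_in == 0:
            raise ValueError(
                f"channel {ch!r} has zero in-mask variance; SNR is undefined "
                f"(consider injecting synthetic noise)"
            )
        background = out_mask.mean() if out_mask.size else 0.0
        per_channel[ch] = float((in_mask.mean() - background) / std_in)
    return SnrEstimate(per_channel_snr=per_channel, snr=max(per_channel.values()))
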