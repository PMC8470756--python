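"""Detection and segmentation metrics.

Detections are matched to ground-truth masses one-to-one, greedily in
descending score order, with a bounding-box IoU >= 0.2 criterion for a true
positive.  From the pooled counts:

* ``TPR = TP / (TP + FN)`` — sensitivity over ground-truth masses,
* ``fp_per_image = FP / n_images`` — the false-positive rate reported as
  "FPPI" in results tables,
* ``false_discovery_fraction = FP / (TP + FP)`` — the complementary
  precision-style ratio, bounded by 1, kept as a separate export,
* ``Dice = 2 TP / (2 TP + FP + FN)`` — per image, on pixels, between the
  union of predicted instance masks and the full truth mask.

Cross-run aggregation uses the arithmetic mean and the *sample* standard
deviation (n - 1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mammopart.boxes import Box, box_area, mask_tight_box, validate_box
from mammopart.dataio import LesionMask
from mammopart.errors import ValidationError

DEFAULT_IOU_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# Box IoU and matching
# ---------------------------------------------------------------------------


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open boxes, in pixel areas."""
    a = validate_box(a)
    b = validate_box(b)
    r0 = max(a[0], b[0])
    c0 = max(a[1], b[1])
    r1 = min(a[2], b[2])
    c1 = min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    union = box_area(a) + box_area(b) - inter
    return inter / union


@dataclass
class MatchResult:
    """One image's detection/truth matching outcome."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (det, truth, IoU)
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            pairs=self.pairs + other.pairs,
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


def _truth_boxes(truth) -> list[Box]:
    if isinstance(truth, LesionMask):
        masks = truth.instances()
    else:
        masks = list(truth)
    boxes = []
    for m in masks:
        arr = np.asarray(m)
        if arr.ndim == 2:
            boxes.append(mask_tight_box(arr))
        else:
            boxes.append(validate_box(tuple(arr)))
    return boxes


def match_detections(
    detections,
    truth,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    *,
    maximum_matching: bool = False,
) -> MatchResult:
    """Match one image's detections against its ground-truth masses.

    ``detections`` is a :class:`~mammopart.detector.DetectionSet` (or any
    object with sorted ``instances``); ``truth`` a :class:`LesionMask` or a
    list of per-instance binary masks / boxes.  Greedy matching walks
    detections in descending score order, each taking the highest-IoU still
    unmatched truth with IoU >= threshold.  ``maximum_matching=True``
    instead maximizes the number of matched pairs (used as a cross-check;
    greedy can in principle fall below the maximum).
    """
    if not 0 < iou_threshold <= 1:
        raise ValidationError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    det_boxes = [validate_box(inst.box) for inst in detections.instances]
    truth_boxes = _truth_boxes(truth)
    n_det, n_truth = len(det_boxes), len(truth_boxes)
    iou = np.zeros((n_det, n_truth))
    for i, db in enumerate(det_boxes):
        for j, tb in enumerate(truth_boxes):
            iou[i, j] = box_iou(db, tb)
    eligible = iou >= iou_threshold

    pairs: list[tuple[int, int, float]] = []
    if maximum_matching and n_det and n_truth:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        graph = csr_matrix(eligible.astype(np.int8))
        col_for_row = maximum_bipartite_matching(graph, perm_type="column")
        for i, j in enumerate(col_for_row):
            if j >= 0:
                pairs.append((i, int(j), float(iou[i, j])))
    else:
        taken = np.zeros(n_truth, dtype=bool)
        for i in range(n_det):  # instances already sorted by descending score
            candidates = np.flatnonzero(eligible[i] & ~taken)
            if candidates.size == 0:
                continue
            j = int(candidates[np.argmax(iou[i, candidates])])
            taken[j] = True
            pairs.append((i, j, float(iou[i, j])))

    tp = len(pairs)
    return MatchResult(pairs=pairs, tp=tp, fp=n_det - tp, fn=n_truth - tp)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def dice_score(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Pixelwise Dice between a (union) predicted mask and the truth mask.

    Both masks empty returns 1.0 by convention (nothing to find, nothing
    found).
    """
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(pred.sum()) - tp
    fn = int(truth.sum()) - tp
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


# ---------------------------------------------------------------------------
# Per-run summaries and cross-run aggregation
# ---------------------------------------------------------------------------


@dataclass
class MetricSummary:
    """One experiment run's metrics over its test set."""

    tpr: float
    fp_per_image: float
    false_discovery_fraction: float
    dice_mean: float
    dice_std: float
    n_images: int
    tp: int = 0
    fp: int = 0
    fn: int = 0


def summarize_run(
    matches: list[MatchResult],
    dices: list[float | None],
    *,
    macro_tpr: bool = False,
) -> MetricSummary:
    """Pool per-image match results and Dice scores into one summary.

    TPR pools TP/FN counts over the whole test set (micro average;
    ``macro_tpr=True`` averages per-image TPRs over images that contain at
    least one truth instance).  Dice statistics are taken over images with
    at least one truth mass only — entries of ``dices`` for mass-free
    images should be None and are excluded.
    """
    if not matches:
        raise ValidationError("summarize_run needs at least one test image")
    if len(dices) != len(matches):
        raise ValidationError("matches and dices must align per image")
    total = MatchResult()
    for m in matches:
        total = total + m
    n_truth = total.tp + total.fn
    if n_truth == 0:
        raise ValidationError("no ground-truth mass in the whole test set; TPR undefined")
    if macro_tpr:
        per_image = [
            m.tp / (m.tp + m.fn) for m in matches if (m.tp + m.fn) > 0
        ]
        tpr = float(np.mean(per_image))
    else:
        tpr = total.tp / n_truth
    n_images = len(matches)
    dice_values = np.array([d for d in dices if d is not None], dtype=float)
    if dice_values.size == 0:
        raise ValidationError("no image with a truth mass has a Dice value")
    dice_std = float(np.std(dice_values, ddof=1)) if dice_values.size > 1 else 0.0
    n_det = total.tp + total.fp
    return MetricSummary(
        tpr=float(tpr),
        fp_per_image=total.fp / n_images,
        false_discovery_fraction=(total.fp / n_det) if n_det else 0.0,
        dice_mean=float(dice_values.mean()),
        dice_std=dice_std,
        n_images=n_images,
        tp=total.tp,
        fp=total.fp,
        fn=total.fn,
    )


@dataclass
class AggregateRow:
    """Mean and sample SD (n-1) of each metric across experiment repeats."""

    tpr_mean: float
    tpr_std: float
    fppi_mean: float
    fppi_std: float
    dice_mean_mean: float
    dice_mean_std: float
    dice_std_mean: float
    dice_std_std: float
    n_runs: int


def aggregate_runs(summaries: list[MetricSummary]) -> AggregateRow:
    """Aggregate >= 2 per-run summaries elementwise (mean, sample SD)."""
    if len(summaries) < 2:
        raise ValidationError("aggregate_runs needs at least 2 runs")

    def stats(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1))

    tpr_mean, tpr_std = stats([s.tpr for s in summaries])
    fppi_mean, fppi_std = stats([s.fp_per_image for s in summaries])
    dm_mean, dm_std = stats([s.dice_mean for s in summaries])
    ds_mean, ds_std = stats([s.dice_std for s in summaries])
    return AggregateRow(
        tpr_mean=tpr_mean,
        tpr_std=tpr_std,
        fppi_mean=fppi_mean,
        fppi_std=fppi_std,
        dice_mean_mean=dm_mean,
        dice_mean_std=dm_std,
        dice_std_mean=ds_mean,
        dice_std_std=ds_std,
        n_runs=len(summaries),
    )


def format_row(summary: MetricSummary) -> str:
    """Presentation rounding: 3 decimals for TPR/Dice, 2 for FPPI."""
    return (
        f"{summary.tpr:.3f} @ {summary.fp_per_image:.2f}"
        f"\t{summary.dice_mean:.3f} ± {summary.dice_std:.3f}"
    )


def format_aggregate(row: AggregateRow) -> tuple[str, str]:
    avg = (
        f"{row.tpr_mean:.3f} @ {row.fppi_mean:.2f}"
        f"\t{row.dice_mean_mean:.3f} ± {row.dice_std_mean:.3f}"
    )
    std = (
        f"{row.tpr_std:.3f} @ {row.fppi_std:.2f}"
        f"\t{row.dice_mean_std:.3f} ± {row.dice_std_std:.3f}"
    )
    return avg, std
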