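"""Detector contract and a trainable classical baseline.

The pipeline is detector-agnostic: anything that maps a pseudo-color
mammogram to a :class:`DetectionSet` (scored boxes + instance masks) plugs
in.  The package ships a deliberately simple, fully deterministic baseline
that thresholds a weighted combination of the two MMS channels (G and B —
the lesion-enhanced signals; the raw grayscale R channel is excluded so the
baseline measures what the pseudo-color transform adds), extracts
8-connected components, and keeps components whose pixel area lies in a
fitted range.  Its three knobs (response threshold, channel weights, area
range) are fitted by exhaustive grid search.

External adapter contract
-------------------------
An external model (e.g. an instance-segmentation network) integrates by
implementing ``adapter(pcm: PseudoColorImage) -> DetectionSet`` on
1024x1024-resized PCMs.  The boundary validator below enforces the
contract: boxes inside image bounds, nonempty masks contained in their
boxes, scores in [0, 1]; unsorted instances are re-sorted on ingestion and
malformed sets are rejected.  The evaluation stage treats adapter output
identically to baseline output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from mammopart.boxes import Box, box_in_bounds, mask_in_box, mask_tight_box, validate_box
from mammopart.dataio import LesionMask
from mammopart.errors import ValidationError
from mammopart.evaluate import DEFAULT_IOU_THRESHOLD, box_iou
from mammopart.mms_pcm import PseudoColorImage


@dataclass
class Instance:
    """One detected mass: box, binary mask (full image shape), score in [0, 1]."""

    box: Box
    mask: np.ndarray
    score: float

    def __post_init__(self) -> None:
        self.box = validate_box(self.box)
        self.mask = np.asarray(self.mask).astype(bool)
        if not 0 <= self.score <= 1:
            raise ValidationError(f"score {self.score} outside [0, 1]")


@dataclass
class DetectionSet:
    """All detections for one image, sorted by descending score."""

    image_id: str
    instances: list[Instance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.instances = sorted(self.instances, key=lambda i: -i.score)

    def __len__(self) -> int:
        return len(self.instances)

    def union_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Union of all instance masks (all-zero array of ``shape`` if empty)."""
        if not self.instances:
            if shape is None:
                raise ValidationError("empty DetectionSet needs an explicit shape")
            return np.zeros(shape, dtype=bool)
        out = np.zeros(self.instances[0].mask.shape, dtype=bool)
        for inst in self.instances:
            out |= inst.mask
        return out


def validate_detection_set(det: DetectionSet, image_shape: tuple[int, int]) -> DetectionSet:
    """Boundary validator for externally produced detections."""
    for inst in det.instances:
        if not box_in_bounds(inst.box, image_shape):
            raise ValidationError(
                f"{det.image_id}: box {inst.box} outside image {image_shape}"
            )
        if inst.mask.shape != tuple(image_shape):
            raise ValidationError(
                f"{det.image_id}: mask shape {inst.mask.shape} != image {image_shape}"
            )
        if not inst.mask.any():
            raise ValidationError(f"{det.image_id}: empty instance mask")
        if not mask_in_box(inst.mask, inst.box):
            raise ValidationError(f"{det.image_id}: mask escapes its box")
    # DetectionSet re-sorts on construction; rebuilding normalizes ordering.
    return DetectionSet(image_id=det.image_id, instances=det.instances)


def oracle_adapter(truth: LesionMask) -> DetectionSet:
    """Adapter that returns the ground truth as detections (score 1.0).

    Running it through the full pipeline must give TPR 1.0, 0 FP/image and
    Dice 1.0 — the regression test that isolates evaluation correctness
    from detection quality."""
    instances = [
        Instance(box=mask_tight_box(m), mask=m, score=1.0) for m in truth.instances()
    ]
    return DetectionSet(image_id=truth.image_id, instances=instances)


# ---------------------------------------------------------------------------
# Baseline model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineModel:
    """Threshold/area-filter detector over the combined MMS channels."""

    response_threshold: float  # in (0, 1], on the per-image normalized response
    area_range_px: tuple[int, int]
    channel_weights: tuple[float, float]  # (wG, wB), nonnegative, sum 1

    def __post_init__(self) -> None:
        if not 0 < self.response_threshold <= 1:
            raise ValidationError("response_threshold must be in (0, 1]")
        lo, hi = self.area_range_px
        if not 0 < lo < hi:
            raise ValidationError(f"area_range_px must be increasing, got {self.area_range_px}")
        wg, wb = self.channel_weights
        if wg < 0 or wb < 0 or abs(wg + wb - 1.0) > 1e-9:
            raise ValidationError("channel_weights must be nonnegative and sum to 1")


def _combined_response(model_weights: tuple[float, float], pcm: PseudoColorImage) -> np.ndarray:
    """Weighted G/B combination, min-max normalized to [0, 1] per image."""
    wg, wb = model_weights
    combined = wg * pcm.g.astype(float) + wb * pcm.b.astype(float)
    lo, hi = combined.min(), combined.max()
    if hi == lo:
        return np.zeros(combined.shape)
    return (combined - lo) / (hi - lo)


def _components(response: np.ndarray, threshold: float) -> list[tuple[Box, int, float]]:
    """(box, area, mean response) of each 8-connected supra-threshold component."""
    binary = response >= threshold
    labels, n = cc_label(binary, connectivity=2, return_num=True)
    out = []
    for k in range(1, n + 1):
        comp = labels == k
        box = mask_tight_box(comp)
        out.append((box, int(comp.sum()), float(response[comp].mean())))
    return out


def detect(model: BaselineModel, pcm: PseudoColorImage) -> DetectionSet:
    """Deterministic detection: threshold the combined response, keep
    8-connected components with in-range pixel area."""
    response = _combined_response(model.channel_weights, pcm)
    binary = response >= model.response_threshold
    labels, n = cc_label(binary, connectivity=2, return_num=True)
    lo, hi = model.area_range_px
    instances = []
    for k in range(1, n + 1):
        comp = labels == k
        area = int(comp.sum())
        if not lo <= area <= hi:
            continue
        instances.append(
            Instance(
                box=mask_tight_box(comp),
                mask=comp,
                score=float(np.clip(response[comp].mean(), 0.0, 1.0)),
            )
        )
    return DetectionSet(image_id=pcm.image_id, instances=instances)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def default_grid(pixel_spacing_mm: float) -> dict:
    """A small, physically anchored search grid.

    Area-range options are the physical mass-area range converted to pixels
    at the given spacing, with a loose and a tight margin."""
    from mammopart.mms_pcm import MASS_AREA_RANGE_MM2

    lo_px = MASS_AREA_RANGE_MM2[0] / pixel_spacing_mm**2
    hi_px = MASS_AREA_RANGE_MM2[1] / pixel_spacing_mm**2
    return {
        "response_threshold": [0.45, 0.55, 0.65, 0.75],
        "channel_weights": [(1.0, 0.0), (0.5, 0.5), (0.0, 1.0)],
        "area_range_px": [
            (max(4, int(0.25 * lo_px)), int(2.0 * hi_px)),
            (max(4, int(0.75 * lo_px)), int(1.25 * hi_px)),
        ],
    }


def fit_baseline(
    train_images: list[PseudoColorImage],
    train_masks: list[LesionMask],
    grid: dict,
    seed: int = 0,
    *,
    fp_penalty: float = 0.1,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> BaselineModel:
    """Exhaustive grid search maximizing ``TPR - fp_penalty * FP-per-image``
    on the training subset.  Ties break toward the higher threshold, then
    grid order.  Fully deterministic (``seed`` is accepted for interface
    symmetry with stochastic detectors)."""
    del seed  # the baseline fit has no stochastic component
    if len(train_images) != len(train_masks):
        raise ValidationError("train_images and train_masks must align")
    truth_boxes = [
        [mask_tight_box(m) for m in msk.instances()] for msk in train_masks
    ]
    n_truth_total = sum(len(b) for b in truth_boxes)
    if n_truth_total == 0:
        raise ValidationError("fit_baseline needs at least one positive training image")

    thresholds = sorted(grid["response_threshold"])
    weight_options = list(grid["channel_weights"])
    area_options = list(grid["area_range_px"])
    n_images = len(train_images)

    best_key: tuple[float, float] | None = None
    best_model: BaselineModel | None = None
    for weights in weight_options:
        responses = [_combined_response(weights, pcm) for pcm in train_images]
        for threshold in thresholds:
            comps = [_components(resp, threshold) for resp in responses]
            for area_range in area_options:
                lo, hi = area_range
                tp = 0
                fp = 0
                for image_comps, boxes in zip(comps, truth_boxes):
                    kept = [
                        c for c in image_comps if lo <= c[1] <= hi
                    ]
                    kept.sort(key=lambda c: -c[2])  # descending score, as detect() emits
                    taken = [False] * len(boxes)
                    for box, _, _ in kept:
                        ious = [
                            box_iou(box, tb) if not taken[j] else -1.0
                            for j, tb in enumerate(boxes)
                        ]
                        if ious and max(ious) >= iou_threshold:
                            taken[int(np.argmax(ious))] = True
                            tp += 1
                        else:
                            fp += 1
                tpr = tp / n_truth_total
                objective = tpr - fp_penalty * fp / n_images
                key = (objective, threshold)
                if best_key is None or key > best_key:
                    best_key = key
                    best_model = BaselineModel(
                        response_threshold=threshold,
                        area_range_px=tuple(area_range),
                        channel_weights=tuple(weights),
                    )
    assert best_model is not None
    return best_model
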