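"""Geometric and intensity preprocessing of mammograms.

The chain mirrors the usual preparation of full-field digital mammograms
whose background is exactly zero:

1. crop to the tight bounding box of the nonzero (breast) pixels,
2. resize to one fourth of the original size (area interpolation),
3. min-max normalize to the 16-bit range,
4. pad to a square, anchoring the breast to its chest-wall side.

Every step records enough geometry (crop box, scale factor, padding) to map
output coordinates back to the original image, and the same geometry can be
replayed on a lesion mask (without the intensity normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mammopart.boxes import Box
from mammopart.dataio import LesionMask, Mammogram
from mammopart.errors import ValidationError

#: Ordered augmentation menu. Flip-up and flip-down are both a vertical flip
#: and flip-left/right both a horizontal flip; the menu keeps all four named
#: entries so random sampling is over the 7 named operations.
AUGMENT_OPS = (
    "flip-up",
    "flip-down",
    "flip-left",
    "flip-right",
    "rot90",
    "rot180",
    "rot270",
)


@dataclass
class PreprocessedImage:
    """Result of the crop → resize → normalize → pad chain."""

    image_id: str
    pixels: np.ndarray  # square, integer, in [0, 65535]
    crop_box: Box  # in original coordinates
    scale_factor: float  # output px per input px (before padding)
    pad: tuple[int, int, int, int]  # top, bottom, left, right

    def to_original(self, r: float, c: float) -> tuple[float, float]:
        """Map an output (padded) coordinate back to original coordinates."""
        top, _, left, _ = self.pad
        return (
            (r - top) / self.scale_factor + self.crop_box[0],
            (c - left) / self.scale_factor + self.crop_box[1],
        )


# ---------------------------------------------------------------------------
# Chain steps
# ---------------------------------------------------------------------------


def crop_breast_region(image: Mammogram | np.ndarray) -> tuple[np.ndarray, Box]:
    """Extract the tight bounding box of all nonzero pixels."""
    pixels = image.pixels if isinstance(image, Mammogram) else np.asarray(image)
    rows = np.flatnonzero(pixels.any(axis=1))
    cols = np.flatnonzero(pixels.any(axis=0))
    if rows.size == 0:
        raise ValidationError("empty breast: image has no nonzero pixel")
    box: Box = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    return pixels[box[0] : box[2], box[1] : box[3]].copy(), box


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) matrix of fractional pixel coverages for 1-D area resize.

    Output pixel j covers the input interval [j*n_in/n_out, (j+1)*n_in/n_out);
    the weight of input pixel i is its overlap with that interval, normalized
    by the interval length actually inside the image (so edge pixels of a
    non-integer ratio are true means, not zero-padded means).
    """
    scale = n_in / n_out
    weights = np.zeros((n_out, n_in))
    for j in range(n_out):
        lo, hi = j * scale, min((j + 1) * scale, n_in)
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, i1):
            weights[j, i] = min(hi, i + 1) - max(lo, i)
        weights[j] /= hi - lo
    return weights


def resize_area(pixels: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Exact area (local-mean) interpolation to ``out_shape`` (float output)."""
    arr = np.asarray(pixels, dtype=float)
    h_in, w_in = arr.shape
    h_out, w_out = out_shape
    if h_in % h_out == 0 and w_in % w_out == 0:
        # integer factors: plain block means, no weight matrices needed
        fr, fc = h_in // h_out, w_in // w_out
        return arr.reshape(h_out, fr, w_out, fc).mean(axis=(1, 3))
    wr = _area_weights(h_in, h_out)
    wc = _area_weights(w_in, w_out)
    return wr @ arr @ wc.T


def resize_quarter(pixels: np.ndarray) -> np.ndarray:
    """Downscale by 4 in each dimension with area interpolation.

    Output dimensions are ``ceil(dim / 4)``; the output is rounded back to
    the input's integer dtype so dynamic range is preserved.
    """
    arr = np.asarray(pixels)
    if arr.shape[0] < 4 or arr.shape[1] < 4:
        raise ValidationError(f"image {arr.shape} too small to quarter-resize")
    out_shape = (-(-arr.shape[0] // 4), -(-arr.shape[1] // 4))
    resized = resize_area(arr, out_shape)
    if np.issubdtype(arr.dtype, np.integer):
        return np.rint(resized).astype(arr.dtype)
    return resized


def resize_mask_quarter(mask: np.ndarray) -> np.ndarray:
    """Quarter-resize a binary mask: area interpolation then re-binarize at 0.5."""
    arr = np.asarray(mask).astype(float)
    if arr.shape[0] < 4 or arr.shape[1] < 4:
        raise ValidationError(f"mask {arr.shape} too small to quarter-resize")
    out_shape = (-(-arr.shape[0] // 4), -(-arr.shape[1] // 4))
    return resize_area(arr, out_shape) >= 0.5


def normalize_16bit(pixels: np.ndarray) -> np.ndarray:
    """Affinely map [min, max] onto [0, 65535], rounding half-to-even.

    A constant image maps to all zeros (degenerate range).
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot normalize an empty array")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint16)
    return np.rint((arr - lo) * (65535.0 / (hi - lo))).astype(np.uint16)


def pad_square(
    pixels: np.ndarray, breast_side: str = "L"
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Zero-pad to a square of side ``max(h, w)``.

    The breast stays anchored to its chest-wall side: an L breast touches
    the left edge (padding goes right), an R breast the right edge. Vertical
    padding is split evenly (extra row at the bottom).
    """
    if breast_side not in ("L", "R"):
        raise ValidationError(f"breast_side must be 'L' or 'R', got {breast_side!r}")
    arr = np.asarray(pixels)
    h, w = arr.shape
    side = max(h, w)
    top = (side - h) // 2
    bottom = side - h - top
    left, right = (0, side - w) if breast_side == "L" else (side - w, 0)
    out = np.pad(arr, ((top, bottom), (left, right)))
    return out, (top, bottom, left, right)


def preprocess_image(image: Mammogram) -> PreprocessedImage:
    """Run the full crop → quarter-resize → normalize → pad chain."""
    cropped, crop_box = crop_breast_region(image)
    resized = resize_quarter(cropped)
    normalized = normalize_16bit(resized)
    padded, pad = pad_square(normalized, image.laterality or "L")
    return PreprocessedImage(
        image_id=image.image_id,
        pixels=padded,
        crop_box=crop_box,
        scale_factor=resized.shape[0] / cropped.shape[0],
        pad=pad,
    )


def preprocess_mask(mask: LesionMask, reference: PreprocessedImage, breast_side: str = "L") -> np.ndarray:
    """Replay an image's geometry (crop, resize, pad) on its lesion mask."""
    r0, c0, r1, c1 = reference.crop_box
    cropped = mask.mask[r0:r1, c0:c1]
    resized = resize_mask_quarter(cropped)
    padded, _ = pad_square(resized.astype(np.uint8), breast_side)
    return padded.astype(bool)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _apply_op(arr: np.ndarray, op: str) -> np.ndarray:
    axes = (0, 1)  # spatial axes; channel axis (if any) untouched
    if op in ("flip-up", "flip-down"):
        return np.flip(arr, axis=0)
    if op in ("flip-left", "flip-right"):
        return np.flip(arr, axis=1)
    if op == "rot90":
        return np.rot90(arr, 1, axes=axes)
    if op == "rot180":
        return np.rot90(arr, 2, axes=axes)
    if op == "rot270":
        return np.rot90(arr, 3, axes=axes)
    raise ValidationError(f"unknown augmentation op {op!r}")


def augment(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    op_id: int | None = None,
    rng_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one of the 7 named flip/rotation operations to image and mask.

    ``op_id`` indexes :data:`AUGMENT_OPS`; when absent an operation is drawn
    uniformly using ``rng_seed``. Image and mask receive the identical
    spatial transform.
    """
    if op_id is None:
        rng = np.random.default_rng(rng_seed)
        op_id = int(rng.integers(len(AUGMENT_OPS)))
    if not 0 <= op_id < len(AUGMENT_OPS):
        raise ValidationError(f"op_id {op_id} outside 0..{len(AUGMENT_OPS) - 1}")
    op = AUGMENT_OPS[op_id]
    out_image = _apply_op(np.asarray(image), op).copy()
    out_mask = None if mask is None else _apply_op(np.asarray(mask), op).copy()
    return out_image, out_mask


def augment_dataset(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    rng_seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Double a set of (image, mask) pairs by adding one random augmentation
    of each pair. Originals come first, in order."""
    rng = np.random.default_rng(rng_seed)
    out_images = list(images)
    out_masks = list(masks)
    for img, msk in zip(images, masks):
        op_id = int(rng.integers(len(AUGMENT_OPS)))
        aug_img, aug_msk = augment(img, msk, op_id=op_id)
        out_images.append(aug_img)
        out_masks.append(aug_msk)
    return out_images, out_masks
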