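"""Reading and writing of the pipeline's on-disk formats.

Formats handled here:

* **manifest** — a UTF-8 CSV with one row per image linking ``image_id`` to
  ``case_id``, laterality (L/R), view (CC/MLO), file paths and pixel spacing;
* **mammograms** — DICOM, or 16-bit single-channel PNG/TIFF;
* **lesion masks** — single-channel PNG, 0 = background, nonzero = lesion,
  distinct integers = distinct mass instances;
* **detections** — JSON with per-instance run-length-encoded masks.

Reading never rescales pixel values.  Boxes follow the package convention:
row-major, 0-based, half-open ``[r0, c0, r1, c1)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from mammopart.boxes import Box, box_in_bounds, mask_in_box, validate_box
from mammopart.errors import FormatError, ValidationError

MANIFEST_COLUMNS = [
    "image_id",
    "case_id",
    "laterality",
    "view",
    "image_path",
    "mask_path",
    "pixel_spacing_mm",
]

_LATERALITIES = {"L", "R"}
_VIEWS = {"CC", "MLO"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifestRecord:
    image_id: str
    case_id: str
    laterality: str
    view: str
    image_path: str
    mask_path: str | None
    pixel_spacing_mm: float


@dataclass
class Manifest:
    """A validated image/case manifest.

    Invariants (enforced by :meth:`validate`): unique ``image_id``; 1–4
    images per case with unique (laterality, view) pairs; positive pixel
    spacing.
    """

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def image_ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    @property
    def case_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.case_id, None)
        return list(seen)

    def by_case(self) -> dict[str, list[ManifestRecord]]:
        out: dict[str, list[ManifestRecord]] = {}
        for r in self.records:
            out.setdefault(r.case_id, []).append(r)
        return out

    def record(self, image_id: str) -> ManifestRecord:
        for r in self.records:
            if r.image_id == image_id:
                return r
        raise KeyError(image_id)

    def validate(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate image_id(s): {dupes}")
        for case_id, recs in self.by_case().items():
            if not 1 <= len(recs) <= 4:
                raise ValidationError(
                    f"case {case_id!r} has {len(recs)} images; expected 1-4"
                )
            pairs = [(r.laterality, r.view) for r in recs]
            if len(set(pairs)) != len(pairs):
                raise ValidationError(
                    f"case {case_id!r} repeats a (laterality, view) pair"
                )
        for r in self.records:
            if r.laterality not in _LATERALITIES:
                raise ValidationError(f"bad laterality {r.laterality!r}")
            if r.view not in _VIEWS:
                raise ValidationError(f"bad view {r.view!r}")
            if not r.pixel_spacing_mm > 0:
                raise ValidationError(
                    f"pixel_spacing_mm must be > 0, got {r.pixel_spacing_mm}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": r.image_id,
                "case_id": r.case_id,
                "laterality": r.laterality,
                "view": r.view,
                "image_path": r.image_path,
                "mask_path": "" if r.mask_path is None else r.mask_path,
                "pixel_spacing_mm": r.pixel_spacing_mm,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


@dataclass
class Mammogram:
    """One grayscale mammogram in native detector units.

    Background (non-breast) pixels are exactly 0; all values are
    nonnegative and below ``2**bit_depth``.
    """

    image_id: str
    pixels: np.ndarray
    bit_depth: int
    pixel_spacing_mm: float | None = None
    laterality: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("mammogram pixels must be a 2-D array")
        if not 8 <= self.bit_depth <= 16:
            raise ValidationError(f"bit_depth {self.bit_depth} out of range 8-16")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("mammogram pixels must be nonnegative")
        if self.pixels.size and self.pixels.max() >= 2**self.bit_depth:
            raise ValidationError(
                f"pixel values exceed 2**{self.bit_depth} - 1"
            )


@dataclass
class LesionMask:
    """Binary lesion mask paired with an image, plus optional instance labels."""

    image_id: str
    mask: np.ndarray
    instance_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be a 2-D array")
        if self.instance_labels is not None:
            self.instance_labels = np.asarray(self.instance_labels)
            if self.instance_labels.shape != self.mask.shape:
                raise ValidationError("instance_labels shape differs from mask")
            if bool(np.any((self.instance_labels > 0) != self.mask)):
                raise ValidationError("instance_labels support differs from mask")

    def instances(self) -> list[np.ndarray]:
        """Per-mass boolean masks; one entry per instance label (or one for
        the whole mask if no labels were provided and the mask is nonempty)."""
        if self.instance_labels is None:
            return [self.mask.copy()] if self.mask.any() else []
        labels = np.unique(self.instance_labels)
        return [self.instance_labels == v for v in labels if v > 0]


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a CSV manifest."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"image_id": str, "case_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"manifest {path} is missing column(s): {missing}")
    records = []
    for row in frame.itertuples(index=False):
        mask_path = getattr(row, "mask_path")
        if mask_path is None or (isinstance(mask_path, float) and np.isnan(mask_path)):
            mask_path = None
        elif isinstance(mask_path, str) and not mask_path.strip():
            mask_path = None
        records.append(
            ManifestRecord(
                image_id=str(row.image_id),
                case_id=str(row.case_id),
                laterality=str(row.laterality),
                view=str(row.view),
                image_path=str(row.image_path),
                mask_path=mask_path,
                pixel_spacing_mm=float(row.pixel_spacing_mm),
            )
        )
    return Manifest(records)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def leakage_risk_report(manifest: Manifest) -> dict:
    """Cases with more than one image — the ones a random split can leak."""
    multi = {c: [r.image_id for r in recs] for c, recs in manifest.by_case().items() if len(recs) > 1}
    return {
        "n_images": len(manifest),
        "n_cases": len(manifest.case_ids),
        "n_multi_image_cases": len(multi),
        "multi_image_cases": multi,
    }


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

_DICOM_SUFFIXES = {".dcm", ".dicom"}
_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


def read_image(
    path: str | Path,
    *,
    image_id: str | None = None,
    pixel_spacing_mm: float | None = None,
) -> Mammogram:
    """Read a mammogram from DICOM or 16-bit PNG/TIFF.

    DICOM pixel spacing, when present, is preferred over the
    ``pixel_spacing_mm`` argument (typically the manifest value); a
    disagreement of more than 1% triggers a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _DICOM_SUFFIXES:
        return _read_dicom(path, image_id=image_id, manifest_spacing=pixel_spacing_mm)
    if suffix in _RASTER_SUFFIXES:
        return _read_raster(path, image_id=image_id, pixel_spacing_mm=pixel_spacing_mm)
    raise FormatError(f"unsupported image format: {path.name!r}")


def _read_dicom(path: Path, *, image_id: str | None, manifest_spacing: float | None) -> Mammogram:
    import pydicom

    ds = pydicom.dcmread(str(path))
    pixels = np.asarray(ds.pixel_array)
    if pixels.ndim != 2:
        raise FormatError(f"{path.name}: expected a single-frame grayscale DICOM")
    bit_depth = int(getattr(ds, "BitsStored", 16))
    spacing = None
    tag = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if tag is not None:
        spacing = float(tag[0])
        if manifest_spacing is not None and abs(spacing - manifest_spacing) > 0.01 * manifest_spacing:
            warnings.warn(
                f"{path.name}: DICOM pixel spacing {spacing} differs >1% from "
                f"manifest value {manifest_spacing}; using the DICOM value",
                stacklevel=3,
            )
    if spacing is None:
        spacing = manifest_spacing
    return Mammogram(
        image_id=image_id or path.stem,
        pixels=pixels,
        bit_depth=bit_depth,
        pixel_spacing_mm=spacing,
    )


def _read_raster(path: Path, *, image_id: str | None, pixel_spacing_mm: float | None) -> Mammogram:
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "P"):
            raise FormatError(f"{path.name}: mammograms must be single-channel, got mode {im.mode}")
        if im.mode not in ("I", "I;16", "I;16B", "I;16L"):
            raise FormatError(
                f"{path.name}: expected a 16-bit image, got mode {im.mode}"
            )
        pixels = np.asarray(im, dtype=np.uint16)
    return Mammogram(
        image_id=image_id or path.stem,
        pixels=pixels,
        bit_depth=16,
        pixel_spacing_mm=pixel_spacing_mm,
    )


def write_image_16bit(pixels: np.ndarray, path: str | Path) -> None:
    """Write a 2-D integer array in [0, 65535] as a 16-bit grayscale PNG/TIFF."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D array")
    if arr.size and (arr.min() < 0 or arr.max() > 65535):
        raise ValidationError("pixel values out of the 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(str(path))


def write_rgb8(channels: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 array as an RGB PNG."""
    arr = np.asarray(channels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) array")
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(str(path))


def read_mask(path: str | Path, *, image_id: str | None = None) -> LesionMask:
    """Read a single-channel PNG mask; distinct nonzero values = instances."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            raise FormatError(f"{path.name}: masks must be single-channel")
        labels = np.asarray(im).astype(np.int32)
    return LesionMask(image_id=image_id or path.stem, mask=labels > 0, instance_labels=labels)


def write_mask(mask: LesionMask, path: str | Path) -> None:
    labels = mask.instance_labels
    if labels is None:
        labels = mask.mask.astype(np.int32)
    if labels.max(initial=0) > 255:
        raise ValidationError("more than 255 instances cannot be stored as 8-bit PNG")
    Image.fromarray(labels.astype(np.uint8), mode="L").save(str(path))


# ---------------------------------------------------------------------------
# Detection serialization (JSON + run-length encoded masks)
# ---------------------------------------------------------------------------


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a binary mask (row-major, [start, length] pairs)."""
    flat = np.asarray(mask).astype(bool).ravel()
    # transitions between runs of 0s and 1s
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    runs = [[int(s), int(e - s)] for s, e in zip(starts, ends)]
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(encoded: dict) -> np.ndarray:
    shape = tuple(encoded["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in encoded["runs"]:
        flat[start : start + length] = True
    return flat.reshape(shape)


def write_detections(detections: list, path: str | Path) -> None:
    """Serialize a list of :class:`~mammopart.detector.DetectionSet` to JSON."""
    payload = []
    for det in detections:
        image_payload = {"image_id": det.image_id, "instances": []}
        for inst in det.instances:
            box = validate_box(inst.box)
            if not box_in_bounds(box, inst.mask.shape):
                raise ValidationError(
                    f"{det.image_id}: box {box} outside image bounds {inst.mask.shape}"
                )
            if inst.mask.any() and not mask_in_box(inst.mask, box):
                raise ValidationError(f"{det.image_id}: mask escapes its box")
            image_payload["instances"].append(
                {
                    "box": list(box),
                    "score": float(inst.score),
                    "mask": rle_encode(inst.mask),
                }
            )
        payload.append(image_payload)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_detections(path: str | Path) -> list:
    """Inverse of :func:`write_detections`."""
    from mammopart.detector import DetectionSet, Instance

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    out = []
    for image_payload in payload:
        instances = [
            Instance(
                box=tuple(entry["box"]),
                mask=rle_decode(entry["mask"]),
                score=float(entry["score"]),
            )
            for entry in image_payload["instances"]
        ]
        out.append(DetectionSet(image_id=image_payload["image_id"], instances=instances))
    return out
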