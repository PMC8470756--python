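"""Multi-scale morphological sifting (MMS) and pseudo-color assembly.

MMS is a band-pass granulometric sieve built from grayscale openings with
oriented linear (1-pixel-thick) structuring elements.  Opening with a line
of length L, maximized over orientations, preserves bright structures that
can contain a line of length L at *some* orientation and suppresses
narrower ones; the difference of two such openings (short minus long SE)
therefore enhances bright blobs whose diameter lies between the two SE
lengths — the size signature of a mass.

The sieve runs at two scales whose target mass-area intervals partition the
physical mass-size range; the pseudo-color mammogram (PCM) packs the
grayscale mammogram into the red channel and the two band responses into
green (scale 1, smaller masses) and blue (scale 2, larger masses).  Small
masses hence tend to yellow (R+G), large ones to purple (R+B).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, hypot, pi, sqrt

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import line as draw_line

from mammopart.errors import ConfigError, ValidationError

#: Physical mass-area range (mm^2) the two scales must jointly cover, and
#: the boundary between them (the mean mass area of the target population).
MASS_AREA_RANGE_MM2 = (15.0, 3689.0)
MASS_AREA_SPLIT_MM2 = 479.0

DEFAULT_N_ORIENTATIONS = 12


@dataclass(frozen=True)
class SieveScale:
    """One MMS scale: a band of structuring-element lengths (pixels) tied to
    a physical mass-area interval (mm^2)."""

    scale_index: int  # 1 or 2
    se_length_lower_px: int
    se_length_upper_px: int
    n_orientations: int
    target_mass_area_mm2: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale_index not in (1, 2):
            raise ConfigError("scale_index must be 1 or 2")
        if not 0 < self.se_length_lower_px < self.se_length_upper_px:
            raise ConfigError(
                "need 0 < se_length_lower_px < se_length_upper_px, got "
                f"{self.se_length_lower_px} and {self.se_length_upper_px}"
            )
        if self.n_orientations < 1:
            raise ConfigError("n_orientations must be >= 1")
        lo, hi = self.target_mass_area_mm2
        if not 0 < lo < hi:
            raise ConfigError("target_mass_area_mm2 must be an increasing positive pair")


def equivalent_diameter_px(area_mm2: float, pixel_spacing_mm: float) -> float:
    """Diameter (px) of a disk with the given physical area."""
    return 2.0 * sqrt(area_mm2 / pi) / pixel_spacing_mm


def _round_odd(x: float) -> int:
    return max(1, 2 * int(round((x - 1) / 2)) + 1)


def scales_from_spacing(
    pixel_spacing_mm: float,
    *,
    area_range_mm2: tuple[float, float] = MASS_AREA_RANGE_MM2,
    area_split_mm2: float = MASS_AREA_SPLIT_MM2,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
) -> tuple[SieveScale, SieveScale]:
    """Derive the two sieve scales for images at the given pixel spacing.

    SE lengths are the equivalent diameters of the interval endpoints,
    rounded to odd integers.  Scale 1 covers [low, split] mm^2, scale 2
    [split, high]; together they cover the full physical mass range.
    """
    lo, hi = area_range_mm2
    if not lo < area_split_mm2 < hi:
        raise ConfigError("area_split_mm2 must lie inside area_range_mm2")
    d_lo = _round_odd(equivalent_diameter_px(lo, pixel_spacing_mm))
    d_mid = _round_odd(equivalent_diameter_px(area_split_mm2, pixel_spacing_mm))
    d_hi = _round_odd(equivalent_diameter_px(hi, pixel_spacing_mm))
    if not d_lo < d_mid < d_hi:
        raise ConfigError(
            f"pixel spacing {pixel_spacing_mm} mm gives degenerate SE lengths "
            f"({d_lo}, {d_mid}, {d_hi}); scales are not resolvable"
        )
    scale1 = SieveScale(1, d_lo, d_mid, n_orientations, (lo, area_split_mm2))
    scale2 = SieveScale(2, d_mid, d_hi, n_orientations, (area_split_mm2, hi))
    return scale1, scale2


# ---------------------------------------------------------------------------
# Oriented openings and band responses
# ---------------------------------------------------------------------------


def line_footprint(length: int, angle_rad: float) -> np.ndarray:
    """1-pixel-thick linear structuring element of ``length`` pixels end to
    end, centered, at the given angle."""
    if length < 1:
        raise ValidationError("se length must be >= 1")
    if length == 1:
        return np.ones((1, 1), dtype=bool)
    half = (length - 1) / 2.0
    dr = half * np.sin(angle_rad)
    dc = half * np.cos(angle_rad)
    c = int(ceil(abs(dr) if abs(dr) > abs(dc) else abs(dc)))
    fp = np.zeros((2 * c + 1, 2 * c + 1), dtype=bool)
    r1, c1 = int(round(c + dr)), int(round(c + dc))
    rr, cc = draw_line(2 * c - r1, 2 * c - c1, r1, c1)
    fp[rr, cc] = True
    fp[c, c] = True  # origin always included
    return fp


def orientation_angles(n_orientations: int) -> np.ndarray:
    """``n`` equally spaced angles in [0, pi)."""
    return np.arange(n_orientations) * (pi / n_orientations)


def oriented_opening_max(
    pixels: np.ndarray, se_length_px: int, n_orientations: int = DEFAULT_N_ORIENTATIONS
) -> np.ndarray:
    """Pointwise maximum over orientations of grayscale opening with a
    linear SE of the given length.

    Anti-extensive for nonnegative input: the result never exceeds the
    input (openings are computed against a zero-valued exterior, matching
    the zero-background convention of the mammograms).
    """
    arr = np.asarray(pixels, dtype=float)
    if se_length_px < 1:
        raise ValidationError("se_length_px must be >= 1")
    if se_length_px > hypot(*arr.shape):
        raise ValidationError(
            f"se_length_px {se_length_px} exceeds the image diagonal"
        )
    if se_length_px == 1:
        return arr.copy()
    out = np.full(arr.shape, -np.inf)
    for angle in orientation_angles(n_orientations):
        fp = line_footprint(se_length_px, angle)
        opened = ndi.grey_opening(arr, footprint=fp, mode="constant", cval=0.0)
        np.maximum(out, opened, out=out)
    return out


def mms_band(
    pixels: np.ndarray, scale: SieveScale
) -> np.ndarray:
    """Band response of one sieve scale: opening at the lower SE length
    minus opening at the upper SE length, clamped at 0.

    Structures narrower than the lower length are removed by both openings;
    structures wider than the upper length survive both; only the in-band
    sizes remain."""
    lower = oriented_opening_max(pixels, scale.se_length_lower_px, scale.n_orientations)
    upper = oriented_opening_max(pixels, scale.se_length_upper_px, scale.n_orientations)
    return np.clip(lower - upper, 0.0, None)


# ---------------------------------------------------------------------------
# Pseudo-color assembly
# ---------------------------------------------------------------------------


@dataclass
class PseudoColorImage:
    """3-channel 8-bit image: R = grayscale mammogram, G = MMS scale 1,
    B = MMS scale 2 (each channel min-max scaled to 8-bit per image)."""

    image_id: str
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.r.shape, self.g.shape, self.b.shape}
        if len(shapes) != 1:
            raise ValidationError(f"channel shapes differ: {shapes}")
        for name, ch in (("r", self.r), ("g", self.g), ("b", self.b)):
            if ch.size and (ch.min() < 0 or ch.max() > 255):
                raise ValidationError(f"channel {name} outside [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    def as_array(self) -> np.ndarray:
        """(H, W, 3) uint8 view suitable for writing as RGB."""
        return np.stack([self.r, self.g, self.b], axis=-1).astype(np.uint8)

    @classmethod
    def from_array(cls, arr: np.ndarray, image_id: str = "") -> "PseudoColorImage":
        arr = np.asarray(arr)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValidationError("expected an (H, W, 3) array")
        return cls(image_id=image_id, r=arr[..., 0], g=arr[..., 1], b=arr[..., 2])


def scale_to_8bit(pixels: np.ndarray) -> np.ndarray:
    """Affinely map [min, max] onto [0, 255] (round half-to-even); a
    constant image maps to zeros."""
    arr = np.asarray(pixels, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot scale an empty array")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def assemble_pcm(
    gm: np.ndarray, band1: np.ndarray, band2: np.ndarray, image_id: str = ""
) -> PseudoColorImage:
    """Pack grayscale + two band responses into an 8-bit pseudo-color image."""
    if not (gm.shape == band1.shape == band2.shape):
        raise ValidationError(
            f"shape mismatch: {gm.shape}, {band1.shape}, {band2.shape}"
        )
    return PseudoColorImage(
        image_id=image_id,
        r=scale_to_8bit(gm),
        g=scale_to_8bit(band1),
        b=scale_to_8bit(band2),
    )


def compute_pcm(
    pixels: np.ndarray,
    scales: tuple[SieveScale, SieveScale],
    image_id: str = "",
) -> PseudoColorImage:
    """Full PCM for one preprocessed mammogram.

    The openings are evaluated on the tight bounding box of the nonzero
    region only (the zero background contributes nothing and passes through
    as zero), which keeps the morphology cost proportional to the breast.
    """
    arr = np.asarray(pixels, dtype=float)
    band1 = np.zeros_like(arr)
    band2 = np.zeros_like(arr)
    nz_rows = np.flatnonzero(arr.any(axis=1))
    nz_cols = np.flatnonzero(arr.any(axis=0))
    if nz_rows.size:
        # expand the box by the largest SE so border responses match a
        # full-image computation and the window always fits the SE
        margin = max(s.se_length_upper_px for s in scales)
        r0 = max(0, int(nz_rows[0]) - margin)
        r1 = min(arr.shape[0], int(nz_rows[-1]) + 1 + margin)
        c0 = max(0, int(nz_cols[0]) - margin)
        c1 = min(arr.shape[1], int(nz_cols[-1]) + 1 + margin)
        window = arr[r0:r1, c0:c1]
        band1[r0:r1, c0:c1] = mms_band(window, scales[0])
        band2[r0:r1, c0:c1] = mms_band(window, scales[1])
    return assemble_pcm(arr, band1, band2, image_id=image_id)
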