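"""Synthetic mammogram-like cases with correlated multi-view structure.

The generator does not attempt photorealism.  It emulates exactly the
statistical structure the partition study depends on:

* a census of cases, each contributing up to 4 views (left/right x CC/MLO),
  with a configurable share of mass-bearing cases;
* a zero-intensity background with a breast-shaped (half-ellipse)
  foreground of smooth low-frequency texture plus pixel noise;
* 1-2 masses per case, rendered in every view of the case as blurred
  anisotropic bright blobs with exact binary ground-truth masks, physical
  areas drawn log-uniformly from a configurable range;
* *intra-case correlation*: a mass's latent parameters (area, and above
  all its contrast, the "difficulty" that drives detection) are drawn once
  per case and re-realized per view with jitter controlled by
  ``intra_case_correlation`` — at 1.0 all views share identical latents, at
  0.0 views are independent.

Contrast is the correlated difficulty latent because it is what couples the
views of one case: when views of a case land on both sides of a random
train/test split, the test views are near-replicas of training material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi, sqrt

import numpy as np
import scipy.ndimage as ndi

from mammopart.dataio import LesionMask, Mammogram, Manifest, ManifestRecord
from mammopart.errors import ConfigError

#: Minimum renderable mass radius in pixels; below this the discrete mask
#: can no longer represent the requested physical area.
MIN_MASS_RADIUS_PX = 0.75


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic census.

    Defaults emulate a 115-case FFDM screening population: every case
    contributes all 4 views, 107/115 of cases carry masses, mass areas span
    15-3689 mm^2, and images are at quarter scale (0.28 mm/px, 640x832).
    Intensity parameters are fractions of the detector dynamic range.
    """

    n_cases: int = 115
    images_per_case: dict = field(default_factory=lambda: {4: 1.0})
    image_shape: tuple[int, int] = (640, 832)
    pixel_spacing_mm: float = 0.28
    p_case_has_mass: float = 107 / 115
    p_second_mass: float = 9 / 107  # 116 masses over 107 mass-bearing cases
    mass_area_mm2_range: tuple[float, float] = (15.0, 3689.0)
    intra_case_correlation: float = 0.9
    noise_sd: float = 0.02
    texture_amplitude: float = 0.025
    texture_sigma_frac: float = 0.03  # texture correlation length / image height
    base_intensity: float = 0.35
    mass_contrast_median: float = 0.30
    mass_contrast_log_sd: float = 0.35
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        if not 0 <= self.p_case_has_mass <= 1:
            raise ConfigError("p_case_has_mass must be in [0, 1]")
        if not 0 <= self.intra_case_correlation <= 1:
            raise ConfigError("intra_case_correlation must be in [0, 1]")
        if abs(sum(self.images_per_case.values()) - 1.0) > 1e-9:
            raise ConfigError("images_per_case probabilities must sum to 1")
        if any(k not in (2, 4) for k in self.images_per_case):
            raise ConfigError("images_per_case supports 2 or 4 views only")
        lo, hi = self.mass_area_mm2_range
        if not 0 < lo < hi:
            raise ConfigError("mass_area_mm2_range must be an increasing positive pair")
        min_radius_px = sqrt(lo / pi) / self.pixel_spacing_mm
        if min_radius_px < MIN_MASS_RADIUS_PX:
            raise ConfigError(
                f"smallest mass radius {min_radius_px:.2f} px is unrenderable at "
                f"{self.pixel_spacing_mm} mm spacing"
            )
        max_diam_px = 2 * sqrt(hi / pi) / self.pixel_spacing_mm
        if max_diam_px > 0.8 * min(self.image_shape):
            raise ConfigError(
                f"largest mass diameter {max_diam_px:.0f} px does not fit the "
                f"{self.image_shape} image"
            )


@dataclass
class MassLatent:
    """Case-level latent parameters of one mass."""

    area_mm2: float
    contrast: float
    aspect: float  # minor/major axis ratio
    z_contrast: float  # standard-normal driver behind `contrast`


@dataclass
class SyntheticCase:
    case_id: str
    masses: list[MassLatent]
    views: list[str]  # e.g. ["L-CC", "L-MLO", ...]


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------


def _breast_region(shape: tuple[int, int], laterality: str, view: str) -> np.ndarray:
    """Half-ellipse breast support anchored to the chest-wall edge."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    a = (0.46 if view == "CC" else 0.55) * h  # semi-axis along rows
    b = 0.85 * w  # semi-axis along columns
    cr = h / 2.0
    if laterality == "L":
        dist = ((rr - cr) / a) ** 2 + (cc / b) ** 2
    else:
        dist = ((rr - cr) / a) ** 2 + ((w - 1 - cc) / b) ** 2
    return dist <= 1.0


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    angle: float,
) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def render_view(
    config: SyntheticConfig,
    case: SyntheticCase,
    view_label: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one view: (intensity image as integers, instance-labeled mask).

    View-level mass parameters are the case latents re-jittered according to
    ``intra_case_correlation`` (see module docstring).
    """
    rho = config.intra_case_correlation
    laterality, view = view_label.split("-")
    shape = config.image_shape
    breast = _breast_region(shape, laterality, view)

    sigma_tex = config.texture_sigma_frac * shape[0]
    texture = ndi.gaussian_filter(rng.normal(size=shape), sigma_tex)
    texture *= config.texture_amplitude / max(texture.std(), 1e-12)
    field_img = config.base_intensity + texture + rng.normal(0, config.noise_sd, shape)

    labels = np.zeros(shape, dtype=np.int32)
    area_jitter_sd = (1.0 - rho) * 0.5
    for idx, mass in enumerate(case.masses, start=1):
        area_mm2 = mass.area_mm2 * np.exp(rng.normal(0, area_jitter_sd))
        # contrast: correlated mixture of the case driver and a fresh view draw
        z_view = sqrt(rho) * mass.z_contrast + sqrt(1.0 - rho) * rng.normal()
        contrast = config.mass_contrast_median * np.exp(config.mass_contrast_log_sd * z_view)
        area_px = area_mm2 / config.pixel_spacing_mm**2
        aspect = mass.aspect
        semi_major = sqrt(area_px / (pi * aspect))
        semi_minor = aspect * semi_major
        angle = rng.uniform(0, pi)
        center = _sample_center(breast, semi_major, rng)
        mask = _ellipse_mask(shape, center, semi_major, semi_minor, angle) & breast
        if not mask.any():  # fully clipped (should not happen) — skip
            continue
        bump = ndi.gaussian_filter(mask.astype(float), 0.25 * semi_minor + 0.5)
        peak = bump.max()
        if peak > 0:
            field_img += contrast * bump / peak
        labels[mask] = idx

    scale = 2**config.bit_depth - 1
    pixels = np.rint(np.clip(field_img, 0.0, 1.0) * scale).astype(np.int32)
    pixels = np.clip(pixels, 1, scale)  # breast interior stays nonzero
    pixels[~breast] = 0
    labels[~breast] = 0
    return pixels, labels


def _sample_center(
    breast: np.ndarray, radius: float, rng: np.random.Generator
) -> tuple[float, float]:
    """A mass center such that the mass stays inside the breast region."""
    interior = ndi.binary_erosion(breast, iterations=max(1, int(np.ceil(radius))))
    candidates = np.argwhere(interior)
    if candidates.size == 0:
        candidates = np.argwhere(breast)
    r, c = candidates[rng.integers(len(candidates))]
    return float(r), float(c)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

_ALL_VIEWS = ("L-CC", "L-MLO", "R-CC", "R-MLO")


def sample_case(
    config: SyntheticConfig, case_id: str, rng: np.random.Generator
) -> SyntheticCase:
    """Draw one case's latent parameters (mass presence, sizes, contrast)."""
    masses: list[MassLatent] = []
    if rng.random() < config.p_case_has_mass:
        n_masses = 2 if rng.random() < config.p_second_mass else 1
        lo, hi = config.mass_area_mm2_range
        for _ in range(n_masses):
            masses.append(
                MassLatent(
                    area_mm2=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                    contrast=float("nan"),  # realized per view
                    aspect=float(rng.uniform(0.5, 0.95)),
                    z_contrast=float(rng.normal()),
                )
            )
    n_views_options = sorted(config.images_per_case)
    probs = [config.images_per_case[k] for k in n_views_options]
    n_views = int(rng.choice(n_views_options, p=probs))
    if n_views == 4:
        views = list(_ALL_VIEWS)
    else:
        side = "L" if rng.random() < 0.5 else "R"
        views = [f"{side}-CC", f"{side}-MLO"]
    return SyntheticCase(case_id=case_id, masses=masses, views=views)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[Manifest, dict[str, Mammogram], dict[str, LesionMask]]:
    """Generate the full synthetic census.

    Returns the manifest plus in-memory images and masks keyed by image id.
    Fully deterministic given ``config.seed``; each case consumes an
    independent random substream, so cases are independent of each other
    and of the census order.
    """
    root_seq = np.random.SeedSequence(config.seed)
    case_seqs = root_seq.spawn(config.n_cases)
    records: list[ManifestRecord] = []
    images: dict[str, Mammogram] = {}
    masks: dict[str, LesionMask] = {}
    for i, seq in enumerate(case_seqs):
        rng = np.random.default_rng(seq)
        case_id = f"case{i:04d}"
        case = sample_case(config, case_id, rng)
        for view_label in case.views:
            image_id = f"{case_id}_{view_label}"
            pixels, labels = render_view(config, case, view_label, rng)
            laterality, view = view_label.split("-")
            images[image_id] = Mammogram(
                image_id=image_id,
                pixels=pixels,
                bit_depth=config.bit_depth,
                pixel_spacing_mm=config.pixel_spacing_mm,
                laterality=laterality,
            )
            masks[image_id] = LesionMask(
                image_id=image_id, mask=labels > 0, instance_labels=labels
            )
            records.append(
                ManifestRecord(
                    image_id=image_id,
                    case_id=case_id,
                    laterality=laterality,
                    view=view,
                    image_path=f"synthetic://{image_id}.png",
                    mask_path=f"synthetic://{image_id}_mask.png",
                    pixel_spacing_mm=config.pixel_spacing_mm,
                )
            )
    return Manifest(records), images, masks


# ---------------------------------------------------------------------------
# Deterministic phantoms for unit tests and property checks
# ---------------------------------------------------------------------------


def planted_phantom(kind: str, **params) -> tuple[np.ndarray, np.ndarray]:
    """Minimal deterministic fixtures: (image, mask).

    Kinds:

    * ``empty`` — all-zero image and mask (``shape``).
    * ``single-disk`` — one disk of exact ``diameter_px`` at ``center``
      (default image center) with ``intensity`` (default 1000) on a zero
      background, optional constant ``background`` inside a breast-like
      band.
    * ``two-scale-pair`` — two disks whose diameters are the midpoints of
      the two sieve scales implied by ``pixel_spacing_mm``.
    """
    if kind == "empty":
        shape = params.get("shape", (64, 64))
        return np.zeros(shape, dtype=np.int32), np.zeros(shape, dtype=bool)

    if kind == "single-disk":
        shape = params.get("shape", (128, 128))
        diameter = float(params["diameter_px"])
        center = params.get("center", ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0))
        intensity = params.get("intensity", 1000)
        background = params.get("background", 0)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= (diameter / 2.0) ** 2
        image = np.full(shape, background, dtype=np.int32)
        image[mask] = intensity
        return image, mask

    if kind == "two-scale-pair":
        from mammopart.mms_pcm import scales_from_spacing

        spacing = params.get("pixel_spacing_mm", 2.0)
        shape = params.get("shape", (160, 320))
        scale1, scale2 = scales_from_spacing(spacing)
        d1 = (scale1.se_length_lower_px + scale1.se_length_upper_px) / 2.0
        d2 = (scale2.se_length_lower_px + scale2.se_length_upper_px) / 2.0
        img1, m1 = planted_phantom(
            "single-disk", shape=shape, diameter_px=d1, center=(shape[0] / 2, shape[1] * 0.25)
        )
        img2, m2 = planted_phantom(
            "single-disk", shape=shape, diameter_px=d2, center=(shape[0] / 2, shape[1] * 0.75)
        )
        return img1 + img2, m1 | m2

    raise ConfigError(f"unknown phantom kind {kind!r}")
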