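"""Shared fixtures: programmatic manifests and a small synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from mammopart.dataio import Manifest, ManifestRecord
from mammopart.stability import precompute_pcms
from mammopart.synthetic_data import SyntheticConfig, generate_dataset

ALL_VIEWS = (("L", "CC"), ("L", "MLO"), ("R", "CC"), ("R", "MLO"))


def build_manifest(
    n_cases: int,
    views_per_case: int | list[int] = 4,
    pixel_spacing_mm: float = 0.28,
) -> Manifest:
    """A purely synthetic manifest (no files behind it)."""
    if isinstance(views_per_case, int):
        views_per_case = [views_per_case] * n_cases
    records = []
    for i, n_views in enumerate(views_per_case):
        case_id = f"case{i:04d}"
        for lat, view in ALL_VIEWS[:n_views]:
            image_id = f"{case_id}_{lat}-{view}"
            records.append(
                ManifestRecord(
                    image_id=image_id,
                    case_id=case_id,
                    laterality=lat,
                    view=view,
                    image_path=f"{image_id}.png",
                    mask_path=f"{image_id}_mask.png",
                    pixel_spacing_mm=pixel_spacing_mm,
                )
            )
    return Manifest(records)


def census_manifest_410() -> Manifest:
    """A 410-image / 115-case manifest shaped like the target census:
    90 four-view cases + 25 two-view cases = 410 images."""
    views = [4] * 90 + [2] * 25
    assert sum(views) == 410 and len(views) == 115
    return build_manifest(115, views)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_cases=8,
        image_shape=(104, 128),
        pixel_spacing_mm=2.2,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """8 cases x 4 views at coarse resolution, with PCMs precomputed."""
    manifest, images, masks = generate_dataset(small_config)
    pcms = precompute_pcms(images, small_config.pixel_spacing_mm)
    return manifest, images, masks, pcms


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
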