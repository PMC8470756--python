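"""Train/validation/test partitioning, random or case-wise, plus a leakage audit.

A *random* split assigns images to subsets uniformly at random with exact
subset sizes.  A *case-wise* split assigns whole cases (patients) so that no
case spans two subsets — the guarantee that prevents images of one patient
from contaminating both the training and the test set.  Because cases carry
1–4 images each, case-wise subset sizes can only approximate the targets;
the greedy assignment below keeps each realized size within
``max images per case - 1`` of its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import numpy as np

from mammopart.dataio import Manifest
from mammopart.errors import ValidationError

SUBSETS = ("train", "val", "test")


@dataclass
class PartitionAssignment:
    """An image → subset map with the case → subset map that justifies it."""

    image_to_subset: dict[str, str]
    scheme: str  # "random" or "case_wise"
    seed: int
    target_counts: tuple[int, int, int]
    case_to_subset: dict[str, str] | None = None

    def subset(self, name: str) -> list[str]:
        if name not in SUBSETS:
            raise ValidationError(f"unknown subset {name!r}")
        return [i for i, s in self.image_to_subset.items() if s == name]

    @property
    def realized_counts(self) -> tuple[int, int, int]:
        vals = list(self.image_to_subset.values())
        return tuple(vals.count(s) for s in SUBSETS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"image_id": list(self.image_to_subset), "subset": list(self.image_to_subset.values())}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_counts(manifest: Manifest, target_counts: tuple[int, int, int]) -> None:
    if len(target_counts) != 3 or any(c < 0 for c in target_counts):
        raise ValidationError(f"target_counts must be 3 nonnegative ints, got {target_counts}")
    if sum(target_counts) != len(manifest):
        raise ValidationError(
            f"target_counts sum to {sum(target_counts)} but manifest has {len(manifest)} images"
        )


def random_split(
    manifest: Manifest, target_counts: tuple[int, int, int], seed: int
) -> PartitionAssignment:
    """Uniformly random image-level split with exact subset sizes."""
    _check_counts(manifest, target_counts)
    rng = np.random.default_rng(seed)
    ids = list(manifest.image_ids)
    order = rng.permutation(len(ids))
    n_train, n_val, _ = target_counts
    image_to_subset: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            subset = "train"
        elif rank < n_train + n_val:
            subset = "val"
        else:
            subset = "test"
        image_to_subset[ids[idx]] = subset
    # preserve manifest order in the mapping for reproducible serialization
    image_to_subset = {i: image_to_subset[i] for i in ids}
    return PartitionAssignment(
        image_to_subset=image_to_subset,
        scheme="random",
        seed=seed,
        target_counts=tuple(target_counts),
    )


def case_wise_split(
    manifest: Manifest, target_counts: tuple[int, int, int], seed: int
) -> PartitionAssignment:
    """Whole-case split: cases are shuffled by ``seed`` and assigned, one at
    a time, to the subset with the largest remaining image deficit.

    Ties break in train > val > test order.  No case ever spans subsets;
    every realized size is within ``max case size - 1`` images of its
    target (a case larger than every target is infeasible).
    """
    _check_counts(manifest, target_counts)
    cases = manifest.by_case()
    max_case = max(len(v) for v in cases.values())
    if max_case > max(target_counts):
        raise ValidationError(
            f"a case with {max_case} images cannot fit in any subset of {target_counts}"
        )
    rng = np.random.default_rng(seed)
    case_ids = list(cases)
    order = rng.permutation(len(case_ids))
    deficits = {s: float(c) for s, c in zip(SUBSETS, target_counts)}
    case_to_subset: dict[str, str] = {}
    for idx in order:
        case_id = case_ids[idx]
        subset = max(SUBSETS, key=lambda s: (deficits[s], -SUBSETS.index(s)))
        case_to_subset[case_id] = subset
        deficits[subset] -= len(cases[case_id])
    image_to_subset = {
        r.image_id: case_to_subset[r.case_id] for r in manifest.records
    }
    return PartitionAssignment(
        image_to_subset=image_to_subset,
        scheme="case_wise",
        seed=seed,
        target_counts=tuple(target_counts),
        case_to_subset=case_to_subset,
    )


@dataclass
class LeakageReport:
    """Cases spanning two or more subsets, and how much of val/test they touch."""

    leaked_cases: dict[str, dict[str, int]] = field(default_factory=dict)
    n_val_test_images_sharing_train_case: int = 0

    @property
    def n_leaked_cases(self) -> int:
        return len(self.leaked_cases)


def audit_leakage(assignment: PartitionAssignment, manifest: Manifest) -> LeakageReport:
    """Report every case whose images span >= 2 subsets, and count val/test
    images sharing a case with at least one train image."""
    missing = [i for i in manifest.image_ids if i not in assignment.image_to_subset]
    if missing:
        raise ValidationError(f"assignment does not cover image(s): {missing[:5]}")
    report = LeakageReport()
    for case_id, recs in manifest.by_case().items():
        subsets = [assignment.image_to_subset[r.image_id] for r in recs]
        if len(set(subsets)) > 1:
            report.leaked_cases[case_id] = {s: subsets.count(s) for s in SUBSETS if s in subsets}
        if "train" in subsets:
            report.n_val_test_images_sharing_train_case += sum(
                1 for s in subsets if s in ("val", "test")
            )
    return report


def read_split(path: str | Path, manifest: Manifest | None = None) -> dict[str, str]:
    """Read a serialized split (CSV: image_id, subset) back to a mapping."""
    frame = pd.read_csv(path, dtype={"image_id": str})
    mapping = dict(zip(frame["image_id"], frame["subset"]))
    bad = sorted(set(mapping.values()) - set(SUBSETS))
    if bad:
        raise ValidationError(f"unknown subset name(s) in split file: {bad}")
    if manifest is not None and set(mapping) != set(manifest.image_ids):
        raise ValidationError("split file does not cover exactly the manifest's images")
    return mapping
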