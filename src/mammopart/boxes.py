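"""Axis-aligned boxes in the package-wide coordinate convention.

A box is a 4-tuple of integers ``(r0, c0, r1, c1)``: row-major, 0-based,
half-open, so the box covers rows ``r0..r1-1`` and columns ``c0..c1-1``.
"""

from __future__ import annotations

import numpy as np

from mammopart.errors import ValidationError

Box = tuple[int, int, int, int]


def validate_box(box: Box) -> Box:
    """Check that a box is non-degenerate; return it as a tuple of ints."""
    r0, c0, r1, c1 = (int(v) for v in box)
    if r1 <= r0 or c1 <= c0:
        raise ValidationError(f"degenerate box {box!r}: need r0 < r1 and c0 < c1")
    return (r0, c0, r1, c1)


def box_in_bounds(box: Box, shape: tuple[int, int]) -> bool:
    r0, c0, r1, c1 = box
    return 0 <= r0 and 0 <= c0 and r1 <= shape[0] and c1 <= shape[1]


def box_area(box: Box) -> int:
    r0, c0, r1, c1 = box
    return (r1 - r0) * (c1 - c0)


def mask_tight_box(mask: np.ndarray) -> Box:
    """Tight bounding box of the nonzero pixels of ``mask``.

    Raises :class:`ValidationError` for an all-zero mask.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValidationError("cannot take bounding box of an all-zero mask")
    return (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def mask_in_box(mask: np.ndarray, box: Box) -> bool:
    """True if every nonzero pixel of ``mask`` lies inside ``box``."""
    if not mask.any():
        return False
    r0, c0, r1, c1 = mask_tight_box(mask)
    b0, b1, b2, b3 = box
    return b0 <= r0 and b1 <= c0 and r1 <= b2 and c1 <= b3
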