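"""Binary-mask primitives.

A mask is a 2D boolean :class:`numpy.ndarray` indexed ``(row, col)``,
row 0 at the top, 0-based. Every demarcation, skin region and consensus
result in this package is such a mask. PNG serialization uses 8-bit
grayscale with 0 = false and 255 = true.
"""

from __future__ import annotations

import numpy as np
from PIL import Image


def as_mask(a) -> np.ndarray:
    """Validate and return ``a`` as a 2D boolean mask.

    Raises ``ValueError`` for anything that is not a 2D boolean array
    with at least one row and one column.
    """
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"mask must be at least 1x1, got {a.shape}")
    if a.dtype != np.bool_:
        if not np.isin(a, (0, 1)).all():
            raise ValueError("mask values must be boolean or 0/1")
        a = a.astype(bool)
    return a


def require_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def is_subset(inner: np.ndarray, outer: np.ndarray) -> bool:
    """True when every true pixel of ``inner`` is true in ``outer``."""
    require_same_shape(inner, outer)
    return not bool(np.any(inner & ~outer))


def mask_area(mask: np.ndarray) -> int:
    return int(np.count_nonzero(mask))


def write_mask_png(mask: np.ndarray, path) -> None:
    mask = as_mask(mask)
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128
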