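"""Agreement metrics for demarcations.

Two complementary measures: the Dice coefficient, 2|A∩B|/(|A|+|B|),
capturing spatial overlap (0 = none, 1 = identical); and the surface
area error, the absolute difference in the percentage of *skin* pixels
marked, capturing the area-estimation accuracy that clinical surface
scoring cares about. A demarcation can have perfect area (zero surface
area error) yet poor overlap, which is why both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import as_mask, is_subset, mask_area, require_same_shape
from .types import SkinImage

__all__ = [
    "AgreementScore",
    "dice",
    "surface_area_fraction",
    "surface_area_error",
    "score_image",
]


@dataclass
class AgreementScore:
    image_id: str
    label: str                  # crowd name or rater id
    dice: float
    surface_area_error: float   # percentage points of skin pixels
    gt_fraction: float          # % of skin pixels affected per ground truth
    pred_fraction: float        # % of skin pixels marked by the prediction


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient; two empty masks agree perfectly (1.0)."""
    a, b = as_mask(a), as_mask(b)
    require_same_shape(a, b)
    denom = mask_area(a) + mask_area(b)
    if denom == 0:
        return 1.0
    return 2.0 * mask_area(a & b) / denom


def surface_area_fraction(mask: np.ndarray, skin: np.ndarray) -> float:
    """Percentage of skin pixels covered by ``mask`` (which must lie in skin)."""
    mask, skin = as_mask(mask), as_mask(skin)
    if mask_area(skin) == 0:
        raise ValueError("skin mask is empty")
    if not is_subset(mask, skin):
        raise ValueError("mask has pixels outside the skin mask")
    return 100.0 * mask_area(mask) / mask_area(skin)


def surface_area_error(pred: np.ndarray, gt: np.ndarray, skin: np.ndarray) -> float:
    """Absolute difference, in percentage points of skin pixels, between
    the predicted and ground-truth affected-area fractions."""
    return abs(surface_area_fraction(pred, skin) - surface_area_fraction(gt, skin))


def score_image(pred: np.ndarray, image: SkinImage, label: str) -> AgreementScore:
    """Bundle both metrics for one prediction against one image."""
    gt_frac = surface_area_fraction(image.gt_affected, image.skin_mask)
    pred_frac = surface_area_fraction(pred, image.skin_mask)
    return AgreementScore(
        image_id=image.image_id,
        label=label,
        dice=dice(pred, image.gt_affected),
        surface_area_error=abs(pred_frac - gt_frac),
        gt_fraction=gt_frac,
        pred_fraction=pred_frac,
    )
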