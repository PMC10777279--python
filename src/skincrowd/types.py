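"""Domain types for a crowdsourced skin-demarcation study.

The study structure these types encode: 3D patient photos are projected
to several 2D views; each view carries a skin mask and an expert
ground-truth mask of affected skin; photos are split into a
ground-truth-provided set (used for rater feedback and reliability
scoring) and a ground-truth-withheld set (the evaluation set); raters of
varying skill submit polygon demarcations per image, which are fused
into crowd consensus masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .masks import as_mask, is_subset, mask_area

Split = Literal["gt_provided", "gt_withheld"]
Arm = Literal["high_feedback", "low_feedback"]

VALID_SPLITS = ("gt_provided", "gt_withheld")
VALID_ARMS = ("high_feedback", "low_feedback")


@dataclass
class SkinImage:
    """One 2D view of a 3D photo: skin extent plus expert ground truth."""

    image_id: str
    photo_id: str
    view_label: str
    skin_mask: np.ndarray
    gt_affected: np.ndarray
    split: str

    def __post_init__(self) -> None:
        self.skin_mask = as_mask(self.skin_mask)
        self.gt_affected = as_mask(self.gt_affected)
        if self.split not in VALID_SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if mask_area(self.skin_mask) == 0:
            raise ValueError(f"{self.image_id}: skin mask has no true pixel")
        if not is_subset(self.gt_affected, self.skin_mask):
            raise ValueError(f"{self.image_id}: gt_affected is not contained in skin_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.skin_mask.shape

    @property
    def is_affected(self) -> bool:
        """Whether the expert ground truth marks any affected skin."""
        return mask_area(self.gt_affected) > 0


@dataclass(frozen=True)
class RaterSkill:
    """Generative skill parameters of one simulated rater.

    boundary_jitter_sigma : px
        Scale of zero-mean noise applied to traced boundary vertices.
    region_detection_prob : probability
        Chance that an affected region is noticed at all.
    false_positive_rate : regions/image
        Expected number of spurious marked blobs (Poisson).
    node_budget : int >= 3
        Maximum polygon vertices per region, mimicking the coarse
        node-based outlines a touch interface produces.
    """

    boundary_jitter_sigma: float
    region_detection_prob: float
    false_positive_rate: float
    node_budget: int

    def __post_init__(self) -> None:
        if self.boundary_jitter_sigma < 0:
            raise ValueError("boundary_jitter_sigma must be >= 0")
        if not 0.0 <= self.region_detection_prob <= 1.0:
            raise ValueError("region_detection_prob must be in [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")
        if self.node_budget < 3:
            raise ValueError("node_budget must be >= 3")


@dataclass
class RaterProfile:
    rater_id: str
    arm: str
    enrollment_order: int
    skill: RaterSkill

    def __post_init__(self) -> None:
        if self.arm not in VALID_ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.enrollment_order < 1:
            raise ValueError("enrollment_order must be a positive integer")


@dataclass
class Demarcation:
    """One rater's submission for one image.

    ``polygons`` holds closed vertex loops in continuous (row, col)
    coordinates; ``mask`` is their rasterization clipped to the image's
    skin mask. ``sequence_index`` is the arrival rank within the image
    (1..n, no gaps); ``arrival_index`` is a study-global submission
    counter used to order a single rater's submissions over time.
    """

    rater_id: str
    image_id: str
    polygons: list[np.ndarray]
    mask: np.ndarray
    sequence_index: int = 1
    arrival_index: int = 0

    def __post_init__(self) -> None:
        self.mask = as_mask(self.mask)
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        if self.sequence_index < 1:
            raise ValueError("sequence_index must be >= 1")


@dataclass(frozen=True)
class CrowdSpec:
    """Rule for assembling a crowd for an image.

    Exactly one of ``first_r`` (earliest r submissions from ``arm``) or
    ``top_k`` (k most reliable available raters from ``arm``) is set.
    """

    name: str
    arm: str
    first_r: int | None = None
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in VALID_ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if (self.first_r is None) == (self.top_k is None):
            raise ValueError("exactly one of first_r / top_k must be set")
        if self.first_r is not None and self.first_r < 1:
            raise ValueError("first_r must be >= 1")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class StudyDataset:
    """A full simulated (or loaded) study."""

    images: dict[str, SkinImage]
    raters: dict[str, RaterProfile]
    demarcations: list[Demarcation]
    exposure_log: dict[str, list[str]] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        orders = [r.enrollment_order for r in self.raters.values()]
        if len(set(orders)) != len(orders):
            raise ValueError("enrollment_order values must be unique")
        seen: set[tuple[str, str]] = set()
        per_image: dict[str, list[int]] = {}
        for d in self.demarcations:
            if d.rater_id not in self.raters:
                raise ValueError(f"demarcation references unknown rater {d.rater_id!r}")
            if d.image_id not in self.images:
                raise ValueError(f"demarcation references unknown image {d.image_id!r}")
            key = (d.rater_id, d.image_id)
            if key in seen:
                raise ValueError(f"duplicate demarcation for {key}")
            seen.add(key)
            img = self.images[d.image_id]
            if not is_subset(d.mask, img.skin_mask):
                raise ValueError(f"demarcation mask exceeds skin for {key}")
            per_image.setdefault(d.image_id, []).append(d.sequence_index)
        for image_id, idx in per_image.items():
            if sorted(idx) != list(range(1, len(idx) + 1)):
                raise ValueError(f"sequence_index gap for image {image_id!r}")
        # all views of one photo share a geometry
        shapes: dict[str, tuple[int, int]] = {}
        for img in self.images.values():
            prev = shapes.setdefault(img.photo_id, img.shape)
            if prev != img.shape:
                raise ValueError(f"views of photo {img.photo_id!r} differ in shape")

    def demarcations_for_image(self, image_id: str) -> list[Demarcation]:
        if image_id not in self.images:
            raise KeyError(image_id)
        out = [d for d in self.demarcations if d.image_id == image_id]
        out.sort(key=lambda d: d.sequence_index)
        return out

    def images_in_split(self, split: str, affected_only: bool = False) -> list[SkinImage]:
        out = [img for img in self.images.values() if img.split == split]
        if affected_only:
            out = [img for img in out if img.is_affected]
        return sorted(out, key=lambda im: im.image_id)

    def evaluation_images(self) -> list[SkinImage]:
        """The study's evaluation scope: withheld images with affected skin."""
        return self.images_in_split("gt_withheld", affected_only=True)
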