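"""Study configuration.

A :class:`RunConfig` fully determines a simulated study given one master
seed: pixel geometry, photo counts and viewing angles per split, arm
sizes with their feedback rates and per-image quotas, the skill
distributions raters are drawn from, the crowd definitions, and the
analysis options the downstream modules consume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .types import CrowdSpec, VALID_ARMS

#: angle grid used to label views: horizontal x vertical rotations of
#: 0 / +15 / -15 degrees; "0_0" (the original camera view) comes first.
VIEW_LABELS = (
    "0_0",
    "15_0", "-15_0", "0_15", "0_-15",
    "15_15", "15_-15", "-15_15", "-15_-15",
)


@dataclass
class SkillDistribution:
    """Per-arm distribution raters' skill parameters are drawn from.

    Boundary jitter is lognormal (median ``jitter_median_px``, log-sd
    ``jitter_log_sd``), detection probability is Beta(a, b), the
    false-positive rate is gamma with mean ``fp_rate_mean``, and the
    node budget is uniform on [node_budget_min, node_budget_max].
    ``jitter_scale`` multiplies every drawn jitter, which is how a
    better-trained arm is emulated when desired.
    """

    jitter_median_px: float = 2.0
    jitter_log_sd: float = 0.5
    detection_alpha: float = 8.0
    detection_beta: float = 2.0
    fp_rate_mean: float = 0.2
    node_budget_min: int = 10
    node_budget_max: int = 30
    jitter_scale: float = 1.0


@dataclass
class ArmConfig:
    n_raters: int
    feedback_rate: float
    raters_per_image: int
    skill: SkillDistribution = field(default_factory=SkillDistribution)

    def __post_init__(self) -> None:
        if not 0.0 < self.feedback_rate <= 1.0:
            raise ValueError("feedback_rate must be in (0, 1]")
        if self.raters_per_image < 0:
            raise ValueError("raters_per_image must be >= 0")
        if self.raters_per_image > self.n_raters:
            raise ValueError(
                f"raters_per_image quota {self.raters_per_image} infeasible "
                f"with a pool of {self.n_raters} raters"
            )


@dataclass
class SplitConfig:
    photos_affected: int
    photos_unaffected: int
    n_views: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_views <= len(VIEW_LABELS):
            raise ValueError(f"n_views must be in [1, {len(VIEW_LABELS)}]")


@dataclass
class GroundTruthConfig:
    n_regions_min: int = 1
    n_regions_max: int = 3
    coverage_min: float = 0.05
    coverage_max: float = 0.30


@dataclass
class ViewConfig:
    max_shift: float = 2.0
    max_rotation: float = 10.0


@dataclass
class AnalysisOptions:
    vote_threshold: float = 0.5          # study-faithful plurality threshold
    ranking_metric: str = "mean_dice"    # or "mean_sae"
    photo_reduction: str = "median"      # per-photo reduction of view errors
    sd_pooling: str = "pooled"           # or "per_view"


@dataclass
class RunConfig:
    height: int = 96
    width: int = 96
    gt_provided: SplitConfig = field(default_factory=lambda: SplitConfig(100, 20, 7))
    gt_withheld: SplitConfig = field(default_factory=lambda: SplitConfig(79, 161, 9))
    ground_truth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    views: ViewConfig = field(default_factory=ViewConfig)
    arms: dict[str, ArmConfig] = field(default_factory=dict)
    crowds: dict[str, CrowdSpec] = field(default_factory=dict)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    skill_drift: float = 0.0   # px of jitter change per prior submission; 0 = time-constant skill
    detection_correlation: float = 0.8  # shared-difficulty copula correlation across raters
    extent_bias_sd: float = 0.15        # log-sd of the shared per-region boundary-extent bias

    def __post_init__(self) -> None:
        for name, crowd in self.crowds.items():
            if crowd.arm not in self.arms:
                raise ValueError(f"crowd {name!r} references undefined arm {crowd.arm!r}")

    # -- canonical study configurations -------------------------------------

    @classmethod
    def full_scale(cls) -> "RunConfig":
        """The full study layout: 360 photos -> 3000 2D images, two arms
        with feedback rates 1/4 and 1/14, crowds r=17 (both arms), r=32
        (low arm) and top-5 (low arm)."""
        return cls(
            height=96,
            width=96,
            gt_provided=SplitConfig(photos_affected=100, photos_unaffected=20, n_views=7),
            gt_withheld=SplitConfig(photos_affected=79, photos_unaffected=161, n_views=9),
            arms={
                "high_feedback": ArmConfig(n_raters=130, feedback_rate=1 / 4, raters_per_image=17),
                "low_feedback": ArmConfig(n_raters=161, feedback_rate=1 / 14, raters_per_image=35),
            },
            crowds={
                "high_r17": CrowdSpec("high_r17", "high_feedback", first_r=17),
                "low_r17": CrowdSpec("low_r17", "low_feedback", first_r=17),
                "low_r32": CrowdSpec("low_r32", "low_feedback", first_r=32),
                "low_top5": CrowdSpec("low_top5", "low_feedback", top_k=5),
            },
        )

    @classmethod
    def desk_scale(cls) -> "RunConfig":
        """A structurally identical small study that runs in seconds:
        same two-arm / two-split / four-crowd layout at reduced photo
        counts, rater pools and pixel geometry."""
        return cls(
            height=64,
            width=64,
            gt_provided=SplitConfig(photos_affected=8, photos_unaffected=2, n_views=7),
            gt_withheld=SplitConfig(photos_affected=6, photos_unaffected=2, n_views=9),
            arms={
                # the high-feedback arm gets a modestly lower boundary
                # jitter, emulating the training benefit of frequent
                # expert feedback
                "high_feedback": ArmConfig(
                    n_raters=20, feedback_rate=1 / 4, raters_per_image=8,
                    skill=SkillDistribution(jitter_scale=0.8)),
                "low_feedback": ArmConfig(n_raters=24, feedback_rate=1 / 14, raters_per_image=12),
            },
            crowds={
                "high_r8": CrowdSpec("high_r8", "high_feedback", first_r=8),
                "low_r8": CrowdSpec("low_r8", "low_feedback", first_r=8),
                "low_r12": CrowdSpec("low_r12", "low_feedback", first_r=12),
                "low_top5": CrowdSpec("low_top5", "low_feedback", top_k=5),
            },
        )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kw: dict = {}
        for key in ("height", "width", "skill_drift", "detection_correlation",
                    "extent_bias_sd"):
            if key in d:
                kw[key] = d[key]
        for key, sub in (("gt_provided", SplitConfig), ("gt_withheld", SplitConfig),
                         ("ground_truth", GroundTruthConfig), ("views", ViewConfig),
                         ("analysis", AnalysisOptions)):
            if key in d:
                kw[key] = sub(**d[key])
        if "arms" in d:
            arms = {}
            for name, a in d["arms"].items():
                a = dict(a)
                skill = SkillDistribution(**a.pop("skill", {}))
                arms[name] = ArmConfig(skill=skill, **a)
            kw["arms"] = arms
        if "crowds" in d:
            kw["crowds"] = {name: CrowdSpec(**c) for name, c in d["crowds"].items()}
        return cls(**kw)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        """Stable hash of the fully materialized configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
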