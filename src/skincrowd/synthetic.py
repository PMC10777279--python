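"""Synthetic study generator.

Emulates the structure of a crowdsourced skin-demarcation study without
any patient data: each simulated "3D photo" is a base 2D skin image with
smooth ground-truth lesion blobs; its multiple viewing angles are small
rigid transforms of the base masks (the same skin seen under slightly
different geometry); simulated raters of heterogeneous skill trace the
lesion boundaries with a limited vertex budget, positional jitter,
imperfect region detection and occasional spurious blobs, mirroring the
coarse, sharp-edged outlines a touch interface produces.

Randomness: one master seed. Each (rater, image) pair gets its own
stream derived by hashing (seed, rater_id, image_id), so a single
demarcation is reproducible regardless of the order in which the study
is generated.
"""

from __future__ import annotations

import hashlib

import numpy as np
from scipy import ndimage as ndi
from scipy.special import ndtr
from skimage import measure

from .config import RunConfig, SkillDistribution, VIEW_LABELS
from .masks import mask_area
from .raster import rasterize_polygons
from .types import Demarcation, RaterProfile, RaterSkill, SkinImage, StudyDataset

__all__ = [
    "generate_ground_truth",
    "project_views",
    "simulate_rater_demarcation",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# low-level helpers

def _derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary string/int parts (below 2**31)."""
    h = hashlib.blake2b("|".join(str(p) for p in parts).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


def _wobbly_loop(center, radius, harmonics, n_nodes=64):
    """Closed loop around ``center``: a circle of ``radius`` px modulated
    by a few low-frequency radial harmonics (amp, order, phase)."""
    theta = np.linspace(0.0, 2 * np.pi, n_nodes, endpoint=False)
    r = np.full_like(theta, float(radius))
    for amp, order, phase in harmonics:
        r = r * (1.0 + amp * np.cos(order * theta + phase))
    r = np.clip(r, 0.5, None)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return np.column_stack([rows, cols])


def _draw_harmonics(rng, n=3, max_amp=0.22):
    return [(rng.uniform(0.05, max_amp), int(rng.integers(2, 6)), rng.uniform(0, 2 * np.pi))
            for _ in range(n)]


# ---------------------------------------------------------------------------
# ground truth

def generate_ground_truth(
    photo_id: str,
    height: int,
    width: int,
    n_regions: int,
    coverage_target: float,
    seed: int,
    *,
    split: str = "gt_withheld",
    view_label: str = "0_0",
) -> SkinImage:
    """Generate the base view of one simulated photo.

    The skin mask is a single large wobbly-elliptical region covering
    most of the frame; the affected mask is the union of ``n_regions``
    smooth blobs placed inside the skin, with total area steered to
    ``coverage_target`` (a fraction of the skin area, hit within +-30%).
    Deterministic given ``seed``.
    """
    if height < 32 or width < 32:
        raise ValueError("height and width must be >= 32")
    if not 0.0 <= coverage_target <= 0.9:
        raise ValueError("coverage_target must be in [0, 0.9]")
    if n_regions < 0:
        raise ValueError("n_regions must be >= 0")

    rng = np.random.default_rng(int(seed) % (2**31 - 1))

    # skin: wobbly ellipse centred in the frame, >= 50% of pixels
    center = ((height - 1) / 2.0, (width - 1) / 2.0)
    theta = np.linspace(0.0, 2 * np.pi, 128, endpoint=False)
    wob = 1.0 + 0.04 * np.cos(int(rng.integers(2, 5)) * theta + rng.uniform(0, 2 * np.pi))
    rows = center[0] + 0.47 * height * wob * np.sin(theta)
    cols = center[1] + 0.47 * width * wob * np.cos(theta)
    skin = rasterize_polygons([np.column_stack([rows, cols])], (height, width))
    skin_area = mask_area(skin)
    assert skin_area >= 0.5 * height * width, "skin generation violated its own contract"

    gt = np.zeros_like(skin)
    if n_regions > 0 and coverage_target > 0:
        target = coverage_target * skin_area
        if target > skin_area:
            raise ValueError("impossible coverage: target exceeds skin area")
        # eligible centres: comfortably interior skin pixels
        dist = ndi.distance_transform_edt(skin)
        base_radius = max(np.sqrt(target / n_regions / np.pi), 1.5)
        eligible = np.argwhere(dist >= min(base_radius * 0.5, dist.max() * 0.8))
        centers = eligible[rng.choice(len(eligible), size=n_regions, replace=False)]
        shapes = [_draw_harmonics(rng) for _ in range(n_regions)]
        radius = base_radius
        for _ in range(12):
            loops = [_wobbly_loop(c, radius, h) for c, h in zip(centers, shapes)]
            gt = rasterize_polygons(loops, (height, width)) & skin
            area = mask_area(gt)
            if abs(area - target) <= 0.15 * target:
                break
            ratio = np.sqrt(target / max(area, 1.0))
            radius *= float(np.clip(ratio, 0.7, 1.4))

    return SkinImage(
        image_id=f"{photo_id}:{view_label}",
        photo_id=photo_id,
        view_label=view_label,
        skin_mask=skin,
        gt_affected=gt,
        split=split,
    )


# ---------------------------------------------------------------------------
# views

def _rigid_transform(mask: np.ndarray, angle_deg: float, shift) -> np.ndarray:
    """Rotate ``mask`` about its frame centre and translate, nearest
    neighbour, so boolean masks stay boolean and subsets stay subsets."""
    if angle_deg == 0.0 and shift[0] == 0.0 and shift[1] == 0.0:
        return mask.copy()
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    c = (np.asarray(mask.shape, dtype=float) - 1) / 2.0
    # output coordinate p samples input at rot.T @ (p - c - shift) + c
    offset = c - rot.T @ (c + np.asarray(shift, dtype=float))
    out = ndi.affine_transform(
        mask.astype(np.uint8), rot.T, offset=offset, order=0,
        mode="constant", cval=0, prefilter=False,
    )
    return out.astype(bool)


def project_views(
    image: SkinImage,
    view_labels: list[str],
    max_shift: float,
    max_rotation: float,
    seed: int,
) -> list[SkinImage]:
    """Create one view per label as a small rigid transform of ``image``.

    All outputs share the source ``photo_id`` and geometry; the label
    ``"0_0"`` is the identity view. A transform that would push more
    than 5% of skin pixels out of frame is rejected with an error.
    """
    if not view_labels:
        raise ValueError("view_labels must be non-empty")
    rng = np.random.default_rng(int(seed) % (2**31 - 1))
    src_area = mask_area(image.skin_mask)
    out: list[SkinImage] = []
    for label in view_labels:
        if label == "0_0":
            angle, shift = 0.0, (0.0, 0.0)
        else:
            angle = float(rng.uniform(-max_rotation, max_rotation))
            shift = tuple(rng.uniform(-max_shift, max_shift, size=2))
        skin = _rigid_transform(image.skin_mask, angle, shift)
        gt = _rigid_transform(image.gt_affected, angle, shift)
        if mask_area(skin) < 0.95 * src_area:
            raise ValueError(
                f"view {label!r}: transform pushes more than 5% of skin out of frame"
            )
        out.append(SkinImage(
            image_id=f"{image.photo_id}:{label}",
            photo_id=image.photo_id,
            view_label=label,
            skin_mask=skin,
            gt_affected=gt,
            split=image.split,
        ))
    return out


# ---------------------------------------------------------------------------
# rater behaviour

def _trace_region(region_mask: np.ndarray, node_budget: int, sigma: float, rng,
                  extent_scale: float = 1.0) -> np.ndarray | None:
    """Trace one connected region as a jittered, budget-limited loop,
    optionally rescaled radially about its centroid (shared extent bias)."""
    contours = measure.find_contours(region_mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    # find_contours places pixel centres at integer coordinates; shift to
    # the continuous frame where centres sit at (r+0.5, c+0.5)
    contour = contour + 0.5
    n = min(node_budget, len(contour))
    if n < 3:
        return None
    idx = np.linspace(0, len(contour) - 1, n, endpoint=False).astype(int)
    loop = contour[idx]
    if extent_scale != 1.0:
        centroid = loop.mean(axis=0)
        loop = centroid + extent_scale * (loop - centroid)
    if sigma > 0:
        loop = loop + rng.normal(0.0, sigma, size=loop.shape)
    return loop


def simulate_rater_demarcation(
    image: SkinImage,
    rater: RaterProfile,
    seed: int,
    *,
    jitter_sigma: float | None = None,
    detection_correlation: float = 0.8,
    extent_bias_sd: float = 0.0,
) -> Demarcation:
    """Simulate one rater's polygon submission for one image.

    Each ground-truth connected region is detected with the rater's
    detection probability; detected boundaries are traced with at most
    ``node_budget`` vertices and vertex jitter of scale
    ``boundary_jitter_sigma`` px; Poisson-many spurious blobs are added
    inside the skin. The rasterized mask is clipped to the skin mask.

    Two image-level (rater-shared) difficulty components emulate how a
    whole crowd errs together on a hard photo:

    * Detection uses a Gaussian copula: a rater detects a region iff
      ``Phi(rho * z_region + sqrt(1 - rho^2) * z_rater) < p`` with
      ``rho = detection_correlation``. The marginal detection
      probability is exactly ``p`` for every rater, but the same subtle
      region tends to be missed by most of the crowd at once.
    * ``extent_bias_sd > 0`` applies a shared log-normal radial scale
      ``exp(N(0, extent_bias_sd))`` per (image, region) to every
      rater's traced boundary — the crowd collectively over- or
      under-extends the same border, an error that consensus voting
      cannot remove and that within-crowd spread does not signal.

    Both shared components default off/neutral here; study-level
    simulation wires them from the run configuration. Deterministic
    given (seed, rater_id, image_id) regardless of call order.
    ``jitter_sigma`` overrides the profile value (used by the
    skill-drift knob).
    """
    if not 0.0 <= detection_correlation <= 1.0:
        raise ValueError("detection_correlation must be in [0, 1]")
    if extent_bias_sd < 0:
        raise ValueError("extent_bias_sd must be >= 0")
    skill = rater.skill
    sigma = skill.boundary_jitter_sigma if jitter_sigma is None else float(jitter_sigma)
    rng = np.random.default_rng(_derive_seed(seed, rater.rater_id, image.image_id))

    polygons: list[np.ndarray] = []
    labels, n_regions = measure.label(image.gt_affected, return_num=True)
    rho = detection_correlation
    shared_rng = np.random.default_rng(_derive_seed(seed, "difficulty", image.image_id))
    z_shared = shared_rng.normal(size=n_regions)
    extent = np.exp(shared_rng.normal(0.0, extent_bias_sd, size=n_regions)) \
        if extent_bias_sd > 0 else np.ones(n_regions)
    for lab in range(1, n_regions + 1):
        z_rater = rng.normal()
        u = ndtr(rho * z_shared[lab - 1] + np.sqrt(1.0 - rho**2) * z_rater)
        if not u < skill.region_detection_prob:
            continue
        loop = _trace_region(labels == lab, skill.node_budget, sigma, rng,
                             extent_scale=float(extent[lab - 1]))
        if loop is not None:
            polygons.append(loop)

    n_spurious = int(rng.poisson(skill.false_positive_rate))
    if n_spurious > 0:
        skin_pixels = np.argwhere(image.skin_mask)
        for _ in range(n_spurious):
            center = skin_pixels[rng.integers(len(skin_pixels))] + 0.5
            radius = rng.uniform(1.5, 0.08 * min(image.shape))
            n_nodes = int(min(skill.node_budget, 24))
            polygons.append(_wobbly_loop(center, radius, _draw_harmonics(rng, 2), n_nodes))

    mask = rasterize_polygons(polygons, image.shape) & image.skin_mask
    return Demarcation(
        rater_id=rater.rater_id,
        image_id=image.image_id,
        polygons=polygons,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# the whole study

def _draw_skill(rng, dist: SkillDistribution) -> RaterSkill:
    sigma = float(rng.lognormal(np.log(dist.jitter_median_px), dist.jitter_log_sd))
    return RaterSkill(
        boundary_jitter_sigma=sigma * dist.jitter_scale,
        region_detection_prob=float(rng.beta(dist.detection_alpha, dist.detection_beta)),
        false_positive_rate=float(rng.gamma(2.0, dist.fp_rate_mean / 2.0)),
        node_budget=int(rng.integers(dist.node_budget_min, dist.node_budget_max + 1)),
    )


def simulate_study(config: RunConfig, seed: int) -> StudyDataset:
    """Generate a full study: images, raters, demarcations, exposure log.

    Photos and views follow the configured split layout; every image
    receives the configured number of demarcations from each arm, with
    per-image ``sequence_index`` reflecting simulated arrival order.
    Each rater's exposure log records which ground-truth-provided images
    counted as feedback at the arm's rate (every ``round(1/rate)``-th
    provided case in that rater's own submission order). Fully
    deterministic given ``seed``.
    """
    seed = int(seed) % (2**31 - 1)
    rng = np.random.default_rng(_derive_seed(seed, "study"))

    # raters: interleaved enrollment across arms
    pool: list[str] = []
    for arm_name, arm in config.arms.items():
        pool.extend([arm_name] * arm.n_raters)
    rng.shuffle(pool)
    raters: dict[str, RaterProfile] = {}
    arm_members: dict[str, list[str]] = {a: [] for a in config.arms}
    for order, arm_name in enumerate(pool, start=1):
        rid = f"r{order:04d}"
        raters[rid] = RaterProfile(
            rater_id=rid,
            arm=arm_name,
            enrollment_order=order,
            skill=_draw_skill(rng, config.arms[arm_name].skill),
        )
        arm_members[arm_name].append(rid)

    # images
    images: dict[str, SkinImage] = {}
    gtc = config.ground_truth
    for split_name, scfg in (("gt_provided", config.gt_provided),
                             ("gt_withheld", config.gt_withheld)):
        tag = "p" if split_name == "gt_provided" else "w"
        specs = [("aff", i, True) for i in range(scfg.photos_affected)]
        specs += [("una", i, False) for i in range(scfg.photos_unaffected)]
        for kind, i, affected in specs:
            photo_id = f"{tag}_{kind}_{i:03d}"
            if affected:
                n_regions = int(rng.integers(gtc.n_regions_min, gtc.n_regions_max + 1))
                coverage = float(rng.uniform(gtc.coverage_min, gtc.coverage_max))
            else:
                n_regions, coverage = 0, 0.0
            base = generate_ground_truth(
                photo_id, config.height, config.width, n_regions, coverage,
                seed=_derive_seed(seed, "photo", photo_id), split=split_name,
            )
            views = project_views(
                base, list(VIEW_LABELS[:scfg.n_views]),
                config.views.max_shift, config.views.max_rotation,
                seed=_derive_seed(seed, "views", photo_id),
            )
            for v in views:
                images[v.image_id] = v

    # demarcations: per image, quota from each arm, shuffled arrival order
    demarcations: list[Demarcation] = []
    submissions_by_rater: dict[str, int] = {rid: 0 for rid in raters}
    provided_count: dict[str, int] = {rid: 0 for rid in raters}
    exposure_log: dict[str, list[str]] = {rid: [] for rid in raters}
    arrival_counter = 0
    for image_id in sorted(images):
        image = images[image_id]
        participants: list[str] = []
        for arm_name, arm in config.arms.items():
            if arm.raters_per_image == 0:
                continue
            chosen = rng.choice(arm_members[arm_name], size=arm.raters_per_image, replace=False)
            participants.extend(chosen.tolist())
        rng.shuffle(participants)
        for si, rid in enumerate(participants, start=1):
            rater = raters[rid]
            jitter = None
            if config.skill_drift != 0.0:
                jitter = max(
                    0.0,
                    rater.skill.boundary_jitter_sigma
                    + config.skill_drift * submissions_by_rater[rid],
                )
            d = simulate_rater_demarcation(
                image, rater, seed, jitter_sigma=jitter,
                detection_correlation=config.detection_correlation,
                extent_bias_sd=config.extent_bias_sd)
            d.sequence_index = si
            arrival_counter += 1
            d.arrival_index = arrival_counter
            demarcations.append(d)
            submissions_by_rater[rid] += 1
            if image.split == "gt_provided":
                provided_count[rid] += 1
                every = max(1, round(1.0 / config.arms[rater.arm].feedback_rate))
                if provided_count[rid] % every == 0:
                    exposure_log[rid].append(image_id)

    return StudyDataset(
        images=images,
        raters=raters,
        demarcations=demarcations,
        exposure_log=exposure_log,
        config_echo=config.to_dict(),
    )
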