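"""Shared builders for test fixtures: hand-made masks/demarcations and
small purpose-built studies (skill-contrast pool, homogeneous crowd,
fixed-skill learning study) used by both unit and acceptance tests."""

from __future__ import annotations

import numpy as np

from skincrowd import (
    Demarcation,
    RaterProfile,
    RaterSkill,
    SkinImage,
    StudyDataset,
    generate_ground_truth,
    simulate_rater_demarcation,
)
from skincrowd.synthetic import _derive_seed


def rect_loop(r0: float, c0: float, r1: float, c1: float) -> np.ndarray:
    """Closed rectangle loop in (row, col) continuous coordinates."""
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=float)


def rect_mask(shape, r0, c0, r1, c1) -> np.ndarray:
    """Boolean mask of pixels whose centers lie in [r0,r1) x [c0,c1)."""
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def make_dem(mask, rater_id="r1", image_id="img", seq=1, arrival=0) -> Demarcation:
    """Mask-first demarcation fixture; the polygon loop is nominal
    (bounding box) since only the mask participates in fusion/metrics."""
    mask = np.asarray(mask, dtype=bool)
    if mask.any():
        rows, cols = np.nonzero(mask)
        polygons = [rect_loop(rows.min(), cols.min(), rows.max() + 1, cols.max() + 1)]
    else:
        polygons = []
    return Demarcation(rater_id=rater_id, image_id=image_id, polygons=polygons,
                       mask=mask, sequence_index=seq, arrival_index=arrival)


def skin_image_from_masks(skin, gt, image_id="img", photo_id="photo",
                          view_label="0_0", split="gt_withheld") -> SkinImage:
    return SkinImage(image_id=image_id, photo_id=photo_id, view_label=view_label,
                     skin_mask=skin, gt_affected=gt, split=split)


def _profiles(arm, skills):
    return {
        f"{arm[0]}{i:03d}": RaterProfile(
            rater_id=f"{arm[0]}{i:03d}", arm=arm, enrollment_order=i + 1, skill=s,
        )
        for i, s in enumerate(skills)
    }


def build_custom_study(images, raters, seed, rng=None, **sim_kwargs) -> StudyDataset:
    """Every rater demarcates every image; arrival order shuffled per image."""
    rng = rng or np.random.default_rng(_derive_seed(seed, "arrivals"))
    demarcations = []
    arrival = 0
    for image_id in sorted(images):
        img = images[image_id]
        order = list(sorted(raters))
        rng.shuffle(order)
        for si, rid in enumerate(order, start=1):
            d = simulate_rater_demarcation(img, raters[rid], seed, **sim_kwargs)
            d.sequence_index = si
            arrival += 1
            d.arrival_index = arrival
            demarcations.append(d)
    return StudyDataset(images=images, raters=raters, demarcations=demarcations)


def skill_contrast_study(seed, n_provided=30, n_withheld=8, size=48,
                         n_low=5, n_high=12, sigma_low=1.0, sigma_high=6.0):
    """A low-feedback pool with a known skill split: ``n_low`` raters at
    boundary jitter ``sigma_low`` px and ``n_high`` at ``sigma_high`` px,
    detection 1 and no false positives, each demarcating every image.
    Returns (dataset, low_jitter_rater_ids)."""
    images = {}
    for i in range(n_provided):
        img = generate_ground_truth(f"prov_{i:03d}", size, size, 2, 0.15,
                                    seed=_derive_seed(seed, "prov", i), split="gt_provided")
        images[img.image_id] = img
    for i in range(n_withheld):
        img = generate_ground_truth(f"with_{i:03d}", size, size, 2, 0.15,
                                    seed=_derive_seed(seed, "with", i), split="gt_withheld")
        images[img.image_id] = img
    skills = [RaterSkill(sigma_low, 1.0, 0.0, 24)] * n_low
    skills += [RaterSkill(sigma_high, 1.0, 0.0, 24)] * n_high
    raters = _profiles("low_feedback", skills)
    low_ids = sorted(raters)[:n_low]
    return build_custom_study(images, raters, seed), low_ids


def homogeneous_study(seed, n_photos=40, n_raters=17, size=48,
                      sigma=2.0, detection=1.0, fp_rate=0.2,
                      extent_bias_sd=0.15):
    """Identical-skill crowd over ``n_photos`` withheld affected photos
    (one view each), under the study-default shared-difficulty model.

    This is a *null* condition for the disagreement-vs-accuracy
    analysis, so every nuisance common cause is excluded by design:
    every rater has identical skill; lesion count and coverage are held
    fixed across photos (varying lesion size would couple rater SD and
    consensus error through the absolute percentage-point scale of the
    surface-area metric); and detection is certain, so the crowd always
    finds the lesion and consensus error is driven by the shared
    boundary-extent bias — an error mode that within-crowd spread
    genuinely does not signal. Region drop-outs are a separate, rare
    failure mode exercised by the detection-calibration tests."""
    images = {}
    for i in range(n_photos):
        img = generate_ground_truth(f"ph_{i:03d}", size, size, 2, 0.15,
                                    seed=_derive_seed(seed, "ph", i), split="gt_withheld")
        images[img.image_id] = img
    skills = [RaterSkill(sigma, detection, fp_rate, 24)] * n_raters
    raters = _profiles("low_feedback", skills)
    return build_custom_study(images, raters, seed, extent_bias_sd=extent_bias_sd)


def learning_study(seed, n_raters=5, n_images=100, size=48):
    """Time-constant-skill raters over ``n_images`` affected withheld
    images, for learning-curve analysis."""
    images = {}
    for i in range(n_images):
        img = generate_ground_truth(f"lrn_{i:03d}", size, size, 2, 0.15,
                                    seed=_derive_seed(seed, "lrn", i), split="gt_withheld")
        images[img.image_id] = img
    skills = [RaterSkill(2.0, 0.9, 0.2, 24)] * n_raters
    raters = _profiles("low_feedback", skills)
    return build_custom_study(images, raters, seed)
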