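"""Synthetic study generator: ground truth, views, rater noise, full study."""

import numpy as np
import pytest

from skincrowd import (
    RaterProfile,
    RaterSkill,
    RunConfig,
    dice,
    generate_ground_truth,
    project_views,
    simulate_rater_demarcation,
    simulate_study,
)
from skincrowd.config import SplitConfig
from skincrowd.masks import is_subset
from skincrowd.raster import rasterize_polygons

from helpers import skin_image_from_masks


def circle_loop(center, radius, n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(t),
                            center[1] + radius * np.cos(t)])


class TestGenerateGroundTruth:
    def test_no_regions_means_empty_mask(self):
        img = generate_ground_truth("p", 48, 48, 0, 0.0, seed=1)
        assert not img.gt_affected.any()

    def test_seeded_determinism(self):
        a = generate_ground_truth("p", 64, 64, 2, 0.2, seed=5)
        b = generate_ground_truth("p", 64, 64, 2, 0.2, seed=5)
        assert (a.skin_mask == b.skin_mask).all()
        assert (a.gt_affected == b.gt_affected).all()

    def test_coverage_within_band(self):
        img = generate_ground_truth("p", 128, 128, 3, 0.10, seed=7)
        frac = img.gt_affected.sum() / img.skin_mask.sum()
        assert 0.07 <= frac <= 0.13

    def test_skin_is_large_and_gt_contained(self):
        img = generate_ground_truth("p", 64, 64, 3, 0.25, seed=3)
        assert img.skin_mask.sum() >= 0.5 * 64 * 64
        assert is_subset(img.gt_affected, img.skin_mask)

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            generate_ground_truth("p", 16, 64, 1, 0.1, seed=1)

    def test_impossible_coverage_rejected(self):
        with pytest.raises(ValueError):
            generate_ground_truth("p", 64, 64, 1, 0.95, seed=1)


class TestProjectViews:
    def test_identity_transform_reproduces_source(self):
        src = generate_ground_truth("p", 64, 64, 2, 0.15, seed=2)
        views = project_views(src, ["0_0", "15_0"], max_shift=0, max_rotation=0, seed=9)
        for v in views:
            assert (v.skin_mask == src.skin_mask).all()
            assert (v.gt_affected == src.gt_affected).all()

    def test_nine_views_share_photo_id(self):
        src = generate_ground_truth("p", 64, 64, 2, 0.15, seed=2)
        labels = ["0_0", "15_0", "-15_0", "0_15", "0_-15",
                  "15_15", "15_-15", "-15_15", "-15_-15"]
        views = project_views(src, labels, max_shift=2, max_rotation=10, seed=4)
        assert len(views) == 9
        assert {v.photo_id for v in views} == {"p"}
        assert len({v.image_id for v in views}) == 9

    def test_affected_fraction_approximately_preserved(self):
        src = generate_ground_truth("p", 96, 96, 2, 0.15, seed=11)
        views = project_views(src, ["0_0", "15_0", "0_15", "15_15"],
                              max_shift=3, max_rotation=15, seed=6)
        base = views[0].gt_affected.sum() / views[0].skin_mask.sum()
        for v in views[1:]:
            frac = v.gt_affected.sum() / v.skin_mask.sum()
            assert abs(frac - base) <= 0.02

    def test_subset_invariant_survives_transform(self):
        src = generate_ground_truth("p", 64, 64, 3, 0.25, seed=13)
        for v in project_views(src, ["0_0", "15_15", "-15_-15"], 3, 15, seed=2):
            assert is_subset(v.gt_affected, v.skin_mask)

    def test_excessive_shift_rejected(self):
        src = generate_ground_truth("p", 64, 64, 1, 0.1, seed=2)
        with pytest.raises(ValueError, match="out of frame"):
            # a shift of the frame width cannot keep 95% of skin in view
            project_views(src, ["big"], max_shift=64, max_rotation=0, seed=12)

    def test_empty_labels_rejected(self):
        src = generate_ground_truth("p", 64, 64, 1, 0.1, seed=2)
        with pytest.raises(ValueError):
            project_views(src, [], 0, 0, seed=1)


class TestSimulateRaterDemarcation:
    def _rater(self, sigma=0.0, detect=1.0, fp=0.0, nodes=200, rid="r1"):
        return RaterProfile(rid, "low_feedback", 1,
                            RaterSkill(sigma, detect, fp, nodes))

    def test_blind_rater_submits_empty_mask(self):
        img = generate_ground_truth("p", 64, 64, 2, 0.2, seed=3)
        d = simulate_rater_demarcation(img, self._rater(detect=0.0), seed=5)
        assert not d.mask.any() and d.polygons == []

    def test_dense_trace_of_convex_region_is_faithful(self):
        skin = np.ones((128, 128), bool)
        gt = rasterize_polygons([circle_loop((64, 64), 30)], (128, 128))
        img = skin_image_from_masks(skin, gt, image_id="conv")
        d = simulate_rater_demarcation(img, self._rater(), seed=7)
        assert dice(d.mask, gt) >= 0.95

    def test_seeded_determinism_and_call_order_independence(self):
        img = generate_ground_truth("p", 64, 64, 2, 0.2, seed=3)
        other = generate_ground_truth("q", 64, 64, 1, 0.1, seed=4)
        r = self._rater(sigma=2.0, detect=0.8, fp=0.5, nodes=20)
        a = simulate_rater_demarcation(img, r, seed=9)
        simulate_rater_demarcation(other, r, seed=9)  # interleaved call
        b = simulate_rater_demarcation(img, r, seed=9)
        assert (a.mask == b.mask).all()
        assert all((p == q).all() for p, q in zip(a.polygons, b.polygons))

    def test_demarcation_clipped_to_skin(self):
        img = generate_ground_truth("p", 64, 64, 2, 0.2, seed=3)
        d = simulate_rater_demarcation(
            img, self._rater(sigma=8.0, detect=1.0, fp=2.0, nodes=16), seed=2)
        assert is_subset(d.mask, img.skin_mask)

    def test_mean_dice_non_increasing_in_jitter(self):
        img = generate_ground_truth("p", 64, 64, 2, 0.15, seed=21)
        means = []
        for sigma in (0.0, 2.0, 6.0):
            r = self._rater(sigma=sigma, nodes=24, rid=f"s{sigma}")
            scores = [dice(simulate_rater_demarcation(img, r, seed=s).mask, img.gt_affected)
                      for s in range(30)]
            means.append(np.mean(scores))
        assert means[0] >= means[1] >= means[2]

    def test_detection_rate_calibrated(self):
        from skimage import measure
        img = generate_ground_truth("p", 96, 96, 3, 0.15, seed=17)
        k = measure.label(img.gt_affected, return_num=True)[1]
        p = 0.6
        r = self._rater(sigma=0.0, detect=p, fp=0.0, nodes=24)
        detected = total = 0
        for s in range(200):
            d = simulate_rater_demarcation(img, r, seed=s)
            detected += len(d.polygons)
            total += k
        assert abs(detected / total - p) <= 0.05


class TestSimulateStudy:
    def test_desk_scale_structure(self):
        cfg = RunConfig.desk_scale()
        data = simulate_study(cfg, seed=1)
        n_expected = (8 + 2) * 7 + (6 + 2) * 9
        assert len(data.images) == n_expected
        # per (rater, image) uniqueness and sequence integrity are
        # enforced by StudyDataset.validate() at construction
        per_image = {}
        for d in data.demarcations:
            per_image.setdefault(d.image_id, []).append(d)
        quota = sum(a.raters_per_image for a in cfg.arms.values())
        assert all(len(v) == quota for v in per_image.values())

    def test_determinism(self):
        cfg = RunConfig.desk_scale()
        cfg.gt_provided = SplitConfig(2, 1, 2)
        cfg.gt_withheld = SplitConfig(2, 1, 2)
        a = simulate_study(cfg, seed=3)
        b = simulate_study(cfg, seed=3)
        assert sorted(a.images) == sorted(b.images)
        for iid in a.images:
            assert (a.images[iid].gt_affected == b.images[iid].gt_affected).all()
        for da, db in zip(a.demarcations, b.demarcations):
            assert da.rater_id == db.rater_id and da.image_id == db.image_id
            assert (da.mask == db.mask).all()

    def test_feedback_exposure_rates(self):
        cfg = RunConfig.desk_scale()
        data = simulate_study(cfg, seed=2)
        for rid, seen in data.exposure_log.items():
            rater = data.raters[rid]
            provided = [d for d in data.demarcations
                        if d.rater_id == rid
                        and data.images[d.image_id].split == "gt_provided"]
            every = round(1 / cfg.arms[rater.arm].feedback_rate)
            assert len(seen) == len(provided) // every
            assert all(data.images[i].split == "gt_provided" for i in seen)

    def test_infeasible_quota_rejected(self):
        cfg = RunConfig.desk_scale()
        with pytest.raises(ValueError, match="infeasible"):
            cfg.arms["high_feedback"].raters_per_image = 99
            cfg.arms["high_feedback"].__post_init__()

    def test_all_masks_respect_skin(self):
        cfg = RunConfig.desk_scale()
        cfg.gt_provided = SplitConfig(2, 0, 2)
        cfg.gt_withheld = SplitConfig(2, 1, 3)
        data = simulate_study(cfg, seed=5)
        for img in data.images.values():
            assert is_subset(img.gt_affected, img.skin_mask)
        for d in data.demarcations:
            assert is_subset(d.mask, data.images[d.image_id].skin_mask)

    def test_skill_drift_knob_changes_later_submissions(self):
        cfg = RunConfig.desk_scale()
        cfg.gt_provided = SplitConfig(2, 0, 2)
        cfg.gt_withheld = SplitConfig(2, 0, 2)
        flat = simulate_study(cfg, seed=7)
        cfg.skill_drift = 1.5
        drifting = simulate_study(cfg, seed=7)
        diffs = [not (a.mask == b.mask).all()
                 for a, b in zip(flat.demarcations, drifting.demarcations)]
        assert any(diffs)
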