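"""Study-level analyses: summaries, crowd comparison, spread, regression."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from skincrowd import CrowdSpec, RaterProfile, RaterSkill, StudyDataset
from skincrowd.analysis import (
    compare_crowds,
    photo_spread,
    summarize_crowd,
    variability_vs_error,
)

from helpers import make_dem, rect_mask, skin_image_from_masks


def scores_frame(dices, saes, crowd="c"):
    return pd.DataFrame({
        "image_id": [f"i{k}" for k in range(len(dices))],
        "crowd_name": crowd, "dice": dices, "surface_area_error": saes,
    })


class TestSummarizeCrowd:
    def test_five_values_percentiles(self):
        s = summarize_crowd(scores_frame([0.1] * 5, [1, 2, 3, 4, 5]), "c")
        assert s.median_sae == 3 and s.iqr_sae == (2, 4)

    def test_single_image_degenerate(self):
        s = summarize_crowd(scores_frame([0.7], [9.0]), "c")
        assert s.median_dice == s.mean_dice == 0.7
        assert s.iqr_sae == (9.0, 9.0)

    def test_hand_computed_six_rows(self):
        d = [0.5, 0.9, 0.7, 0.6, 0.8, 1.0]
        e = [10.0, 2.0, 6.0, 8.0, 4.0, 0.0]
        s = summarize_crowd(scores_frame(d, e), "c")
        assert s.median_dice == pytest.approx(0.75)
        assert s.mean_dice == pytest.approx(np.mean(d))
        assert s.iqr_dice == (pytest.approx(0.625), pytest.approx(0.875))
        assert s.median_sae == pytest.approx(5.0)
        assert s.medians_in_iqr if hasattr(s, "medians_in_iqr") else True
        assert s.iqr_sae[0] <= s.median_sae <= s.iqr_sae[1]

    def test_permutation_invariance(self, rng):
        d = rng.random(9).tolist()
        e = (rng.random(9) * 20).tolist()
        ref = summarize_crowd(scores_frame(d, e), "c")
        perm = rng.permutation(9)
        got = summarize_crowd(scores_frame([d[i] for i in perm],
                                           [e[i] for i in perm]), "c")
        assert got.median_dice == ref.median_dice
        assert got.iqr_dice == ref.iqr_dice
        assert got.median_sae == ref.median_sae
        assert got.iqr_sae == ref.iqr_sae
        assert got.mean_dice == pytest.approx(ref.mean_dice)
        assert got.mean_sae == pytest.approx(ref.mean_sae)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_crowd(scores_frame([], []), "c")


def exact_mw_oracle(a, b):
    """Independent full enumeration of the two-sided Mann-Whitney p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
          for idx in combinations(range(n1 + n2), n1)]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestCompareCrowds:
    def test_separated_samples_exact(self):
        u, p = compare_crowds([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_identical_samples_complete_tie(self):
        u, p = compare_crowds([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(9 / 2)
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self, rng):
        a = rng.random(5).tolist()
        b = rng.random(6).tolist()
        u_ab, p_ab = compare_crowds(a, b)
        u_ba, p_ba = compare_crowds(b, a)
        assert u_ba == pytest.approx(len(a) * len(b) - u_ab)
        assert p_ba == pytest.approx(p_ab)

    @given(st.data())
    def test_exact_mode_matches_enumeration_all_n_le_8(self, data):
        n1 = data.draw(st.integers(1, 7))
        n2 = data.draw(st.integers(1, 8 - n1))
        # small integer values force plenty of ties
        a = data.draw(st.lists(st.integers(0, 4), min_size=n1, max_size=n1))
        b = data.draw(st.lists(st.integers(0, 4), min_size=n2, max_size=n2))
        u, p = compare_crowds(a, b)
        u_ref, p_ref = exact_mw_oracle(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_exact_mode_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            perm = rng.permutation(100)  # one draw: a and b cannot tie
            a = perm[:4].astype(float)
            b = perm[50:56].astype(float)
            u, p = compare_crowds(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_approximate_mode_matches_scipy(self, rng):
        a = (rng.random(20) * 10).round(0)
        b = (rng.random(25) * 10).round(0) + 1
        u, p = compare_crowds(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_crowds([], [1.0])


class TestPhotoSpread:
    def _map(self, mapping):
        return pd.DataFrame([{"image_id": i, "photo_id": p, "view_label": v}
                             for i, (p, v) in mapping.items()])

    def test_identical_views_have_zero_range(self):
        scores = scores_frame([0.5] * 3, [7.0, 7.0, 7.0])
        m = self._map({"i0": ("ph", "a"), "i1": ("ph", "b"), "i2": ("ph", "c")})
        (ps,) = photo_spread(scores, m)
        assert ps.error_range == (7.0, 7.0) and ps.median_error == 7.0

    def test_ordering_by_descending_median(self):
        scores = scores_frame([0.5] * 3, [5.0, 12.0, 3.0])
        m = self._map({"i0": ("a", "v"), "i1": ("b", "v"), "i2": ("c", "v")})
        out = photo_spread(scores, m)
        assert [p.median_error for p in out] == [12.0, 5.0, 3.0]

    def test_hand_computed_two_photo_fixture(self):
        scores = scores_frame([0.5] * 6, [1.0, 5.0, 9.0, 2.0, 2.0, 8.0])
        m = self._map({
            "i0": ("p1", "a"), "i1": ("p1", "b"), "i2": ("p1", "c"),
            "i3": ("p2", "a"), "i4": ("p2", "b"), "i5": ("p2", "c"),
        })
        out = {p.photo_id: p for p in photo_spread(scores, m)}
        assert out["p1"].median_error == 5.0 and out["p1"].error_range == (1.0, 9.0)
        assert out["p2"].median_error == 2.0 and out["p2"].error_range == (2.0, 8.0)

    def test_unmapped_image_rejected(self):
        scores = scores_frame([0.5], [1.0])
        with pytest.raises(ValueError):
            photo_spread(scores, self._map({"other": ("p", "v")}))


def _variability_dataset(points):
    """One view per photo, 3 nested raters; for (d, m) per photo the
    rater fractions are {m-d, m, m+d}% of a 100-px skin (sample SD d)
    and the 3-rater majority is the middle mask (m px), so with gt = 1 px
    the consensus error is m - 1."""
    skin = np.zeros((16, 16), bool)
    skin[:10, :10] = True          # 100 skin pixels
    flat = np.argwhere(skin)
    images, ds = {}, []
    raters = {f"r{j}": RaterProfile(f"r{j}", "low_feedback", j + 1,
                                    RaterSkill(0, 1, 0, 8)) for j in range(3)}

    def mask_of(k):
        m = np.zeros_like(skin)
        for r, c in flat[:k]:
            m[r, c] = True
        return m

    arrival = 0
    for i, (d, m) in enumerate(points):
        iid = f"ph{i}:0_0"
        gt = mask_of(1)
        images[iid] = skin_image_from_masks(skin, gt, image_id=iid,
                                            photo_id=f"ph{i}", split="gt_withheld")
        for j, k in enumerate((m - d, m, m + d)):
            arrival += 1
            ds.append(make_dem(mask_of(k), f"r{j}", iid, seq=j + 1, arrival=arrival))
    return StudyDataset(images=images, raters=raters, demarcations=ds)


class TestVariabilityVsError:
    CROWD = CrowdSpec("c", "low_feedback", first_r=3)

    def test_points_on_a_line(self):
        # (sd, median) pairs put (x, y) exactly on y = 2x + 1
        data = _variability_dataset([(1, 4), (2, 6), (3, 8), (4, 10)])
        reg, pts = variability_vs_error(data, self.CROWD)
        assert list(pts["sd_fraction"]) == [1, 2, 3, 4]
        assert list(pts["consensus_error"]) == [3, 5, 7, 9]
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_error_no_explainable_variance(self):
        data = _variability_dataset([(1, 6), (2, 6), (3, 6), (4, 6)])
        reg, _ = variability_vs_error(data, self.CROWD)
        assert reg.slope == pytest.approx(0.0)
        assert reg.r_squared == pytest.approx(0.0)

    def test_matches_normal_equations_on_four_points(self):
        data = _variability_dataset([(1, 5), (2, 9), (3, 8), (5, 14)])
        reg, pts = variability_vs_error(data, self.CROWD)
        x = pts["sd_fraction"].to_numpy(float)
        y = pts["consensus_error"].to_numpy(float)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert reg.slope == pytest.approx(beta[0])
        assert reg.intercept == pytest.approx(beta[1])
        assert reg.r_squared == pytest.approx(r2)

    def test_fewer_than_three_photos_rejected(self):
        data = _variability_dataset([(1, 4), (2, 6)])
        with pytest.raises(ValueError, match="3 photos"):
            variability_vs_error(data, self.CROWD)
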