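"""Study-level analyses of crowd performance.

Covers the four analyses a consensus-demarcation study reports: crowd
performance summaries (median/IQR/mean of Dice and surface area error),
Mann-Whitney comparison between crowds, the per-photo spread of error
across viewing angles of the same skin, and the regression of consensus
error on the spread of individual raters' surface-area estimates (does
disagreement predict inaccuracy?).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import assemble_crowd, majority_vote
from .metrics import score_image, surface_area_fraction
from .types import CrowdSpec, StudyDataset

__all__ = [
    "CrowdSummary",
    "RegressionResult",
    "PhotoSpread",
    "summarize_crowd",
    "compare_crowds",
    "photo_spread",
    "variability_vs_error",
    "score_crowd",
]

#: combined sample size at or below which the Mann-Whitney p-value is
#: computed by full enumeration rather than the normal approximation
EXACT_LIMIT = 12


@dataclass
class CrowdSummary:
    crowd_name: str
    n_images: int
    median_dice: float
    iqr_dice: tuple[float, float]
    median_sae: float
    iqr_sae: tuple[float, float]
    mean_dice: float
    mean_sae: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class PhotoSpread:
    photo_id: str
    per_view_errors: list[tuple[str, float]]
    median_error: float
    error_range: tuple[float, float]


# ---------------------------------------------------------------------------
# scoring a crowd over the evaluation set

def score_crowd(
    dataset: StudyDataset,
    crowd: CrowdSpec,
    scores=None,
    images=None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Consensus-vs-ground-truth scores for one crowd over ``images``
    (default: the withheld affected evaluation set). One row per image
    with the AgreementScore fields."""
    if images is None:
        images = dataset.evaluation_images()
    rows = []
    for img in images:
        crowd_demarcations = assemble_crowd(dataset, img.image_id, crowd, scores=scores)
        cons = majority_vote(crowd_demarcations, crowd_name=crowd.name, threshold=threshold)
        s = score_image(cons.mask, img, crowd.name)
        rows.append({
            "image_id": s.image_id, "crowd_name": s.label, "dice": s.dice,
            "surface_area_error": s.surface_area_error,
            "gt_fraction": s.gt_fraction, "pred_fraction": s.pred_fraction,
        })
    return pd.DataFrame(rows)


def summarize_crowd(scores: pd.DataFrame, crowd_name: str) -> CrowdSummary:
    """Median, IQR (25th/75th percentile, linear interpolation) and mean
    of Dice and surface area error over a crowd's per-image scores."""
    sub = scores[scores["crowd_name"] == crowd_name] if "crowd_name" in scores else scores
    if len(sub) == 0:
        raise ValueError(f"no score rows for crowd {crowd_name!r}")
    d = sub["dice"].to_numpy(dtype=float)
    e = sub["surface_area_error"].to_numpy(dtype=float)
    q = lambda x, p: float(np.percentile(x, p))  # noqa: E731 - linear interpolation
    return CrowdSummary(
        crowd_name=crowd_name,
        n_images=len(sub),
        median_dice=q(d, 50), iqr_dice=(q(d, 25), q(d, 75)),
        median_sae=q(e, 50), iqr_sae=(q(e, 25), q(e, 75)),
        mean_dice=float(d.mean()), mean_sae=float(e.mean()),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def compare_crowds(errors_a, errors_b) -> tuple[float, float]:
    """Mann-Whitney U (for sample A) with a two-sided p-value.

    Uses full enumeration of all C(n, n1) rank assignments when the
    combined sample size is at most ``EXACT_LIMIT`` (midranks handle
    ties); otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(list(errors_a), dtype=float)
    b = np.asarray(list(errors_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks = _midranks(np.concatenate([a, b]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n <= EXACT_LIMIT:
        total = comb(n, n1)
        le = ge = 0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            if u <= u_obs + 1e-9:
                le += 1
            if u >= u_obs - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_obs, p

    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    diff = u_obs - mean
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / sqrt(var)
    p = 2.0 * 0.5 * (1.0 - erf(abs(z) / sqrt(2.0)))
    return u_obs, min(1.0, p)


# ---------------------------------------------------------------------------
# per-photo spread across viewing angles

def photo_spread(scores: pd.DataFrame, image_map: pd.DataFrame) -> list[PhotoSpread]:
    """Per-photo surface-area-error spread across that photo's views,
    ordered by descending median error.

    ``scores`` needs columns image_id, surface_area_error; ``image_map``
    maps image_id -> (photo_id, view_label).
    """
    m = image_map.set_index("image_id")
    missing = [i for i in scores["image_id"] if i not in m.index]
    if missing:
        raise ValueError(f"images without a photo mapping: {missing[:5]}")
    joined = scores.join(m, on="image_id")
    out = []
    for photo_id, grp in joined.groupby("photo_id"):
        errs = [(str(v), float(e)) for v, e in
                zip(grp["view_label"], grp["surface_area_error"])]
        vals = np.array([e for _, e in errs])
        out.append(PhotoSpread(
            photo_id=str(photo_id),
            per_view_errors=errs,
            median_error=float(np.median(vals)),
            error_range=(float(vals.min()), float(vals.max())),
        ))
    out.sort(key=lambda p: -p.median_error)
    return out


# ---------------------------------------------------------------------------
# rater variability vs consensus accuracy

def variability_vs_error(
    dataset: StudyDataset,
    crowd: CrowdSpec,
    scores=None,
    photo_reduction: str = "median",
    sd_pooling: str = "pooled",
    threshold: float = 0.5,
) -> tuple[RegressionResult, pd.DataFrame]:
    """Regress per-photo consensus surface-area error on the SD of the
    crowd's individual surface-area estimates for that photo.

    x per photo: sample SD (n-1 denominator) of individual raters'
    surface-area fractions, pooled over the photo's views (or per-view
    SDs averaged, ``sd_pooling="per_view"``). y per photo: the
    ``photo_reduction`` (median or mean) over the photo's per-view
    consensus surface-area errors. Returns the OLS fit of y on x and
    the per-photo points.
    """
    if photo_reduction not in ("median", "mean"):
        raise ValueError("photo_reduction must be 'median' or 'mean'")
    if sd_pooling not in ("pooled", "per_view"):
        raise ValueError("sd_pooling must be 'pooled' or 'per_view'")

    images = dataset.evaluation_images()
    by_photo: dict[str, list] = {}
    for img in images:
        by_photo.setdefault(img.photo_id, []).append(img)
    if len(by_photo) < 3:
        raise ValueError(f"need at least 3 photos, got {len(by_photo)}")

    rows = []
    for photo_id in sorted(by_photo):
        fractions_pooled: list[float] = []
        per_view_sds: list[float] = []
        view_errors: list[float] = []
        for img in by_photo[photo_id]:
            ds = assemble_crowd(dataset, img.image_id, crowd, scores=scores)
            fracs = [surface_area_fraction(d.mask, img.skin_mask) for d in ds]
            fractions_pooled.extend(fracs)
            if len(fracs) > 1:
                per_view_sds.append(float(np.std(fracs, ddof=1)))
            cons = majority_vote(ds, crowd_name=crowd.name, threshold=threshold)
            view_errors.append(score_image(cons.mask, img, crowd.name).surface_area_error)
        if sd_pooling == "pooled":
            sd = float(np.std(fractions_pooled, ddof=1)) if len(fractions_pooled) > 1 else 0.0
        else:
            sd = float(np.mean(per_view_sds)) if per_view_sds else 0.0
        reduce = np.median if photo_reduction == "median" else np.mean
        rows.append({"photo_id": photo_id, "sd_fraction": sd,
                     "consensus_error": float(reduce(view_errors))})

    points = pd.DataFrame(rows)
    fit = stats.linregress(points["sd_fraction"], points["consensus_error"])
    r2 = float(fit.rvalue**2) if not np.isnan(fit.rvalue) else 0.0
    result = RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r2, n_points=len(points),
    )
    return result, points
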