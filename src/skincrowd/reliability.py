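"""Rater reliability tracking, top-k selection and learning curves.

Individual performance is tracked only on the ground-truth-provided
split (the images whose expert answer may be revealed as feedback); the
withheld split stays untouched for evaluation. Reliability ranks feed
per-image top-k crowd assembly. Learning curves bin each rater's error
over their first ``horizon`` submissions on affected withheld images.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .metrics import dice, surface_area_error
from .types import Demarcation, StudyDataset

__all__ = ["track_rater_performance", "select_top_k", "learning_curve"]

_METRICS = ("mean_dice", "mean_sae")


def _per_demarcation_value(d: Demarcation, dataset: StudyDataset, metric_name: str) -> float:
    img = dataset.images[d.image_id]
    if metric_name == "mean_dice":
        return dice(d.mask, img.gt_affected)
    return surface_area_error(d.mask, img.gt_affected, img.skin_mask)


def track_rater_performance(dataset: StudyDataset, metric_name: str = "mean_dice") -> pd.DataFrame:
    """Mean per-rater score over their demarcations of gt_provided images.

    Returns a DataFrame with columns ``rater_id, metric_name, value,
    n_scored, unscored, enrollment_order``; raters with no demarcation
    on the provided split carry ``unscored=True`` and a NaN value.
    """
    if metric_name not in _METRICS:
        raise ValueError(f"metric_name must be one of {_METRICS}")
    if not any(img.split == "gt_provided" for img in dataset.images.values()):
        raise ValueError("dataset has no gt_provided images to score raters on")

    values: dict[str, list[float]] = {rid: [] for rid in dataset.raters}
    for d in dataset.demarcations:
        if dataset.images[d.image_id].split != "gt_provided":
            continue
        values[d.rater_id].append(_per_demarcation_value(d, dataset, metric_name))

    rows = []
    for rid, rater in dataset.raters.items():
        vals = values[rid]
        rows.append({
            "rater_id": rid,
            "metric_name": metric_name,
            "value": float(np.mean(vals)) if vals else np.nan,
            "n_scored": len(vals),
            "unscored": len(vals) == 0,
            "enrollment_order": rater.enrollment_order,
        })
    return pd.DataFrame(rows).sort_values("rater_id", ignore_index=True)


def select_top_k(demarcations: list[Demarcation], scores: pd.DataFrame, k: int) -> list[Demarcation]:
    """The k demarcations whose raters rank best by reliability.

    Higher ``mean_dice`` is better; lower ``mean_sae`` is better.
    Unscored raters rank last; ties break toward the smaller
    enrollment_order. When fewer than k demarcations exist, all are
    returned with a warning.
    """
    if not demarcations:
        raise ValueError("cannot select from an empty demarcation list")
    if k < 1:
        raise ValueError("k must be >= 1")
    image_ids = {d.image_id for d in demarcations}
    if len(image_ids) > 1:
        raise ValueError(f"demarcations span multiple images: {sorted(image_ids)}")

    metric = scores["metric_name"].iloc[0] if len(scores) else "mean_dice"
    table = scores.set_index("rater_id")

    def sort_key(d: Demarcation):
        if d.rater_id in table.index and not bool(table.loc[d.rater_id, "unscored"]):
            v = float(table.loc[d.rater_id, "value"])
            rank_value = -v if metric == "mean_dice" else v
            unscored = 1 if np.isnan(v) else 0
        else:
            rank_value, unscored = 0.0, 1
        order = (int(table.loc[d.rater_id, "enrollment_order"])
                 if d.rater_id in table.index else np.inf)
        return (unscored, rank_value, order)

    ranked = sorted(demarcations, key=sort_key)
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} demarcations available for top-{k} selection",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]


def learning_curve(
    dataset: StudyDataset,
    window: int = 20,
    horizon: int = 100,
    metric_name: str = "mean_sae",
) -> pd.DataFrame:
    """Per-rater binned error over their first ``horizon`` affected
    withheld images, in the rater's own submission order.

    Only raters with at least ``horizon`` qualifying demarcations are
    included. Returns columns ``rater_id, bin_start, bin_end, mean_error``
    with ``horizon/window`` bins per rater (bins are 1-based image
    ranges, e.g. 1-20, 21-40, ...).
    """
    if metric_name not in _METRICS:
        raise ValueError(f"metric_name must be one of {_METRICS}")
    if window > horizon:
        raise ValueError("window must not exceed horizon")
    if horizon % window != 0:
        raise ValueError("window must divide horizon")

    qualifying: dict[str, list[Demarcation]] = {}
    for d in dataset.demarcations:
        img = dataset.images[d.image_id]
        if img.split == "gt_withheld" and img.is_affected:
            qualifying.setdefault(d.rater_id, []).append(d)

    rows = []
    for rid in sorted(qualifying):
        ds = sorted(qualifying[rid], key=lambda d: d.arrival_index)
        if len(ds) < horizon:
            continue
        ds = ds[:horizon]
        errs = np.array([_per_demarcation_value(d, dataset, metric_name) for d in ds])
        for b in range(horizon // window):
            rows.append({
                "rater_id": rid,
                "bin_start": b * window + 1,
                "bin_end": (b + 1) * window,
                "mean_error": float(errs[b * window:(b + 1) * window].mean()),
            })
    return pd.DataFrame(rows, columns=["rater_id", "bin_start", "bin_end", "mean_error"])
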