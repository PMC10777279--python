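"""Dataset and results persistence.

File layout written by :func:`write_dataset` (and read back losslessly
by :func:`read_dataset`):

    out_dir/
      config_echo.json          materialized generating configuration
      images.csv                image_id, photo_id, view_label, split, height, width
      raters.csv                rater_id, arm, enrollment_order, skill columns
      demarcations.csv          rater_id, image_id, sequence_index, arrival_index,
                                polygons as a JSON string of (row, col) loops
      exposure_log.csv          rater_id, image_id (feedback-counted cases)
      masks/<image_id>.skin.png 8-bit grayscale, 0 = false, 255 = true
      masks/<image_id>.gt.png

Demarcation masks are not stored: they re-rasterize exactly from the
polygon loops under the package's fixed pixel-center rule, which the
round-trip tests assert. All coordinates are 0-based (row, col) with
row 0 at the top.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .masks import read_mask_png, write_mask_png
from .raster import rasterize_polygons
from .reliability import learning_curve, track_rater_performance
from .types import CrowdSpec, Demarcation, RaterProfile, RaterSkill, SkinImage, StudyDataset

__all__ = ["write_dataset", "read_dataset", "run_study"]


def _encode_polygons(polygons) -> str:
    return json.dumps([np.asarray(p).round(6).tolist() for p in polygons])


def _decode_polygons(text: str):
    return [np.asarray(loop, dtype=float) for loop in json.loads(text)]


def write_dataset(dataset: StudyDataset, out_dir) -> Path:
    """Write a study to disk. The parent of ``out_dir`` must exist; the
    directory itself is created. Deterministic: the same dataset always
    produces byte-identical files."""
    out = Path(out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {out.parent}")
    out.mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    with open(out / "config_echo.json", "w", encoding="utf-8") as fh:
        json.dump(dataset.config_echo, fh, indent=2, sort_keys=True)
        fh.write("\n")

    img_rows = []
    for image_id in sorted(dataset.images):
        img = dataset.images[image_id]
        img_rows.append({
            "image_id": img.image_id, "photo_id": img.photo_id,
            "view_label": img.view_label, "split": img.split,
            "height": img.shape[0], "width": img.shape[1],
        })
        write_mask_png(img.skin_mask, out / "masks" / f"{image_id}.skin.png")
        write_mask_png(img.gt_affected, out / "masks" / f"{image_id}.gt.png")
    pd.DataFrame(img_rows).to_csv(out / "images.csv", index=False)

    rater_rows = []
    for rid in sorted(dataset.raters):
        r = dataset.raters[rid]
        rater_rows.append({
            "rater_id": r.rater_id, "arm": r.arm,
            "enrollment_order": r.enrollment_order,
            "boundary_jitter_sigma": r.skill.boundary_jitter_sigma,
            "region_detection_prob": r.skill.region_detection_prob,
            "false_positive_rate": r.skill.false_positive_rate,
            "node_budget": r.skill.node_budget,
        })
    pd.DataFrame(rater_rows).to_csv(out / "raters.csv", index=False)

    dem_rows = [{
        "rater_id": d.rater_id, "image_id": d.image_id,
        "sequence_index": d.sequence_index, "arrival_index": d.arrival_index,
        "polygons": _encode_polygons(d.polygons),
    } for d in dataset.demarcations]
    pd.DataFrame(
        dem_rows,
        columns=["rater_id", "image_id", "sequence_index", "arrival_index", "polygons"],
    ).to_csv(out / "demarcations.csv", index=False)

    exp_rows = [{"rater_id": rid, "image_id": iid}
                for rid in sorted(dataset.exposure_log)
                for iid in dataset.exposure_log[rid]]
    pd.DataFrame(exp_rows, columns=["rater_id", "image_id"]).to_csv(
        out / "exposure_log.csv", index=False)
    return out


def read_dataset(data_dir) -> StudyDataset:
    """Load a study written by :func:`write_dataset`, re-rasterizing
    demarcation masks from their polygon loops."""
    data = Path(data_dir)
    for required in ("images.csv", "raters.csv", "demarcations.csv", "config_echo.json"):
        if not (data / required).exists():
            raise FileNotFoundError(f"missing input file: {data / required}")

    with open(data / "config_echo.json", encoding="utf-8") as fh:
        config_echo = json.load(fh)

    images: dict[str, SkinImage] = {}
    for row in pd.read_csv(data / "images.csv").itertuples():
        skin = read_mask_png(data / "masks" / f"{row.image_id}.skin.png")
        gt = read_mask_png(data / "masks" / f"{row.image_id}.gt.png")
        images[row.image_id] = SkinImage(
            image_id=row.image_id, photo_id=row.photo_id,
            view_label=str(row.view_label), skin_mask=skin, gt_affected=gt,
            split=row.split,
        )

    raters: dict[str, RaterProfile] = {}
    for row in pd.read_csv(data / "raters.csv").itertuples():
        raters[row.rater_id] = RaterProfile(
            rater_id=row.rater_id, arm=row.arm,
            enrollment_order=int(row.enrollment_order),
            skill=RaterSkill(
                boundary_jitter_sigma=float(row.boundary_jitter_sigma),
                region_detection_prob=float(row.region_detection_prob),
                false_positive_rate=float(row.false_positive_rate),
                node_budget=int(row.node_budget),
            ),
        )

    demarcations: list[Demarcation] = []
    dem_df = pd.read_csv(data / "demarcations.csv")
    for row in dem_df.itertuples():
        polygons = _decode_polygons(row.polygons)
        img = images[row.image_id]
        mask = rasterize_polygons(polygons, img.shape) & img.skin_mask
        demarcations.append(Demarcation(
            rater_id=row.rater_id, image_id=row.image_id, polygons=polygons,
            mask=mask, sequence_index=int(row.sequence_index),
            arrival_index=int(row.arrival_index),
        ))

    exposure_log: dict[str, list[str]] = {rid: [] for rid in raters}
    exp_path = data / "exposure_log.csv"
    if exp_path.exists():
        for row in pd.read_csv(exp_path).itertuples():
            exposure_log[row.rater_id].append(row.image_id)

    return StudyDataset(images=images, raters=raters, demarcations=demarcations,
                        exposure_log=exposure_log, config_echo=config_echo)


def run_study(dataset: StudyDataset, out_dir, crowds=None, seed=None) -> Path:
    """Run the full analysis over a dataset and write all result tables.

    Pipeline per crowd: assemble -> plurality consensus -> agreement
    scores over the withheld affected evaluation set; plus rater
    reliability scores, the per-photo view spread, the variability
    regression and learning curves. Writes scores.csv, rater_scores.csv,
    summary.csv, regression.csv, photo_spread.csv, learning_curve.csv
    and run_log.json.
    """
    from .analysis import photo_spread, score_crowd, summarize_crowd, variability_vs_error

    out = Path(out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {out.parent}")
    out.mkdir(exist_ok=True)

    config = RunConfig.from_dict(dataset.config_echo) if dataset.config_echo else RunConfig()
    if crowds is None:
        crowds = config.crowds
    opts = config.analysis

    rater_scores = track_rater_performance(dataset, opts.ranking_metric)
    rater_scores.to_csv(out / "rater_scores.csv", index=False)

    all_scores, summaries, regressions = [], [], []
    spread_rows = []
    for name in sorted(crowds):
        crowd: CrowdSpec = crowds[name]
        scores = score_crowd(dataset, crowd, scores=rater_scores,
                             threshold=opts.vote_threshold)
        all_scores.append(scores)
        s = summarize_crowd(scores, name)
        summaries.append({
            "crowd_name": s.crowd_name, "n_images": s.n_images,
            "median_dice": s.median_dice, "iqr_dice_lo": s.iqr_dice[0],
            "iqr_dice_hi": s.iqr_dice[1], "median_sae": s.median_sae,
            "iqr_sae_lo": s.iqr_sae[0], "iqr_sae_hi": s.iqr_sae[1],
            "mean_dice": s.mean_dice, "mean_sae": s.mean_sae,
        })
        image_map = pd.DataFrame([
            {"image_id": img.image_id, "photo_id": img.photo_id,
             "view_label": img.view_label}
            for img in dataset.evaluation_images()
        ])
        for ps in photo_spread(scores, image_map):
            spread_rows.append({
                "crowd_name": name, "photo_id": ps.photo_id,
                "median_error": ps.median_error,
                "min_error": ps.error_range[0], "max_error": ps.error_range[1],
                "n_views": len(ps.per_view_errors),
            })
        try:
            reg, _pts = variability_vs_error(
                dataset, crowd, scores=rater_scores,
                photo_reduction=opts.photo_reduction, sd_pooling=opts.sd_pooling,
                threshold=opts.vote_threshold)
            regressions.append({
                "crowd_name": name, "slope": reg.slope, "intercept": reg.intercept,
                "r_squared": reg.r_squared, "n_points": reg.n_points,
            })
        except ValueError:
            pass  # fewer than 3 evaluation photos: regression undefined

    pd.concat(all_scores, ignore_index=True).to_csv(out / "scores.csv", index=False)
    pd.DataFrame(summaries).to_csv(out / "summary.csv", index=False)
    pd.DataFrame(regressions).to_csv(out / "regression.csv", index=False)
    pd.DataFrame(spread_rows).to_csv(out / "photo_spread.csv", index=False)

    # learning-curve horizon: first 100 qualifying images when the study
    # is large enough, else the largest 5-bin horizon any rater reached
    eval_ids = {img.image_id for img in dataset.evaluation_images()}
    per_rater = {}
    for d in dataset.demarcations:
        if d.image_id in eval_ids:
            per_rater[d.rater_id] = per_rater.get(d.rater_id, 0) + 1
    best = max(per_rater.values(), default=0)
    horizon = min(100, (best // 5) * 5)
    if horizon >= 5:
        lc = learning_curve(dataset, window=horizon // 5, horizon=horizon)
    else:
        lc = pd.DataFrame(columns=["rater_id", "bin_start", "bin_end", "mean_error"])
    lc.to_csv(out / "learning_curve.csv", index=False)

    log = {
        "seed": seed,
        "config_digest": config.digest(),
        "n_images": len(dataset.images),
        "n_raters": len(dataset.raters),
        "n_demarcations": len(dataset.demarcations),
        "versions": {
            "python": platform.python_version(),
            "skincrowd": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
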