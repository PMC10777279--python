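"""Plurality-vote consensus over crowd demarcations.

For one image, each pixel is labelled with the number of raters who
marked it; the consensus mask keeps every pixel marked by at least half
of the crowd (50% or more — pixels marked by exactly half of an even
crowd are included). Crowds are assembled either as the first r
submissions from an arm or as the top-k most reliable available raters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import require_same_shape
from .types import CrowdSpec, Demarcation, StudyDataset

__all__ = ["VoteCountMap", "ConsensusMask", "vote_counts", "majority_vote", "assemble_crowd"]


@dataclass
class VoteCountMap:
    image_id: str
    n_raters: int
    counts: np.ndarray


@dataclass
class ConsensusMask:
    image_id: str
    crowd_name: str
    n_raters: int
    mask: np.ndarray


def _check_group(demarcations: list[Demarcation]) -> None:
    if not demarcations:
        raise ValueError("need at least one demarcation")
    first = demarcations[0]
    for d in demarcations[1:]:
        if d.image_id != first.image_id:
            raise ValueError(
                f"mixed image_ids: {first.image_id!r} vs {d.image_id!r}"
            )
        require_same_shape(d.mask, first.mask)


def vote_counts(demarcations: list[Demarcation]) -> VoteCountMap:
    """Per-pixel tally of how many raters marked each pixel."""
    _check_group(demarcations)
    counts = np.zeros(demarcations[0].mask.shape, dtype=np.int32)
    for d in demarcations:
        counts += d.mask
    return VoteCountMap(
        image_id=demarcations[0].image_id,
        n_raters=len(demarcations),
        counts=counts,
    )


def majority_vote(
    demarcations: list[Demarcation],
    crowd_name: str = "crowd",
    threshold: float = 0.5,
) -> ConsensusMask:
    """Plurality-vote consensus: pixels marked by >= threshold of the crowd.

    ``threshold`` defaults to the study-faithful 0.5; exact-half ties in
    even crowds are included ("50% or more").
    """
    vc = vote_counts(demarcations)
    mask = vc.counts >= threshold * vc.n_raters
    return ConsensusMask(
        image_id=vc.image_id,
        crowd_name=crowd_name,
        n_raters=vc.n_raters,
        mask=mask,
    )


def assemble_crowd(
    dataset: StudyDataset,
    image_id: str,
    crowd: CrowdSpec,
    scores=None,
) -> list[Demarcation]:
    """Pick the demarcations forming ``crowd`` for one image.

    first_r mode: the r earliest submissions (smallest sequence_index)
    from the crowd's arm; it is an error if fewer than r exist.
    top_k mode: the k available raters from the arm with the best
    reliability scores (``scores`` as produced by
    :func:`skincrowd.reliability.track_rater_performance`).
    Output is ordered by sequence_index either way.
    """
    cand = [
        d for d in dataset.demarcations_for_image(image_id)
        if dataset.raters[d.rater_id].arm == crowd.arm
    ]
    if crowd.first_r is not None:
        if len(cand) < crowd.first_r:
            raise ValueError(
                f"image {image_id!r}: only {len(cand)} demarcations available "
                f"in arm {crowd.arm!r}, need first_r={crowd.first_r}"
            )
        return cand[: crowd.first_r]
    if scores is None:
        raise ValueError("top_k crowd assembly requires a rater score table")
    from .reliability import select_top_k

    chosen = select_top_k(cand, scores, crowd.top_k)
    return sorted(chosen, key=lambda d: d.sequence_index)
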