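"""Directional confusion structures: near/far grouping and pair-count matrices.

Each image's multiple-choice responses are split into a *near* group and a
*far* group — by the selected distance unit in the unbiased experiment
(micrometer/millimeter/centimeter vs meter/kilometer), or by the experimental
manipulation group when apparent distance was manipulated.  Every near
response is paired with every far response, so the count for the ordered
category pair (a, b) is (# near responses of a) x (# far responses of b):
the relative frequency of the directional confusion a-seen-near vs
b-seen-far.  Responses from different images are never paired.

Coordinate convention, used everywhere: ``counts[near_category, far_category]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data_io import (
    CategoryVocabulary,
    DistanceUnit,
    Experiment,
    Group,
    ResponseRecord,
    default_vocabulary,
)

__all__ = [
    "PairCountMatrix",
    "assign_distance_group",
    "group_by_manipulation",
    "pair_counts",
    "pair_counts_from_vectors",
    "aggregate_matrix",
    "display_filter",
    "WrongExperimentError",
]

NEAR = "near"
FAR = "far"

_NEAR_UNITS = {DistanceUnit.MICROMETER, DistanceUnit.MILLIMETER, DistanceUnit.CENTIMETER}
_NEAR_GROUPS = {Group.INSTRUCT_NEAR, Group.OBJECT_SMALL}
_FAR_GROUPS = {Group.INSTRUCT_FAR, Group.OBJECT_LARGE}


class WrongExperimentError(ValueError):
    pass


def assign_distance_group(unit: DistanceUnit) -> str:
    """Map a distance unit to the near/far partition.

    Micrometer, millimeter and centimeter responses form the near group;
    meter and kilometer responses form the far group.
    """
    return NEAR if unit in _NEAR_UNITS else FAR


def group_by_manipulation(record: ResponseRecord) -> str:
    """Near/far partition for the manipulated experiments.

    The instructed-near and small-object (hornet) groups imply a close-up
    reading; instructed-far and large-object (airplane) imply a distant one.
    """
    if record.experiment is Experiment.EXP1:
        raise WrongExperimentError(
            "unbiased records are grouped by distance unit, not manipulation"
        )
    if record.group in _NEAR_GROUPS:
        return NEAR
    if record.group in _FAR_GROUPS:
        return FAR
    raise WrongExperimentError(f"group {record.group.value!r} has no manipulation")


@dataclass(frozen=True)
class PairCountMatrix:
    """Per-image directional confusion counts.

    ``counts[i, j]`` is the number of (near response of category i, far
    response of category j) pairs; rows index the near category, columns the
    far category, over the full vocabulary so the averaging set of the
    ambiguity statistic is identical for every image.  An image whose
    responses all fall in one distance group yields no pairs and is flagged
    ``degenerate``.
    """

    image_id: str
    counts: np.ndarray
    categories: tuple[str, ...]
    near_total: int
    far_total: int

    @property
    def degenerate(self) -> bool:
        return self.near_total == 0 or self.far_total == 0

    def transpose(self) -> "PairCountMatrix":
        return PairCountMatrix(
            self.image_id, self.counts.T.copy(), self.categories,
            self.far_total, self.near_total,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: image_id, near_category, far_category, count."""
        near_idx, far_idx = np.nonzero(self.counts)
        return pd.DataFrame({
            "image_id": self.image_id,
            "near_category": [self.categories[i] for i in near_idx],
            "far_category": [self.categories[j] for j in far_idx],
            "count": self.counts[near_idx, far_idx].astype(int),
        })


def _category_index(vocab: CategoryVocabulary) -> dict[str, int]:
    return {c: i for i, c in enumerate(vocab.choice_categories)}


def pair_counts(
    near_cats: Iterable[str],
    far_cats: Iterable[str],
    vocab: CategoryVocabulary | None = None,
    image_id: str = "",
) -> PairCountMatrix:
    """Directional pair counts from the two response multisets of one image.

    ``counts[a, b] = multiplicity(a in near) * multiplicity(b in far)`` —
    the Cartesian product of the near and far responses.
    """
    vocab = vocab or default_vocabulary()
    index = _category_index(vocab)
    k = len(index)
    near_vec = np.zeros(k, dtype=np.int64)
    far_vec = np.zeros(k, dtype=np.int64)
    for c in near_cats:
        near_vec[index[c]] += 1
    for c in far_cats:
        far_vec[index[c]] += 1
    return pair_counts_from_vectors(near_vec, far_vec, vocab, image_id)


def pair_counts_from_vectors(
    near_vec: np.ndarray,
    far_vec: np.ndarray,
    vocab: CategoryVocabulary,
    image_id: str = "",
) -> PairCountMatrix:
    """Pair counts from per-category response count vectors (fast path)."""
    counts = np.outer(near_vec, far_vec)
    return PairCountMatrix(
        image_id=image_id,
        counts=counts,
        categories=tuple(vocab.choice_categories),
        near_total=int(near_vec.sum()),
        far_total=int(far_vec.sum()),
    )


def aggregate_matrix(
    matrices: Iterable[PairCountMatrix],
    normalize: bool = False,
) -> pd.DataFrame:
    """Cell-wise sum of per-image pair counts across images.

    With ``normalize``, rescale linearly so the maximum cell equals 1 (the
    display convention for the pooled confusion matrix).
    """
    matrices = list(matrices)
    if not matrices:
        return pd.DataFrame()
    cats = matrices[0].categories
    for m in matrices:
        if m.categories != cats:
            raise ValueError("matrices must share a vocabulary")
    total = np.zeros((len(cats), len(cats)), dtype=float)
    for m in matrices:
        total += m.counts
    if normalize and total.max() > 0:
        total = total / total.max()
    return pd.DataFrame(total, index=list(cats), columns=list(cats))


def display_filter(
    matrix: pd.DataFrame,
    ground_truth_set: Iterable[str],
    drop_diagonal: bool = False,
) -> pd.DataFrame:
    """Restrict an aggregated matrix to ground-truth categories for display.

    Optionally zero the diagonal, omitting the cases where both distance
    groups selected the same category.
    """
    keep = [c for c in matrix.index if c in set(ground_truth_set)]
    out = matrix.loc[keep, keep].copy()
    if drop_diagonal:
        np.fill_diagonal(out.values, 0.0)
    return out
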