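"""Exploratory analyses: appearance attributes, organic split, MSA classifier.

Three follow-up questions about what drives material-scale ambiguity:
whether rated appearance attributes (blue tint, blurriness, direct lighting,
gloss, slant) differ between images judged predominantly near vs far;
whether organic (natural) material categories dominate far readings; and
whether the attribute features predict high- vs low-ambiguity images under a
repeated random-split classifier protocol (RBF-kernel SVM with per-split
grid search by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .confusion import NEAR, FAR, assign_distance_group
from .data_io import (
    ATTRIBUTE_NAMES,
    Block,
    CategoryVocabulary,
    DistanceUnit,
    ImageMeta,
    ResponseRecord,
    default_vocabulary,
)
from .inference import TestOutcome, compare_confidence

__all__ = [
    "ClassifierProtocolResult",
    "modal_distance_group",
    "attribute_by_distance",
    "organic_split_frequencies",
    "msa_classifier_protocol",
]


@dataclass(frozen=True)
class ClassifierProtocolResult:
    """Mean test accuracy over repeated random train/test splits."""

    n_splits: int
    mean_cv_accuracy: float
    per_split_accuracies: tuple[float, ...]
    seed: int

    def __post_init__(self):
        assert np.isclose(self.mean_cv_accuracy, np.mean(self.per_split_accuracies))


def modal_distance_group(image_records: Iterable[ResponseRecord]) -> str:
    """Near/far group of an image's most frequent distance unit.

    Ties between units are broken toward the smaller (nearer) unit, so an
    exact near/far tie resolves to near; documented tie rule.
    """
    units = [r.distance_unit for r in image_records
             if r.block is Block.DISTANCE and r.distance_unit is not None]
    if not units:
        raise ValueError("no distance responses for this image")
    tally = Counter(units)
    best = min(tally.items(), key=lambda kv: (-kv[1], kv[0].ordinal_rank))
    return assign_distance_group(best[0])


def attribute_by_distance(
    images: Sequence[ImageMeta],
    modal_groups: Mapping[str, str],
) -> dict[str, TestOutcome]:
    """Mann-Whitney U + pooled-SD d per attribute, near vs far images."""
    outcomes = {}
    for attr in ATTRIBUTE_NAMES:
        near_vals = [im.attribute_ratings[attr] for im in images
                     if attr in im.attribute_ratings
                     and modal_groups.get(im.image_id) == NEAR]
        far_vals = [im.attribute_ratings[attr] for im in images
                    if attr in im.attribute_ratings
                    and modal_groups.get(im.image_id) == FAR]
        if not near_vals or not far_vals:
            raise ValueError(f"attribute {attr!r}: a distance group is empty")
        outcomes[attr] = compare_confidence(near_vals, far_vals)
    return outcomes


def organic_split_frequencies(
    category_ratings: Mapping[str, float],
    exp1_records: Iterable[ResponseRecord],
    vocab: CategoryVocabulary | None = None,
) -> dict[str, float]:
    """Fraction of near- and far-group responses in organic categories.

    Organic categories are those rated strictly above the median
    organic/natural rating over all 26 categories; a category at exactly the
    median is inorganic (below-or-equal rule).  Responses are the unbiased
    experiment's multiple-choice selections, partitioned near/far by the
    participant's distance unit for the same image.
    """
    vocab = vocab or default_vocabulary()
    missing = set(vocab.choice_categories) - set(category_ratings)
    if missing:
        raise ValueError(f"ratings missing for categories: {sorted(missing)}")
    values = [category_ratings[c] for c in vocab.choice_categories]
    median = float(np.median(values))
    organic = {c for c in vocab.choice_categories if category_ratings[c] > median}

    choices: dict[tuple[str, str], str] = {}
    units: dict[tuple[str, str], DistanceUnit] = {}
    for r in exp1_records:
        key = (r.participant_id, r.image_id)
        if r.block is Block.CHOICE:
            choices[key] = r.category
        elif r.block is Block.DISTANCE:
            units[key] = r.distance_unit
    counts = {NEAR: [0, 0], FAR: [0, 0]}  # [organic, total]
    for key, cat in choices.items():
        if key not in units:
            continue
        g = assign_distance_group(units[key])
        counts[g][1] += 1
        if cat in organic:
            counts[g][0] += 1
    out = {}
    for g, (org, total) in counts.items():
        out[g] = org / total if total else float("nan")
    return out


def _default_classifier_factory(param_grid, inner_cv, seed):
    def make():
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf")),
        ])
        return GridSearchCV(
            pipe, param_grid=param_grid,
            cv=StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed),
            scoring="accuracy",
        )
    return make


def msa_classifier_protocol(
    images: Sequence[ImageMeta],
    msa_per_image: Mapping[str, float],
    n_splits: int = 1000,
    seed: int = 0,
    test_size: float = 0.25,
    param_grid: Mapping[str, Sequence[float]] | None = None,
    inner_cv: int = 3,
    classifier_factory: Callable[[], object] | None = None,
) -> ClassifierProtocolResult:
    """Repeated random-split classification of high- vs low-MSA images.

    The target is a median split of per-image MSA (an image at exactly the
    median counts as low).  For each of ``n_splits`` random stratified
    75/25 train/test partitions a fresh classifier — by default an
    RBF-kernel SVM whose C and gamma are grid-searched on the training
    data over a logarithmic 1e-3..1e3 grid — is fit and scored on the test
    set; the result is the mean test accuracy.  Splits that would leave a
    single class in either partition are re-drawn.
    """
    usable = [im for im in images
              if im.image_id in msa_per_image
              and all(a in im.attribute_ratings for a in ATTRIBUTE_NAMES)]
    if len(usable) < 20:
        raise ValueError(f"need >= 20 images with complete features, got {len(usable)}")
    X = np.array([
        [im.attribute_ratings[a] for a in ATTRIBUTE_NAMES]
        + ([im.self_similarity] if im.self_similarity is not None else [])
        for im in usable
    ])
    msa = np.array([msa_per_image[im.image_id] for im in usable])
    y = (msa > np.median(msa)).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("MSA median split produced a single class")

    if param_grid is None:
        grid = np.logspace(-3, 3, 7)
        param_grid = {"svm__C": grid, "svm__gamma": grid}
    factory = classifier_factory or _default_classifier_factory(param_grid, inner_cv, seed)

    rng = np.random.default_rng(seed)
    accuracies = []
    for _ in range(n_splits):
        while True:
            split_seed = int(rng.integers(2**31))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, stratify=y, random_state=split_seed,
            )
            if len(np.unique(y_tr)) == 2 and len(np.unique(y_te)) == 2:
                break
        model = factory()
        model.fit(X_tr, y_tr)
        accuracies.append(float(model.score(X_te, y_te)))
    return ClassifierProtocolResult(
        n_splits=n_splits,
        mean_cv_accuracy=float(np.mean(accuracies)),
        per_split_accuracies=tuple(accuracies),
        seed=seed,
    )
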