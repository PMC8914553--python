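"""Material-Scale Ambiguity: the directional-asymmetry statistic and its nulls.

For one image, the near and far response groups define a pair-count matrix
``C`` over the category vocabulary (``C[a, b]`` = # near responses of a times
# far responses of b).  The Material-Scale Ambiguity (MSA) is the root mean
squared difference between corresponding cells of the lower and upper
triangles of ``C``, the diagonal excluded:

    MSA = sqrt( mean over unordered pairs {a, b}, a != b of (C[a,b] - C[b,a])^2 )

A symmetric confusion pattern — one that does not depend on assumed
distance — gives MSA = 0; directional (distance-dependent) confusions give
MSA > 0.  By default the averaging set is all C(26, 2) = 325 vocabulary
pairs with raw pair counts, so the denominator is identical for every image;
both choices are pluggable (``pair_set``, ``count_scale``).

Chance levels come from permutation nulls: shuffling the distance units
across an image's responses (unbiased experiment, response level) or
shuffling participants' group membership (manipulated experiments,
participant level), recomputing MSA each time, and averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .confusion import (
    NEAR,
    PairCountMatrix,
    assign_distance_group,
    group_by_manipulation,
    pair_counts_from_vectors,
)
from .data_io import (
    Block,
    CategoryVocabulary,
    DistanceUnit,
    Experiment,
    ResponseRecord,
    default_vocabulary,
)
from .inference import DegenerateDataError, wilcoxon_paired

__all__ = [
    "MSAResult",
    "ExperimentSummary",
    "msa_from_counts",
    "msa_from_vectors",
    "permuted_msa_units",
    "chance_msa_units",
    "chance_msa_groups",
    "summarize_experiment",
    "rank_images",
    "paired_choice_units",
    "analyze_exp1_msa",
    "analyze_exp2_msa",
]

PairSet = Literal["full_vocab", "observed_only"]
CountScale = Literal["raw", "normalized"]


@dataclass(frozen=True)
class MSAResult:
    """Per-image observed MSA and its permutation chance level."""

    image_id: str
    msa_observed: float | None
    msa_chance: float | None
    n_permutations: int
    seed: int
    degenerate: bool = False

    @property
    def above_chance(self) -> bool:
        if self.degenerate:
            return False
        return self.msa_observed > self.msa_chance


@dataclass(frozen=True)
class ExperimentSummary:
    """Experiment-level MSA summary with the paired observed-vs-chance test."""

    experiment: str
    mean_msa_observed: float
    ci_observed: tuple[float, float]
    mean_msa_chance: float
    ci_chance: tuple[float, float]
    wilcoxon_T: float
    p_value: float
    paired_d: float
    n_images_above_chance: int
    n_images: int

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "mean_msa_observed": self.mean_msa_observed,
            "ci95_observed": list(self.ci_observed),
            "mean_msa_chance": self.mean_msa_chance,
            "ci95_chance": list(self.ci_chance),
            "wilcoxon_T": self.wilcoxon_T,
            "p_value": self.p_value,
            "paired_d": self.paired_d,
            "n_images_above_chance": self.n_images_above_chance,
            "n_images": self.n_images,
        }


# ---------------------------------------------------------------------------
# the statistic


def _scaled(counts: np.ndarray, near_total: int, far_total: int,
            count_scale: CountScale) -> np.ndarray:
    if count_scale == "raw":
        return np.asarray(counts, dtype=float)
    if count_scale == "normalized":
        denom = near_total * far_total
        return np.asarray(counts, dtype=float) / denom if denom else np.asarray(counts, dtype=float)
    raise ValueError(f"unknown count_scale: {count_scale!r}")


def msa_from_counts(
    matrix: PairCountMatrix,
    pair_set: PairSet = "full_vocab",
    count_scale: CountScale = "raw",
) -> float:
    """RMSE between the lower and upper triangles of a pair-count matrix."""
    if matrix.degenerate:
        raise DegenerateDataError(
            f"image {matrix.image_id!r}: all responses in one distance group"
        )
    c = _scaled(matrix.counts, matrix.near_total, matrix.far_total, count_scale)
    if pair_set == "observed_only":
        support = np.flatnonzero(c.sum(axis=0) + c.sum(axis=1))
        c = c[np.ix_(support, support)]
        if c.shape[0] < 2:
            return 0.0
    elif pair_set != "full_vocab":
        raise ValueError(f"unknown pair_set: {pair_set!r}")
    k = c.shape[0]
    iu = np.triu_indices(k, k=1)
    diffs = c[iu] - c.T[iu]
    return float(np.sqrt(np.mean(diffs**2)))


def msa_from_vectors(near_vec: np.ndarray, far_vec: np.ndarray) -> float:
    """Fast MSA for the default options, from per-category count vectors.

    A pair-count matrix is the outer product ``u v^T``, so the sum of squared
    triangle asymmetries collapses to ``|u|^2 |v|^2 - (u . v)^2`` over
    C(k, 2) unordered pairs.  Equals :func:`msa_from_counts` with
    ``pair_set="full_vocab"``, ``count_scale="raw"``.
    """
    u = np.asarray(near_vec, dtype=float)
    v = np.asarray(far_vec, dtype=float)
    k = u.size
    ss = (u @ u) * (v @ v) - (u @ v) ** 2
    n_pairs = k * (k - 1) // 2
    return float(np.sqrt(max(ss, 0.0) / n_pairs))


# ---------------------------------------------------------------------------
# permutation nulls


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def permuted_msa_units(
    categories: Sequence[str],
    units: Sequence[DistanceUnit],
    vocab: CategoryVocabulary | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """MSA values under random permutations of distance units (response level).

    The unit multiset is preserved and category responses are fixed, so each
    permutation only re-divides the same responses into near and far groups.
    Returns the full null sample of length ``n_perm``.
    """
    vocab = vocab or default_vocabulary()
    if len(categories) != len(units):
        raise ValueError("categories and units must be parallel")
    near_mask = np.array([assign_distance_group(u) == NEAR for u in units])
    if near_mask.all() or (~near_mask).all():
        raise DegenerateDataError("all responses in one distance group")
    index = {c: i for i, c in enumerate(vocab.choice_categories)}
    cat_idx = np.array([index[c] for c in categories])
    k = len(index)
    rng = _as_rng(seed)
    out = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(near_mask)
        u = np.bincount(cat_idx[perm], minlength=k)
        v = np.bincount(cat_idx[~perm], minlength=k)
        out[j] = msa_from_vectors(u, v)
    return out


def chance_msa_units(
    categories: Sequence[str],
    units: Sequence[DistanceUnit],
    vocab: CategoryVocabulary | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean MSA over random permutations of distance units (response level)."""
    return float(permuted_msa_units(categories, units, vocab, n_perm, seed).mean())


def chance_msa_groups(
    response_matrix: np.ndarray,
    near_participants: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-image chance MSA from permuting group membership (participant level).

    ``response_matrix[p, i]`` is participant p's category index for image i;
    ``near_participants`` is the boolean group assignment.  Each permutation
    moves a participant's full response set between groups, preserving group
    sizes, then MSA is recomputed for every image.
    """
    resp = np.asarray(response_matrix)
    mask = np.asarray(near_participants, dtype=bool)
    if mask.all() or (~mask).all():
        raise ValueError("both groups must be non-empty")
    n_part, n_images = resp.shape
    k = int(resp.max()) + 1 if resp.size else 0
    rng = _as_rng(seed)
    totals = np.zeros(n_images)
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        for i in range(n_images):
            u = np.bincount(resp[perm, i], minlength=k)
            v = np.bincount(resp[~perm, i], minlength=k)
            totals[i] += msa_from_vectors(u, v)
    return totals / n_perm


# ---------------------------------------------------------------------------
# record-level pipelines


def paired_choice_units(
    records: Iterable[ResponseRecord],
) -> dict[str, list[tuple[str, DistanceUnit]]]:
    """Join each participant's category choice with their distance unit.

    Returns, per image, the (category, unit) pairs for participants who
    completed both the multiple-choice and distance blocks for that image.
    """
    choices: dict[tuple[str, str], str] = {}
    units: dict[tuple[str, str], DistanceUnit] = {}
    order: list[str] = []
    for r in records:
        key = (r.participant_id, r.image_id)
        if r.block is Block.CHOICE:
            choices[key] = r.category
        elif r.block is Block.DISTANCE:
            units[key] = r.distance_unit
        if r.image_id not in order:
            order.append(r.image_id)
    out: dict[str, list[tuple[str, DistanceUnit]]] = {im: [] for im in order}
    for key, cat in choices.items():
        if key in units:
            out[key[1]].append((cat, units[key]))
    return out


def analyze_exp1_msa(
    records: Iterable[ResponseRecord],
    vocab: CategoryVocabulary | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    pair_set: PairSet = "full_vocab",
    count_scale: CountScale = "raw",
) -> list[MSAResult]:
    """Observed and unit-permutation chance MSA per image, unbiased design."""
    vocab = vocab or default_vocabulary()
    per_image = paired_choice_units(records)
    index = {c: i for i, c in enumerate(vocab.choice_categories)}
    k = len(index)
    results = []
    master = np.random.default_rng(seed)
    for image_id in sorted(per_image):
        pairs = per_image[image_id]
        image_seed = int(master.integers(2**31))
        near = [c for c, u in pairs if assign_distance_group(u) == NEAR]
        far = [c for c, u in pairs if assign_distance_group(u) != NEAR]
        if not near or not far:
            results.append(MSAResult(image_id, None, None, n_perm, image_seed, True))
            continue
        u = np.bincount([index[c] for c in near], minlength=k)
        v = np.bincount([index[c] for c in far], minlength=k)
        if pair_set == "full_vocab" and count_scale == "raw":
            observed = msa_from_vectors(u, v)
        else:
            observed = msa_from_counts(
                pair_counts_from_vectors(u, v, vocab, image_id),
                pair_set=pair_set, count_scale=count_scale,
            )
        chance = _chance_units_options(
            pairs, vocab, n_perm, image_seed, pair_set, count_scale
        )
        results.append(MSAResult(image_id, observed, chance, n_perm, image_seed))
    return results


def _chance_units_options(pairs, vocab, n_perm, seed, pair_set, count_scale):
    if pair_set == "full_vocab" and count_scale == "raw":
        return chance_msa_units(
            [c for c, _ in pairs], [u for _, u in pairs], vocab, n_perm, seed
        )
    # generic (slower) path for non-default statistic options
    index = {c: i for i, c in enumerate(vocab.choice_categories)}
    k = len(index)
    cat_idx = np.array([index[c] for c, _ in pairs])
    near_mask = np.array([assign_distance_group(u) == NEAR for _, u in pairs])
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(near_mask)
        u = np.bincount(cat_idx[perm], minlength=k)
        v = np.bincount(cat_idx[~perm], minlength=k)
        m = pair_counts_from_vectors(u, v, vocab)
        total += msa_from_counts(m, pair_set=pair_set, count_scale=count_scale)
    return total / n_perm


def analyze_exp2_msa(
    records: Iterable[ResponseRecord],
    vocab: CategoryVocabulary | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[MSAResult]:
    """Observed and group-permutation chance MSA per image, manipulated design.

    Records must come from a single manipulated experiment (instructions or
    familiar objects).  The permutation is at participant level: each
    participant's full response set moves between groups together.
    """
    vocab = vocab or default_vocabulary()
    index = {c: i for i, c in enumerate(vocab.choice_categories)}
    k = len(index)
    choice = [r for r in records if r.block is Block.CHOICE]
    if not choice:
        raise ValueError("no multiple-choice records")
    experiments = {r.experiment for r in choice}
    if len(experiments) != 1 or Experiment.EXP1 in experiments:
        raise ValueError("records must come from a single manipulated experiment")
    participants = sorted({r.participant_id for r in choice})
    images = sorted({r.image_id for r in choice})
    p_idx = {p: i for i, p in enumerate(participants)}
    i_idx = {im: i for i, im in enumerate(images)}
    resp = np.full((len(participants), len(images)), -1, dtype=int)
    near_mask = np.zeros(len(participants), dtype=bool)
    for r in choice:
        resp[p_idx[r.participant_id], i_idx[r.image_id]] = index[r.category]
        near_mask[p_idx[r.participant_id]] = group_by_manipulation(r) == NEAR
    if (resp < 0).any():
        raise ValueError("every participant must respond to every image")
    if near_mask.all() or (~near_mask).all():
        raise ValueError("both manipulation groups must be present")

    chance = chance_msa_groups(resp, near_mask, n_perm=n_perm, seed=seed)
    results = []
    for im in images:
        i = i_idx[im]
        u = np.bincount(resp[near_mask, i], minlength=k)
        v = np.bincount(resp[~near_mask, i], minlength=k)
        observed = msa_from_vectors(u, v)
        results.append(MSAResult(im, observed, float(chance[i]), n_perm, seed))
    return results


# ---------------------------------------------------------------------------
# summaries and rankings


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator,
                  n_boot: int = 10_000) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def summarize_experiment(
    results: Iterable[MSAResult],
    experiment: str = "",
    n_boot: int = 10_000,
    seed: int = 0,
) -> ExperimentSummary:
    """Experiment-level means with bootstrap CIs and the paired Wilcoxon test.

    Degenerate images are excluded.  The confidence intervals are seeded
    percentile bootstraps of the mean; the paired effect size is
    mean(observed - chance) / sd(observed - chance); an image counts as
    above chance when its observed MSA exceeds its permutation mean.
    """
    usable = [r for r in results if not r.degenerate]
    if len(usable) < 6:
        raise ValueError(f"need at least 6 non-degenerate images, got {len(usable)}")
    obs = np.array([r.msa_observed for r in usable])
    cha = np.array([r.msa_chance for r in usable])
    rng = np.random.default_rng(seed)
    ci_obs = _bootstrap_ci(obs, rng, n_boot)
    ci_cha = _bootstrap_ci(cha, rng, n_boot)
    try:
        test = wilcoxon_paired(obs, cha)
        T, p, d = test.statistic_value, test.p_value, test.effect_size_value
    except DegenerateDataError:
        T, p, d = float("nan"), 1.0, 0.0
    return ExperimentSummary(
        experiment=experiment,
        mean_msa_observed=float(obs.mean()),
        ci_observed=ci_obs,
        mean_msa_chance=float(cha.mean()),
        ci_chance=ci_cha,
        wilcoxon_T=T,
        p_value=p,
        paired_d=d,
        n_images_above_chance=int(sum(r.above_chance for r in usable)),
        n_images=len(usable),
    )


def rank_images(
    results_by_experiment: Mapping[str, Sequence[MSAResult]],
    combine: bool = False,
) -> list[str]:
    """Image ids in descending MSA order; ties broken by image id.

    With ``combine``, images are ranked by their mean observed MSA across
    experiments; otherwise a single experiment's results are expected.
    """
    if combine:
        per_image: dict[str, list[float]] = {}
        for results in results_by_experiment.values():
            for r in results:
                if not r.degenerate:
                    per_image.setdefault(r.image_id, []).append(r.msa_observed)
        scores = {im: float(np.mean(v)) for im, v in per_image.items()}
    else:
        if len(results_by_experiment) != 1:
            raise ValueError("pass a single experiment or set combine=True")
        (results,) = results_by_experiment.values()
        scores = {r.image_id: r.msa_observed for r in results if not r.degenerate}
    return sorted(scores, key=lambda im: (-scores[im], im))
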