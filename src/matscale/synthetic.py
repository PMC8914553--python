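"""Generative observer model for trial-level material-categorization data.

Simulates the statistical structure the analysis assumes: each participant
adopts a *reading* of an image (near or far assumed viewing distance) and
then draws a material category from a reading-conditional distribution.  A
per-image asymmetry parameter ``lam`` interpolates between scale-independent
responding (lam = 0: the near and far conditionals are identical, so
directional confusions are symmetric in expectation) and a fully
distance-dependent confusable pair (lam = 1: near responses concentrate on
one category, far responses on the other — e.g. bark seen close-up vs stone
seen from afar).

The unbiased design samples readings with probability ``p_near`` and emits a
free-text block, a multiple-choice block with confidence, and a distance
block whose unit is consistent with the reading.  The manipulated designs
shift ``p_near`` by +/- delta per group (instructions), attenuated for the
familiar-objects modality, and emit no distance block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    Block,
    CategoryVocabulary,
    DistanceUnit,
    Experiment,
    Group,
    ImageMeta,
    ResponseRecord,
    default_vocabulary,
)

__all__ = [
    "ImageSpec",
    "SyntheticDesign",
    "simulate_exp1",
    "simulate_exp2",
    "default_design",
    "attribute_table",
]

_NEAR_UNITS = (DistanceUnit.MICROMETER, DistanceUnit.MILLIMETER, DistanceUnit.CENTIMETER)
_FAR_UNITS = (DistanceUnit.METER, DistanceUnit.KILOMETER)

# free-text modifiers prepended occasionally so the normalization chain is
# exercised end-to-end (the lexicon's compound rule strips them)
_MODIFIERS = ("scratched", "desert", "wet", "old", "rough", "dark")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ImageSpec:
    """Generative parameters for one image.

    ``lam`` interpolates the two reading-conditional category distributions
    between a shared base distribution (lam = 0) and point masses on the
    confusable pair ``(pair_near, pair_far)`` (lam = 1):

        near_dist = (1 - lam) * base + lam * point_mass(pair_near)
        far_dist  = (1 - lam) * base + lam * point_mass(pair_far)
    """

    image_id: str
    ground_truth: str
    pair_near: str
    pair_far: str
    lam: float = 0.0
    base_dist: Mapping[str, float] | None = None
    p_near: float = 0.5
    near_unit_probs: tuple[float, float, float] = (0.15, 0.35, 0.5)
    far_unit_probs: tuple[float, float] = (0.7, 0.3)
    confidence_mean: float = 5.0
    confidence_sd: float = 1.0
    manipulation_delta: float = 0.4

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise DesignError(f"lam must be in [0, 1], got {self.lam}")
        if not 0.0 <= self.p_near <= 1.0:
            raise DesignError(f"p_near must be in [0, 1], got {self.p_near}")
        if not 0.0 <= self.manipulation_delta <= 0.5:
            raise DesignError("manipulation_delta must be in [0, 0.5]")

    def conditional(self, reading: str, vocab: CategoryVocabulary) -> np.ndarray:
        """Category distribution given a near or far reading."""
        cats = vocab.choice_categories
        index = {c: i for i, c in enumerate(cats)}
        base = np.zeros(len(cats))
        if self.base_dist is None:
            base[index[self.pair_near]] = 0.5
            base[index[self.pair_far]] = 0.5
        else:
            for c, p in self.base_dist.items():
                base[index[c]] = p
            if not np.isclose(base.sum(), 1.0):
                raise DesignError(f"base_dist must sum to 1, got {base.sum()}")
        point = np.zeros(len(cats))
        point[index[self.pair_near if reading == "near" else self.pair_far]] = 1.0
        return (1.0 - self.lam) * base + self.lam * point


@dataclass(frozen=True)
class SyntheticDesign:
    """Full generative design: participants, images, seed.

    Defaults mirror the study design: 24 participants in the unbiased
    experiment, 12 per group in the manipulated ones, 87 images, 26
    categories.
    """

    images: tuple[ImageSpec, ...]
    n_participants: int = 24
    n_per_group: int = 12
    seed: int = 0
    vocabulary: CategoryVocabulary = field(default_factory=default_vocabulary)

    def image_meta(self) -> list[ImageMeta]:
        return [ImageMeta(s.image_id, s.ground_truth) for s in self.images]


def default_design(
    n_images: int = 87,
    lam: float | Sequence[float] = 0.0,
    n_participants: int = 24,
    n_per_group: int = 12,
    seed: int = 0,
    p_near: float = 0.5,
    manipulation_delta: float = 0.4,
    vocabulary: CategoryVocabulary | None = None,
) -> SyntheticDesign:
    """A design with confusable pairs cycled through the vocabulary.

    ``lam`` may be a scalar (all images) or one value per image.
    """
    vocab = vocabulary or default_vocabulary()
    cats = vocab.choice_categories
    lams = np.broadcast_to(np.asarray(lam, dtype=float), (n_images,))
    images = []
    for i in range(n_images):
        a = cats[(2 * i) % len(cats)]
        b = cats[(2 * i + 1) % len(cats)]
        images.append(ImageSpec(
            image_id=f"img{i:03d}",
            ground_truth=a,
            pair_near=a,
            pair_far=b,
            lam=float(lams[i]),
            p_near=p_near,
            manipulation_delta=manipulation_delta,
        ))
    return SyntheticDesign(
        images=tuple(images), n_participants=n_participants,
        n_per_group=n_per_group, seed=seed, vocabulary=vocab,
    )


def _draw_confidence(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(np.round(rng.normal(mean, sd)), 1, 7))


def _draw_free_text(rng: np.random.Generator, category: str) -> str:
    if rng.random() < 0.3:
        return f"{rng.choice(_MODIFIERS)} {category}"
    return category


def _draw_distance(rng: np.random.Generator, spec: ImageSpec, reading: str):
    if reading == "near":
        unit = _NEAR_UNITS[rng.choice(3, p=np.asarray(spec.near_unit_probs))]
    else:
        unit = _FAR_UNITS[rng.choice(2, p=np.asarray(spec.far_unit_probs))]
    # log-uniform metric value in 1-99 of the chosen unit (descriptive only)
    value = float(np.round(np.exp(rng.uniform(np.log(1.0), np.log(99.0))), 1))
    return unit, value


def simulate_exp1(design: SyntheticDesign) -> tuple[list[ResponseRecord], pd.DataFrame]:
    """Simulate the unbiased experiment.

    Returns the trial records (free, choice and distance blocks) and a
    ground-truth ledger with each trial's latent reading and the image's
    asymmetry parameter.
    """
    rng = np.random.default_rng(design.seed)
    vocab = design.vocabulary
    cats = vocab.choice_categories
    records: list[ResponseRecord] = []
    ledger_rows = []
    for p in range(design.n_participants):
        pid = f"p{p + 1:02d}"
        for spec in design.images:
            reading = "near" if rng.random() < spec.p_near else "far"
            probs = spec.conditional(reading, vocab)
            category = cats[rng.choice(len(cats), p=probs)]
            confidence = _draw_confidence(rng, spec.confidence_mean, spec.confidence_sd)
            unit, value = _draw_distance(rng, spec, reading)
            common = dict(
                participant_id=pid, experiment=Experiment.EXP1,
                group=Group.UNBIASED, image_id=spec.image_id,
            )
            records.append(ResponseRecord(
                **common, block=Block.FREE,
                raw_text=_draw_free_text(rng, category),
            ))
            records.append(ResponseRecord(
                **common, block=Block.CHOICE, category=category,
                confidence=confidence,
            ))
            records.append(ResponseRecord(
                **common, block=Block.DISTANCE,
                distance_unit=unit, distance_value=value,
            ))
            ledger_rows.append({
                "participant_id": pid, "image_id": spec.image_id,
                "lam": spec.lam, "reading": reading, "category": category,
            })
    return records, pd.DataFrame(ledger_rows)


def simulate_exp2(
    design: SyntheticDesign,
    modality: Literal["instructions", "objects"] = "instructions",
    object_attenuation: float = 0.5,
) -> tuple[list[ResponseRecord], pd.DataFrame]:
    """Simulate a manipulated experiment (instructions or familiar objects).

    The near-manipulated group's reading probability is ``p_near + delta``,
    the far-manipulated group's ``p_near - delta`` (clipped to [0, 1]); the
    objects modality attenuates delta by ``object_attenuation`` and lowers
    mean confidence, emulating a weaker, less trusted cue.  No distance block.
    """
    if modality == "instructions":
        experiment = Experiment.EXP2A
        groups = (Group.INSTRUCT_NEAR, Group.INSTRUCT_FAR)
        atten, conf_shift = 1.0, 0.0
    elif modality == "objects":
        experiment = Experiment.EXP2B
        groups = (Group.OBJECT_SMALL, Group.OBJECT_LARGE)
        atten, conf_shift = object_attenuation, -0.2
    else:
        raise DesignError(f"unknown modality: {modality!r}")

    rng = np.random.default_rng(design.seed + (1 if modality == "instructions" else 2))
    vocab = design.vocabulary
    cats = vocab.choice_categories
    records: list[ResponseRecord] = []
    ledger_rows = []
    for g, group in enumerate(groups):
        sign = +1.0 if group in (Group.INSTRUCT_NEAR, Group.OBJECT_SMALL) else -1.0
        for p in range(design.n_per_group):
            pid = f"{modality[:3]}_{group.value}_{p + 1:02d}"
            for spec in design.images:
                p_near = float(np.clip(
                    spec.p_near + sign * atten * spec.manipulation_delta, 0.0, 1.0
                ))
                reading = "near" if rng.random() < p_near else "far"
                probs = spec.conditional(reading, vocab)
                category = cats[rng.choice(len(cats), p=probs)]
                confidence = _draw_confidence(
                    rng, spec.confidence_mean + conf_shift, spec.confidence_sd
                )
                common = dict(
                    participant_id=pid, experiment=experiment, group=group,
                    image_id=spec.image_id,
                )
                records.append(ResponseRecord(
                    **common, block=Block.FREE,
                    raw_text=_draw_free_text(rng, category),
                ))
                records.append(ResponseRecord(
                    **common, block=Block.CHOICE, category=category,
                    confidence=confidence,
                ))
                ledger_rows.append({
                    "participant_id": pid, "group": group.value,
                    "image_id": spec.image_id, "lam": spec.lam,
                    "reading": reading, "category": category,
                })
    return records, pd.DataFrame(ledger_rows)


def attribute_table(
    design: SyntheticDesign,
    seed: int | None = None,
    slant_effect: float = 0.0,
) -> list[ImageMeta]:
    """Synthetic per-image appearance ratings and self-similarity values.

    Ratings (blue tint, blurriness, direct lighting, gloss, slant) are drawn
    on a 0-10 scale; ``slant_effect`` shifts the slant rating upward for
    images whose design favors a far reading (p_near < 0.5), emulating the
    association between slanted surfaces and large apparent distances.
    Stands in for pilot-experiment ratings, which are consumed as
    precomputed numbers.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    images = []
    for spec in design.images:
        ratings = {
            "blue_tint": float(rng.uniform(0, 10)),
            "blurriness": float(rng.uniform(0, 10)),
            "direct_lighting": float(rng.uniform(0, 10)),
            "gloss": float(rng.uniform(0, 10)),
            "slant": float(np.clip(
                rng.uniform(0, 10) + slant_effect * (0.5 - spec.p_near) * 2, 0, 10)),
        }
        images.append(ImageMeta(
            image_id=spec.image_id,
            ground_truth_category=spec.ground_truth,
            attribute_ratings=ratings,
            self_similarity=float(rng.uniform(0, 1)),
        ))
    return images
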