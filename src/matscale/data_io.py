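"""Domain types, CSV schema, validation, and unit handling for trial-level data.

The data model mirrors a three-block psychophysics session: participants
describe a surface material in free text, pick one of 26 material categories
(with a 1-7 confidence rating), and — in the unbiased experiment only —
estimate the camera-to-surface distance by choosing a measurement unit and a
metric value.  One CSV row is one trial.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DistanceUnit",
    "Experiment",
    "Group",
    "Block",
    "ResponseRecord",
    "CategoryVocabulary",
    "ImageMeta",
    "SchemaError",
    "ValidationError",
    "default_vocabulary",
    "read_responses",
    "write_responses",
    "read_images",
    "write_images",
    "to_centimeters",
    "RESPONSE_COLUMNS",
]


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a record invariant; the message names the row."""


class DistanceUnit(enum.Enum):
    """The five measurement units offered for distance estimates.

    ``ordinal_rank`` orders the units by physical size; inferential analyses of
    distance operate on this ordinal scale because magnitudes converted to a
    common unit span many orders of magnitude and are extremely skewed.
    ``cm_factor`` converts a value in this unit to centimeters, for
    descriptive summaries only.
    """

    MICROMETER = ("micrometer", 1, 1e-4)
    MILLIMETER = ("millimeter", 2, 1e-1)
    CENTIMETER = ("centimeter", 3, 1.0)
    METER = ("meter", 4, 1e2)
    KILOMETER = ("kilometer", 5, 1e5)

    def __init__(self, label: str, ordinal_rank: int, cm_factor: float):
        self.label = label
        self.ordinal_rank = ordinal_rank
        self.cm_factor = cm_factor

    @classmethod
    def from_label(cls, label: str) -> "DistanceUnit":
        label = label.strip().lower()
        for member in cls:
            if member.label == label:
                return member
        raise ValidationError(f"unknown distance unit: {label!r}")


class Experiment(enum.Enum):
    EXP1 = "1"
    EXP2A = "2A"
    EXP2B = "2B"


class Group(enum.Enum):
    UNBIASED = "unbiased"
    INSTRUCT_NEAR = "instruct_near"
    INSTRUCT_FAR = "instruct_far"
    OBJECT_SMALL = "object_small"
    OBJECT_LARGE = "object_large"


class Block(enum.Enum):
    FREE = "free"
    CHOICE = "choice"
    DISTANCE = "distance"


#: groups legal for each experiment
_EXPERIMENT_GROUPS = {
    Experiment.EXP1: {Group.UNBIASED},
    Experiment.EXP2A: {Group.INSTRUCT_NEAR, Group.INSTRUCT_FAR},
    Experiment.EXP2B: {Group.OBJECT_SMALL, Group.OBJECT_LARGE},
}


# The 26 multiple-choice material categories.  The categories named in running
# descriptions of the stimulus set (bark, stone, water, plastic, sand, metal,
# wood, plant, carpet, ice, marble, leather, concrete, hair, corduroy) are
# completed with standard material-perception categories; the list is disjoint
# from the extended free-response descriptor list below.  Any analysis accepts
# an alternative vocabulary, e.g. the exact deposited list for a reanalysis.
DEFAULT_CHOICE_CATEGORIES: tuple[str, ...] = (
    "bark", "carpet", "ceramic", "clay", "concrete", "corduroy", "fabric",
    "feathers", "fur", "glass", "hair", "ice", "leather", "marble", "metal",
    "paper", "plant", "plastic", "sand", "skin", "snow", "stone", "water",
    "wax", "wicker", "wood",
)

# Single-word descriptors admitted when reducing free-text answers, beyond the
# choice categories themselves.  "none" is the sink for non-material answers.
DEFAULT_EXTENDED_TERMS: tuple[str, ...] = (
    "aluminum", "asphalt", "basalt", "bast", "bone", "brick", "bronze",
    "cake", "canvas", "cardboard", "cellulose", "cement", "chalk",
    "chalk stone", "chocolate", "cloud", "coal", "copper", "coral", "cord",
    "cork", "cotton", "cotton candy", "crystal", "denim", "detergent",
    "dirt", "dough", "dust", "screed", "felt", "fleece", "flour", "foam",
    "foil", "fungus", "gel", "gem", "glue", "gold", "granite", "graphite",
    "grass", "hay", "honeycomb", "iron", "jade", "jelly", "jute",
    "laminate", "lead", "lime", "limestone", "linen", "meat", "mirror",
    "moss", "mold", "mud", "none", "nylon", "oil", "pearl", "peat",
    "photopaper", "plaster", "plexiglass", "powder", "pumice", "putty",
    "pvc", "quartz", "resin", "rock", "root", "rubber", "rust", "salt",
    "sandpaper", "silicone", "silk", "silver", "slate", "slime", "slom",
    "smoke", "soap", "soil", "sponge", "steel", "straw", "styrofoam",
    "sugar", "sulfur", "talcum", "tar", "velvet", "vinyl", "wheat", "wool",
)


@dataclass(frozen=True)
class CategoryVocabulary:
    """The multiple-choice category list plus the extended free-text terms."""

    choice_categories: tuple[str, ...] = DEFAULT_CHOICE_CATEGORIES
    extended_terms: tuple[str, ...] = DEFAULT_EXTENDED_TERMS

    def __post_init__(self):
        if len(self.choice_categories) != 26:
            raise ValueError(
                f"choice_categories must have exactly 26 entries, "
                f"got {len(self.choice_categories)}"
            )
        union = list(self.choice_categories) + list(self.extended_terms)
        if len(set(union)) != len(union):
            raise ValueError("duplicate labels across vocabulary lists")

    @property
    def allowed_terms(self) -> frozenset[str]:
        """Union vocabulary for normalized free-text terms (includes 'none')."""
        return frozenset(self.choice_categories) | frozenset(self.extended_terms) | {"none"}

    def canonical(self, label: str) -> str:
        """Trim + lower-case a choice category; raise if unknown."""
        c = label.strip().lower()
        if c not in self.choice_categories:
            raise ValidationError(f"unknown category: {label!r}")
        return c


def default_vocabulary() -> CategoryVocabulary:
    return CategoryVocabulary()


@dataclass(frozen=True)
class ResponseRecord:
    """One trial's answer.

    Exactly one of ``raw_text`` / ``category`` / (``distance_unit``,
    ``distance_value``) is populated depending on ``block``; confidence
    accompanies the choice block.
    """

    participant_id: str
    experiment: Experiment
    group: Group
    image_id: str
    block: Block
    raw_text: str = ""
    category: str = ""
    confidence: int | None = None
    distance_unit: DistanceUnit | None = None
    distance_value: float | None = None

    def validate(self, vocab: CategoryVocabulary) -> None:
        if self.group not in _EXPERIMENT_GROUPS[self.experiment]:
            raise ValidationError(
                f"group {self.group.value!r} invalid for experiment "
                f"{self.experiment.value}"
            )
        if self.block is Block.CHOICE:
            if not self.category:
                raise ValidationError("choice block requires a category")
            if self.category not in vocab.choice_categories:
                raise ValidationError(f"unknown category: {self.category!r}")
        elif self.block is Block.FREE:
            if not self.raw_text:
                raise ValidationError("free block requires raw_text")
        elif self.block is Block.DISTANCE:
            if self.distance_unit is None or self.distance_value is None:
                raise ValidationError("distance block requires unit and value")
        if self.experiment is not Experiment.EXP1 and (
            self.distance_unit is not None or self.distance_value is not None
        ):
            raise ValidationError(
                "distance fields must be empty outside Experiment 1"
            )
        if self.confidence is not None and not 1 <= self.confidence <= 7:
            raise ValidationError(f"confidence {self.confidence} outside 1-7")
        if self.distance_value is not None and self.distance_value <= 0:
            raise ValidationError("distance_value must be positive")


@dataclass(frozen=True)
class ImageMeta:
    """Per-image metadata: publisher ground truth plus optional features."""

    image_id: str
    ground_truth_category: str
    attribute_ratings: Mapping[str, float] = field(default_factory=dict)
    self_similarity: float | None = None


ATTRIBUTE_NAMES = ("blue_tint", "blurriness", "direct_lighting", "gloss", "slant")

RESPONSE_COLUMNS = (
    "participant_id", "experiment", "group", "image_id", "block",
    "raw_text", "category", "confidence", "distance_unit", "distance_value",
)


def _parse_row(row: Mapping[str, str], vocab: CategoryVocabulary) -> ResponseRecord:
    def get(col: str) -> str:
        v = row.get(col, "")
        return "" if v is None else str(v).strip()

    try:
        experiment = Experiment(get("experiment"))
    except ValueError:
        raise ValidationError(f"unknown experiment: {get('experiment')!r}")
    try:
        group = Group(get("group").lower())
    except ValueError:
        raise ValidationError(f"unknown group: {get('group')!r}")
    try:
        block = Block(get("block").lower())
    except ValueError:
        raise ValidationError(f"unknown block: {get('block')!r}")

    category = get("category").lower()
    if category and category not in vocab.choice_categories:
        raise ValidationError(f"unknown category: {category!r}")

    confidence: int | None = None
    if get("confidence"):
        try:
            confidence = int(float(get("confidence")))
        except ValueError:
            raise ValidationError(f"confidence not an integer: {get('confidence')!r}")

    unit: DistanceUnit | None = None
    if get("distance_unit"):
        unit = DistanceUnit.from_label(get("distance_unit"))

    value: float | None = None
    if get("distance_value"):
        try:
            value = float(get("distance_value"))
        except ValueError:
            raise ValidationError(
                f"distance_value not numeric: {get('distance_value')!r}"
            )

    rec = ResponseRecord(
        participant_id=get("participant_id"),
        experiment=experiment,
        group=group,
        image_id=get("image_id"),
        block=block,
        raw_text=get("raw_text"),
        category=category,
        confidence=confidence,
        distance_unit=unit,
        distance_value=value,
    )
    rec.validate(vocab)
    return rec


def read_responses(
    path: str | Path,
    vocab: CategoryVocabulary | None = None,
    *,
    strict: bool = True,
) -> list[ResponseRecord]:
    """Read and validate a trial-level responses CSV.

    Row order is preserved.  With ``strict`` (default) the first invalid row
    raises :class:`ValidationError` naming its line; otherwise invalid rows
    are dropped and reported on the returned list's ``.rejected`` attribute
    as ``(line_number, message)`` pairs.
    """
    vocab = vocab or default_vocabulary()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    records: list[ResponseRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            records.append(_parse_row(row, vocab))
        except ValidationError as exc:
            if strict:
                raise ValidationError(f"line {line}: {exc}") from None
            rejected.append((line, str(exc)))

    class _RecordList(list):
        pass

    out = _RecordList(records)
    out.rejected = rejected
    return out


def responses_to_frame(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Flatten records to the canonical CSV column layout."""
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "experiment": r.experiment.value,
            "group": r.group.value,
            "image_id": r.image_id,
            "block": r.block.value,
            "raw_text": r.raw_text,
            "category": r.category,
            "confidence": "" if r.confidence is None else str(r.confidence),
            "distance_unit": "" if r.distance_unit is None else r.distance_unit.label,
            "distance_value": "" if r.distance_value is None else _fmt_number(r.distance_value),
        })
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_responses(records: Iterable[ResponseRecord], path: str | Path) -> None:
    responses_to_frame(records).to_csv(path, index=False)


def read_images(path: str | Path, vocab: CategoryVocabulary | None = None) -> list[ImageMeta]:
    """Read images.csv: image_id, ground_truth, optional attribute columns."""
    vocab = vocab or default_vocabulary()
    df = pd.read_csv(path, dtype={"image_id": str})
    for col in ("image_id", "ground_truth"):
        if col not in df.columns:
            raise SchemaError(f"missing column(s): {col}")
    images = []
    for i, row in df.iterrows():
        gt = str(row["ground_truth"]).strip().lower()
        if gt not in vocab.choice_categories:
            raise ValidationError(f"line {i + 2}: unknown ground truth {gt!r}")
        ratings = {
            a: float(row[a]) for a in ATTRIBUTE_NAMES
            if a in df.columns and pd.notna(row[a])
        }
        ss = None
        if "self_similarity" in df.columns and pd.notna(row["self_similarity"]):
            ss = float(row["self_similarity"])
        images.append(ImageMeta(str(row["image_id"]), gt, ratings, ss))
    return images


def write_images(images: Iterable[ImageMeta], path: str | Path) -> None:
    rows = []
    for im in images:
        row = {"image_id": im.image_id, "ground_truth": im.ground_truth_category}
        for a in ATTRIBUTE_NAMES:
            row[a] = im.attribute_ratings.get(a, "")
        row["self_similarity"] = "" if im.self_similarity is None else im.self_similarity
        rows.append(row)
    cols = ["image_id", "ground_truth", *ATTRIBUTE_NAMES, "self_similarity"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def to_centimeters(value: float, unit: DistanceUnit) -> float:
    """Convert a distance estimate to centimeters (descriptive use only).

    Inferential distance analyses stay on the ordinal unit scale: converted
    magnitudes are extremely skewed and span several orders of magnitude.
    """
    if value <= 0:
        raise ValueError(f"distance value must be positive, got {value}")
    return value * unit.cm_factor
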