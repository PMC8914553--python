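"""Reduce free-text material descriptions to single-term labels.

Free-text answers ("scratched stone", "desert sand", "frozen water") are
reduced to single material terms by a deterministic rule chain — typo
correction, translation, compound reduction to the head noun, synonym
resolution, vocabulary check — driven by an editable lexicon shipped as
package data.  Non-material or unresolvable answers map to the sink term
``"none"``.  Term frequencies from the free block can then be compared, by
rank correlation, with the multiple-choice category frequencies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from scipy import stats

from .data_io import Block, CategoryVocabulary, ResponseRecord, default_vocabulary

__all__ = [
    "NormalizationLexicon",
    "load_lexicon",
    "normalize_description",
    "term_frequencies",
    "task_agreement",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationLexicon:
    """String maps applied, in order, when reducing a free-text description."""

    typo_map: Mapping[str, str] = field(default_factory=dict)
    translation_map: Mapping[str, str] = field(default_factory=dict)
    compound_map: Mapping[str, str] = field(default_factory=dict)
    synonym_map: Mapping[str, str] = field(default_factory=dict)
    none_terms: frozenset[str] = frozenset()
    vocabulary: CategoryVocabulary = field(default_factory=default_vocabulary)

    @property
    def allowed_terms(self) -> frozenset[str]:
        return self.vocabulary.allowed_terms


def load_lexicon(
    path: str | Path | None = None,
    vocabulary: CategoryVocabulary | None = None,
) -> NormalizationLexicon:
    """Load the packaged lexicon, or an override file of the same layout."""
    if path is None:
        text = resources.files("matscale.data").joinpath("lexicon.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return NormalizationLexicon(
        typo_map=dict(raw.get("typo_map", {})),
        translation_map=dict(raw.get("translation_map", {})),
        compound_map=dict(raw.get("compound_map", {})),
        synonym_map=dict(raw.get("synonym_map", {})),
        none_terms=frozenset(raw.get("none_terms", [])),
        vocabulary=vocabulary or default_vocabulary(),
    )


def normalize_description(text: str, lexicon: NormalizationLexicon) -> str:
    """Reduce a free-text material description to a single allowed term.

    Total function: anything unresolved or non-material returns ``"none"``.
    """
    if not text or not text.strip():
        raise ValueError("text must be non-empty")
    s = " ".join(text.strip().lower().split())

    s = lexicon.typo_map.get(s, s)
    s = lexicon.translation_map.get(s, s)
    if s in lexicon.none_terms:
        return "none"

    # compound reduction: explicit head map, else last token — unless the
    # whole phrase is a synonym key (phrase-level synonyms take precedence)
    if " " in s and s not in lexicon.synonym_map and s not in lexicon.allowed_terms:
        if s in lexicon.compound_map:
            s = lexicon.compound_map[s]
        else:
            s = s.split()[-1]
        s = lexicon.typo_map.get(s, s)
        s = lexicon.translation_map.get(s, s)

    s = lexicon.synonym_map.get(s, s)
    if s in lexicon.none_terms:
        return "none"
    return s if s in lexicon.allowed_terms else "none"


def term_frequencies(
    records: Iterable[ResponseRecord],
    block: Block,
    lexicon: NormalizationLexicon | None = None,
) -> dict[str, int]:
    """Count normalized free-text terms or chosen categories.

    Counts sum to the number of responses in the requested block.
    """
    if block not in (Block.FREE, Block.CHOICE):
        raise ValueError("block must be free or choice")
    lexicon = lexicon or load_lexicon()
    counts: Counter[str] = Counter()
    for r in records:
        if r.block is not block:
            continue
        if block is Block.CHOICE:
            counts[r.category] += 1
        else:
            counts[normalize_description(r.raw_text, lexicon)] += 1
    return dict(counts)


def task_agreement(
    freq_free: Mapping[str, int],
    freq_choice: Mapping[str, int],
) -> tuple[float, float]:
    """Spearman rank correlation of term frequencies common to both tasks.

    Common terms are the intersection of the two maps' keys, excluding the
    ``"none"`` sink.  Returns ``(rho, p_value)`` with midrank ties.
    """
    common = sorted((set(freq_free) & set(freq_choice)) - {"none"})
    if len(common) < 3:
        raise InsufficientDataError(
            f"need at least 3 common terms, got {len(common)}"
        )
    x = [freq_free[t] for t in common]
    y = [freq_choice[t] for t in common]
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
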