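"""Stage 3 entity-name refinement.

Recognizers often tag whole noun phrases ("Dnak suppressor protein") as
one entity.  Relations can only be grouped across papers when both
endpoints are bare gene/protein names, so each phrase is reduced through
a pipeline: stoplist removal of frequent non-entity words (cheap, first),
word-level NER over the survivors, and — when the recognizer finds
nothing — a spelling heuristic: a word absent from a common-English
lexicon, or containing digits or internal capitals, is taken to be a
gene/protein name.  A phrase with no surviving word marks the relation
incomplete, and the relation is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .corpus_io import read_word_list
from .ner import DictionaryNer, GeneLexicon, NerProvider, annotate_word
from .types import RelationInstance, normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementConfig",
    "default_stoplist",
    "default_english_lexicon",
    "is_gene_like_word",
    "refine_entity_name",
    "refine_relations",
]


def _data_words(filename: str) -> frozenset[str]:
    ref = resources.files("gix.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return frozenset(read_word_list(path))


def default_stoplist() -> frozenset[str]:
    """Bundled list of frequent non-entity words (config-replaceable)."""
    return _data_words("stoplist.txt")


def default_english_lexicon() -> frozenset[str]:
    """Bundled common-English word list for the spelling heuristic."""
    return _data_words("english_words.txt")


@dataclass(frozen=True)
class RefinementConfig:
    """Stoplist, English lexicon and word-level NER provider.

    Both word sets are case-folded on construction; they need not be
    disjoint (a stoplist word may well be ordinary English).
    """

    stoplist: frozenset[str]
    english_lexicon: frozenset[str]
    provider: NerProvider

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoplist", frozenset(w.casefold() for w in self.stoplist))
        object.__setattr__(
            self, "english_lexicon", frozenset(w.casefold() for w in self.english_lexicon)
        )

    @classmethod
    def default(cls, provider: Optional[NerProvider] = None) -> "RefinementConfig":
        if provider is None:
            provider = DictionaryNer(GeneLexicon(entries=()))
        return cls(
            stoplist=default_stoplist(),
            english_lexicon=default_english_lexicon(),
            provider=provider,
        )


def is_gene_like_word(word: str, lexicon: frozenset[str]) -> bool:
    """Heuristic: is this single word plausibly a gene/protein name?

    Gene names are made of letters, digits and symbols that rarely form
    dictionary words, so a word whose case-folded form is missing from
    the common-English lexicon is treated as a name ("misspelled" implies
    gene-like).  Words containing digits or capitals beyond the first
    character are names regardless — spell lexicons routinely contain
    short gene symbols' lowercase homographs.
    """
    if not word or any(ch.isspace() for ch in word):
        raise ValueError("word must be non-empty and contain no whitespace")
    if any(ch.isdigit() for ch in word):
        return True
    if any(ch.isupper() for ch in word[1:]):
        return True
    return word.casefold() not in lexicon


def refine_entity_name(phrase: str, config: RefinementConfig) -> Optional[str]:
    """Reduce an entity phrase to a bare gene/protein name, if any.

    Pipeline: (1) a single-word phrase is already bare and returned
    as-is; (2) stoplist words are removed; (3) the remaining words go
    through word-level NER, collecting recognized names; (4) if none is
    recognized, the spelling heuristic runs over the remaining words;
    (5) the first surviving word in original order is returned, or
    ``None`` when nothing survives — the relation is then incomplete.
    """
    words = phrase.split()
    if not words:
        return None
    if len(words) == 1:
        return words[0]
    remaining = [w for w in words if w.casefold().strip(".,;:()") not in config.stoplist]
    if not remaining:
        return None
    recognized = []
    for w in remaining:
        mention = annotate_word(w.strip(".,;:()"), config.provider)
        if mention is not None:
            recognized.append((w, mention.normalized_id))
    if recognized:
        if len(recognized) > 1:
            logger.warning(
                "phrase %r contains %d recognized entities; keeping the first",
                phrase, len(recognized),
            )
        return recognized[0][1] or recognized[0][0]
    survivors = [
        w for w in remaining if is_gene_like_word(w.strip(".,;:()") or w, config.english_lexicon)
    ]
    if len(survivors) > 1:
        logger.warning(
            "phrase %r has %d gene-like words; keeping the first", phrase, len(survivors)
        )
    return survivors[0].strip(".,;:()") if survivors else None


def refine_relations(
    positives: Sequence[RelationInstance], config: RefinementConfig
) -> list[RelationInstance]:
    """Refine both endpoints of every relation; drop incomplete ones.

    Instances whose agent or target refines to nothing are dropped with a
    logged reason.  Duplicates arising after refinement (same sentence,
    same refined endpoints) are merged, averaging their scores.  The
    operation is idempotent: already-bare names pass through unchanged.
    """
    merged: dict[tuple[str, str, str], list[RelationInstance]] = {}
    order: list[tuple[str, str, str]] = []
    for inst in positives:
        agent = refine_entity_name(inst.agent, config)
        target = refine_entity_name(inst.target, config)
        if agent is None or target is None:
            logger.info(
                "dropping incomplete relation %s (%r -> %r)",
                inst.instance_id, inst.agent, inst.target,
            )
            continue
        agent, target = normalize_name(agent), normalize_name(target)
        if agent == target:
            logger.info(
                "dropping relation %s: endpoints refine to the same name %r",
                inst.instance_id, agent,
            )
            continue
        key = (inst.sentence_id, agent, target)
        if key not in merged:
            merged[key] = []
            order.append(key)
        merged[key].append(inst.with_endpoints(agent, target))
    out = []
    for key in order:
        group = merged[key]
        first = group[0]
        if len(group) == 1:
            out.append(first)
            continue
        scores = [g.score for g in group if g.score is not None]
        mean = sum(scores) / len(scores) if scores else None
        out.append(first.with_score(mean))
    return out
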