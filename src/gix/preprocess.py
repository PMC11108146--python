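"""Stage 1: query building, organism filtering and sentence elimination.

The stage narrows a set of retrieved abstracts down to sentences that are
worth running through the relation classifier:

1. keep abstracts mentioning the target organism (full binomial or
   abbreviated genus forms, case-insensitive substring over title and
   abstract);
2. split abstracts into sentences (rule-based, abbreviation-aware);
3. sentence eliminator 1 drops sentences a relevance scorer deems
   non-regulatory;
4. sentence eliminator 2 drops sentences with fewer than two distinct
   gene/protein entities — a directed pair needs at least two.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

from .ner import NerProvider
from .types import AbstractRecord, SentenceRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "QuerySpec",
    "RelevanceScorer",
    "TriggerRelevanceScorer",
    "TRIGGER_STEMS",
    "organism_name_forms",
    "build_query",
    "filter_abstracts_by_organism",
    "split_sentences",
    "eliminate_nonregulatory",
    "eliminate_by_entity_count",
]

#: Default keyword phrase appended to the organism name forms in queries.
DEFAULT_KEYWORDS = "gene expression regulation transcriptional"

#: Verb stems signalling a regulatory interaction; shared by the rule
#: relevance scorer and the rule relation scorer so the stub pipeline is
#: internally consistent.
TRIGGER_STEMS = (
    "regulat",
    "repress",
    "activat",
    "induc",
    "bind",
    "express",
    "transcrib",
)

#: Tokens whose trailing period does not end a sentence.
_ABBREVIATIONS = {
    "cf",
    "e.g",
    "i.e",
    "sp",
    "spp",
    "al",  # "et al."
    "fig",
    "vs",
    "approx",
    "no",
    "st",
}


@dataclass(frozen=True)
class QuerySpec:
    """Search specification: organism, keyword phrase, document cap."""

    organism: str
    keywords: str = DEFAULT_KEYWORDS
    retmax: int = 1000
    expand_abbreviations: bool = False

    def __post_init__(self) -> None:
        if not self.organism.strip():
            raise ValidationError("organism is mandatory")
        if not self.keywords.strip():
            raise ValidationError("keywords must be non-empty")
        if self.retmax < 1:
            raise ValidationError("retmax must be >= 1")


class RelevanceScorer(Protocol):
    """Maps sentence text to a regulatory-relevance score in [0, 1]."""

    def score(self, text: str) -> float: ...


@dataclass(frozen=True)
class TriggerRelevanceScorer:
    """Rule scorer: 1.0 if any interaction trigger stem occurs, else 0.0.

    A deterministic stand-in for a fine-tuned sentence classifier; the
    trigger stems are configuration, not constants.
    """

    triggers: tuple[str, ...] = TRIGGER_STEMS

    def score(self, text: str) -> float:
        folded = text.casefold()
        return 1.0 if any(t in folded for t in self.triggers) else 0.0


def organism_name_forms(organism: str) -> set[str]:
    """Surface forms an abstract may use for the organism.

    A binomial ``"Genus species"`` yields the full form plus the dotted
    and undotted genus-initial abbreviations (``"G. species"``,
    ``"G species"``).  Single-word names return themselves.  Downstream
    matching is case-insensitive.
    """
    organism = organism.strip()
    words = organism.split()
    if len(words) < 2:
        return {organism}
    initial = words[0][0].upper()
    rest = " ".join(words[1:])
    return {organism, f"{initial}. {rest}", f"{initial} {rest}"}


def build_query(spec: QuerySpec) -> str:
    """Whitespace-join the organism name form(s) and the keyword phrase.

    With ``expand_abbreviations`` the undotted genus-initial form is
    prepended before the full name (search engines treat the dot as
    noise), e.g. ``"E coli Escherichia coli gene expression regulation
    transcriptional"``.
    """
    words = spec.organism.split()
    parts: list[str] = []
    if spec.expand_abbreviations and len(words) >= 2:
        parts.append(f"{words[0][0].upper()} {' '.join(words[1:])}")
    parts.append(spec.organism.strip())
    parts.append(spec.keywords.strip())
    return " ".join(parts)


def filter_abstracts_by_organism(
    records: Sequence[AbstractRecord], forms: set[str]
) -> list[AbstractRecord]:
    """Keep records whose title or abstract contains any organism form.

    Matching is case-insensitive substring: abbreviated forms legitimately
    end at punctuation, so whole-word matching would lose them.
    """
    if not forms:
        raise ValidationError("forms must be non-empty")
    folded = [f.casefold() for f in forms]
    kept = []
    for rec in records:
        haystack = f"{rec.title} {rec.abstract_text}".casefold()
        if any(f in haystack for f in folded):
            kept.append(rec)
    return kept


_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def _ends_with_abbreviation(prefix: str) -> bool:
    """True if the text before a candidate '.' ends in a known abbreviation
    or a single-letter genus initial (as in "B. subtilis")."""
    match = re.search(r"(\S+)$", prefix)
    if not match:
        return False
    token = match.group(1).rstrip(".").strip("([{\"'")
    if len(token) == 1 and token.isalpha() and token.isupper():
        return True
    return token.casefold() in _ABBREVIATIONS


def split_sentences(record: AbstractRecord) -> list[SentenceRecord]:
    """Split an abstract into sentences with deterministic pmid-derived ids.

    Rule-based: a run of ``.!?`` followed by whitespace (or end of text)
    ends a sentence unless the preceding token is a known abbreviation or
    a genus initial.  Joining the returned texts with single spaces
    reconstructs the abstract modulo inter-sentence whitespace.
    """
    text = record.abstract_text
    if not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        if _ends_with_abbreviation(text[start : match.start()]):
            continue
        chunk = text[start : match.end()].strip()
        if chunk:
            sentences.append(chunk)
        start = match.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [
        SentenceRecord(sentence_id=f"{record.pmid}:s{i}", pmid=record.pmid, text=s)
        for i, s in enumerate(sentences)
    ]


def eliminate_nonregulatory(
    sentences: Sequence[SentenceRecord],
    scorer: RelevanceScorer,
    cutoff: float = 0.5,
) -> tuple[list[SentenceRecord], list[SentenceRecord]]:
    """Sentence eliminator 1: drop sentences scored below ``cutoff``.

    Returns ``(kept, removed)``; the partition is exhaustive and disjoint.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError("cutoff must be in [0, 1]")
    kept, removed = [], []
    for sent in sentences:
        (kept if scorer.score(sent.text) >= cutoff else removed).append(sent)
    return kept, removed


def eliminate_by_entity_count(
    sentences: Sequence[SentenceRecord],
    provider: NerProvider,
) -> tuple[list[SentenceRecord], list[SentenceRecord]]:
    """Sentence eliminator 2: keep sentences with >= 2 distinct entities.

    The provider annotates each sentence; kept sentences carry their
    mentions.  Two mentions of the same normalized gene do not qualify —
    a directed pair needs two distinct entities.  A provider failure on a
    sentence removes it (fail closed) with a logged reason.
    """
    kept, removed = [], []
    for sent in sentences:
        try:
            mentions = tuple(provider.annotate(sent.text))
        except Exception as exc:
            logger.warning("NER failed on %s (%s); removing sentence", sent.sentence_id, exc)
            removed.append(sent)
            continue
        annotated = SentenceRecord(
            sentence_id=sent.sentence_id,
            pmid=sent.pmid,
            text=sent.text,
            mentions=mentions,
            gold_pairs=sent.gold_pairs,
        )
        distinct = {m.normalized_id for m in mentions if m.is_gene}
        (kept if len(distinct) >= 2 else removed).append(annotated)
    return kept, removed
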