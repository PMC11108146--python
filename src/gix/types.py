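"""Core domain types shared across the pipeline stages.

The pipeline moves through four representations: publication abstracts
(:class:`AbstractRecord`), sentences with standoff entity mentions
(:class:`SentenceRecord`), directed candidate pairs rendered with the
anonymization tags (:class:`RelationInstance`), and aggregated directed
relations with confidence factors (:class:`DirectedEdge`).  Prior curated
knowledge enters through :class:`PriorKnowledgeBase`.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AbstractRecord",
    "EntityMention",
    "SentenceRecord",
    "RelationInstance",
    "PriorDatabase",
    "PriorKnowledgeBase",
    "DirectedEdge",
    "ValidationError",
    "normalize_name",
]

GENE_TYPE = "gene/protein"

#: Anonymization tags.  These strings are part of the labelling schema
#: contract and must be reproduced bit-exactly.
AGENT_TAG = "$GENE_AGENT#"
TARGET_TAG = "$GENE_TARGET#"
BLANK_TAG = "BLANK"


class ValidationError(ValueError):
    """An object violates a domain invariant (bad span, missing entity...)."""


def normalize_name(name: str) -> str:
    """Normalize an entity name for cross-document grouping.

    Case-fold and strip surrounding punctuation/whitespace, so that
    ``"CRP"``, ``"crp"`` and ``"crp,"`` aggregate onto one node.
    """
    return name.strip().strip(string.punctuation + string.whitespace).casefold()


@dataclass(frozen=True)
class AbstractRecord:
    """One publication: identifier, title and abstract text.

    ``abstract_text`` may be empty; such records survive parsing but are
    dropped by the downstream sentence-splitting stage.
    """

    pmid: str
    title: str
    abstract_text: str

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValidationError("pmid must be non-empty")


@dataclass(frozen=True)
class EntityMention:
    """A standoff entity annotation: half-open 0-based character span."""

    start: int
    end: int
    surface: str
    entity_type: str = GENE_TYPE
    probability: float = 1.0
    normalized_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span ({self.start}, {self.end}): need 0 <= start < end"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"probability {self.probability} outside [0, 1]")

    @property
    def is_gene(self) -> bool:
        return self.entity_type == GENE_TYPE

    def validate_against(self, text: str) -> None:
        """Check the span lies inside ``text`` and the surface matches."""
        if self.end > len(text):
            raise ValidationError(
                f"span ({self.start}, {self.end}) outside text of length {len(text)}"
            )
        if text[self.start : self.end] != self.surface:
            raise ValidationError(
                f"surface {self.surface!r} != text slice "
                f"{text[self.start:self.end]!r} at ({self.start}, {self.end})"
            )


@dataclass
class SentenceRecord:
    """One sentence with its entity mentions and optional gold pairs.

    ``gold_pairs`` holds directed (agent, target) pairs of normalized ids;
    ``None`` means un-annotated (as opposed to annotated with no relation).
    """

    sentence_id: str
    pmid: str
    text: str
    mentions: tuple[EntityMention, ...] = ()
    gold_pairs: Optional[frozenset[tuple[str, str]]] = None

    def __post_init__(self) -> None:
        self.mentions = tuple(self.mentions)
        if self.gold_pairs is not None:
            self.gold_pairs = frozenset(tuple(p) for p in self.gold_pairs)

    def validate(self) -> None:
        if not self.sentence_id:
            raise ValidationError("sentence_id must be non-empty")
        prev_end = -1
        for m in sorted(self.mentions, key=lambda m: m.start):
            m.validate_against(self.text)
            if m.start < prev_end:
                raise ValidationError(
                    f"{self.sentence_id}: overlapping mentions at offset {m.start}"
                )
            prev_end = m.end
        if self.gold_pairs:
            known = {m.normalized_id for m in self.mentions}
            for agent, target in self.gold_pairs:
                if agent not in known or target not in known:
                    raise ValidationError(
                        f"{self.sentence_id}: gold pair ({agent}, {target}) names "
                        "an entity absent from the mentions"
                    )

    def gene_ids(self) -> list[str]:
        """Distinct gene/protein normalized ids, ordered by first mention."""
        seen: list[str] = []
        for m in sorted(self.mentions, key=lambda m: m.start):
            if m.is_gene and m.normalized_id not in seen:
                seen.append(m.normalized_id)
        return seen


@dataclass(frozen=True)
class RelationInstance:
    """One directed (agent, target) candidate in one sentence.

    ``labelled_text`` is the anonymized rendering: every agent mention is
    the agent tag, every target mention the target tag, and every other
    gene/protein mention is masked.  ``score`` is the relation classifier's
    prediction v_s in [0, 1]; ``label`` the optional gold binary label.
    """

    instance_id: str
    sentence_id: str
    agent: str
    target: str
    labelled_text: str
    score: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.agent == self.target:
            raise ValidationError("agent and target must differ")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")

    def with_score(self, score: Optional[float]) -> "RelationInstance":
        return replace(self, score=score)

    def with_endpoints(self, agent: str, target: str) -> "RelationInstance":
        return replace(self, agent=agent, target=target)


@dataclass(frozen=True)
class PriorDatabase:
    """One curated database: its known regulators and directed relations."""

    name: str
    regulators: frozenset[str] = frozenset()
    relations: frozenset[tuple[str, str]] = frozenset()


@dataclass(frozen=True)
class PriorKnowledgeBase:
    """M curated databases supplying the prior-knowledge component."""

    databases: tuple[PriorDatabase, ...] = ()

    def __post_init__(self) -> None:
        names = [db.name for db in self.databases]
        if len(names) != len(set(names)):
            raise ValidationError("database names must be unique")

    @property
    def M(self) -> int:
        return len(self.databases)


@dataclass
class DirectedEdge:
    """An aggregated directed relation agent -> target with its confidence.

    ``votes`` maps each unique supporting sentence text to the averaged
    classifier vote for that sentence; ``cf1`` is the sum of votes, ``cf2``
    the summed prior score over databases, and ``cf = cf1 + K * cf2``.
    """

    agent: str
    target: str
    votes: dict[str, float] = field(default_factory=dict)
    cf1: float = 0.0
    cf2: int = 0
    cf: float = 0.0
    support: tuple[tuple[str, str], ...] = ()  # (pmid, sentence_id)

    @property
    def n(self) -> int:
        """Number of unique supporting sentences."""
        return len(self.votes)

    @property
    def key(self) -> tuple[str, str]:
        return (self.agent, self.target)
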