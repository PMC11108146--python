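"""Readers and writers for on-disk artifacts.

Formats:

* Abstracts — JSON Lines, one object per line with keys ``pmid``, ``title``,
  ``abstract``.
* Sentence corpus — JSON Lines, one object per sentence with keys
  ``sentence_id``, ``pmid``, ``text``, ``mentions`` (array of
  ``{start, end, surface, type, prob, norm_id}``) and ``gold_pairs``
  (array of ``[agent, target]``, or ``null`` for un-annotated sentences).
* Prior knowledge — two TSV tables with a header row:
  ``regulators.tsv`` (db_name, regulator) and ``relations.tsv``
  (db_name, agent, target).
* Word lists (stoplists, lexicons) — plain text, one token per line,
  ``#`` starts a comment.

All readers are deterministic and order-preserving, and every
reader/writer pair round-trips valid data field-for-field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    AbstractRecord,
    EntityMention,
    PriorDatabase,
    PriorKnowledgeBase,
    SentenceRecord,
    ValidationError,
    normalize_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_abstracts",
    "write_abstracts",
    "read_standoff_corpus",
    "write_standoff_corpus",
    "read_prior_knowledge",
    "write_prior_knowledge",
    "read_word_list",
]


class ParseError(ValueError):
    """A malformed on-disk record; the message names the offending line."""


def _jsonl_objects(path: Path) -> Iterable[tuple[int, dict]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            if not isinstance(obj, dict):
                raise ParseError(f"{path}: line {lineno}: expected a JSON object")
            yield lineno, obj


def read_abstracts(path: str | Path) -> list[AbstractRecord]:
    """Read a JSON Lines abstract file.

    Duplicate pmids are collapsed keeping the first occurrence (retrieval
    services can return duplicates); a warning is logged for each collapse.
    """
    path = Path(path)
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    for lineno, obj in _jsonl_objects(path):
        try:
            rec = AbstractRecord(
                pmid=str(obj["pmid"]),
                title=str(obj.get("title", "")),
                abstract_text=str(obj.get("abstract", "")),
            )
        except (KeyError, ValidationError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        if rec.pmid in seen:
            logger.warning("duplicate pmid %s at line %d: keeping first", rec.pmid, lineno)
            continue
        seen.add(rec.pmid)
        records.append(rec)
    return records


def write_abstracts(records: Sequence[AbstractRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {"pmid": rec.pmid, "title": rec.title, "abstract": rec.abstract_text},
                    ensure_ascii=False,
                )
                + "\n"
            )


def _mention_to_obj(m: EntityMention) -> dict:
    return {
        "start": m.start,
        "end": m.end,
        "surface": m.surface,
        "type": m.entity_type,
        "prob": m.probability,
        "norm_id": m.normalized_id,
    }


def _mention_from_obj(obj: dict) -> EntityMention:
    return EntityMention(
        start=int(obj["start"]),
        end=int(obj["end"]),
        surface=str(obj["surface"]),
        entity_type=str(obj.get("type", "gene/protein")),
        probability=float(obj.get("prob", 1.0)),
        normalized_id=str(obj.get("norm_id", "")),
    )


def read_standoff_corpus(path: str | Path) -> list[SentenceRecord]:
    """Read a JSON Lines sentence corpus, validating every record.

    Invariant violations (span outside the text, gold pair naming an
    entity absent from the mentions, duplicate sentence ids) are rejected
    with an error naming the offending sentence.
    """
    path = Path(path)
    records: list[SentenceRecord] = []
    seen: set[str] = set()
    for lineno, obj in _jsonl_objects(path):
        try:
            gold = obj.get("gold_pairs")
            rec = SentenceRecord(
                sentence_id=str(obj["sentence_id"]),
                pmid=str(obj.get("pmid", "")),
                text=str(obj["text"]),
                mentions=tuple(_mention_from_obj(m) for m in obj.get("mentions", [])),
                gold_pairs=None
                if gold is None
                else frozenset((str(a), str(t)) for a, t in gold),
            )
            rec.validate()
        except (KeyError, ValidationError, TypeError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        if rec.sentence_id in seen:
            raise ParseError(
                f"{path}: line {lineno}: duplicate sentence_id {rec.sentence_id!r}"
            )
        seen.add(rec.sentence_id)
        records.append(rec)
    return records


def write_standoff_corpus(records: Sequence[SentenceRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "sentence_id": rec.sentence_id,
                "pmid": rec.pmid,
                "text": rec.text,
                "mentions": [_mention_to_obj(m) for m in rec.mentions],
                "gold_pairs": None
                if rec.gold_pairs is None
                else sorted([a, t] for a, t in rec.gold_pairs),
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_prior_knowledge(
    regulators_path: str | Path, relations_path: str | Path
) -> PriorKnowledgeBase:
    """Read regulator and relation tables into a :class:`PriorKnowledgeBase`.

    Entity names are normalized (case-fold, strip surrounding punctuation)
    so that lookups from the extraction side match curated spellings.
    Databases named in either table are represented; empty files give
    an empty knowledge base (M = 0).
    """
    regs = pd.read_csv(regulators_path, sep="\t", dtype=str, keep_default_na=False)
    rels = pd.read_csv(relations_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("db_name", "regulator"):
        if col not in regs.columns:
            raise ParseError(f"{regulators_path}: missing column {col!r}")
    for col in ("db_name", "agent", "target"):
        if col not in rels.columns:
            raise ParseError(f"{relations_path}: missing column {col!r}")

    regulators: dict[str, set[str]] = {}
    relations: dict[str, set[tuple[str, str]]] = {}
    for row in regs.itertuples(index=False):
        if not row.regulator:
            raise ValidationError(f"{regulators_path}: empty regulator for {row.db_name}")
        regulators.setdefault(row.db_name, set()).add(normalize_name(row.regulator))
    for row in rels.itertuples(index=False):
        if not row.agent or not row.target:
            raise ValidationError(
                f"{relations_path}: relation with empty agent or target in {row.db_name}"
            )
        relations.setdefault(row.db_name, set()).add(
            (normalize_name(row.agent), normalize_name(row.target))
        )

    names = sorted(set(regulators) | set(relations))
    return PriorKnowledgeBase(
        databases=tuple(
            PriorDatabase(
                name=name,
                regulators=frozenset(regulators.get(name, set())),
                relations=frozenset(relations.get(name, set())),
            )
            for name in names
        )
    )


def write_prior_knowledge(
    kb: PriorKnowledgeBase, regulators_path: str | Path, relations_path: str | Path
) -> None:
    with Path(regulators_path).open("w", encoding="utf-8") as fh:
        fh.write("db_name\tregulator\n")
        for db in kb.databases:
            for reg in sorted(db.regulators):
                fh.write(f"{db.name}\t{reg}\n")
    with Path(relations_path).open("w", encoding="utf-8") as fh:
        fh.write("db_name\tagent\ttarget\n")
        for db in kb.databases:
            for agent, target in sorted(db.relations):
                fh.write(f"{db.name}\t{agent}\t{target}\n")


def read_word_list(path: str | Path) -> set[str]:
    """Read a plain-text word list; one token per line, '#' comments."""
    words: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                words.add(token.casefold())
    return words
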