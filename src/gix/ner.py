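"""Named-entity providers.

The pipeline only needs two capabilities from a gene/protein recognizer:
annotate a whole sentence with standoff mentions, and decide whether a
single word is a gene/protein name (used by entity-name refinement).
:class:`DictionaryNer` is a deterministic lexicon-backed implementation
used throughout the test surface; :class:`ServiceNer` is an optional
adapter for an external RESTful recognizer and is never required.
"""

from __future__ import annotations

import json
import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, runtime_checkable

from .types import GENE_TYPE, EntityMention, ValidationError, normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "GeneLexicon",
    "NerProvider",
    "DictionaryNer",
    "ServiceNer",
    "NerServiceError",
    "stub_annotate",
    "annotate_word",
    "read_lexicon",
    "write_lexicon",
]


@dataclass(frozen=True)
class GeneLexicon:
    """Surface form -> normalized id dictionary for the stub recognizer.

    Matching is case-insensitive; overlaps resolve longest-match first,
    then leftmost.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for surface, _ in self.entries:
            if not surface:
                raise ValidationError("lexicon surface forms must be non-empty")

    @classmethod
    def from_pairs(cls, pairs) -> "GeneLexicon":
        return cls(entries=tuple((s, n) for s, n in pairs))

    @classmethod
    def from_names(cls, names) -> "GeneLexicon":
        """Lexicon where each name normalizes to its case-folded self."""
        return cls(entries=tuple((n, normalize_name(n)) for n in names))

    def casefolded(self) -> dict[str, str]:
        return {s.casefold(): n for s, n in self.entries}


@runtime_checkable
class NerProvider(Protocol):
    """Contract: sentence-level and word-level gene/protein recognition."""

    def annotate(self, text: str) -> list[EntityMention]: ...


def _is_boundary(text: str, i: int) -> bool:
    """True if position i is a token boundary (edge or non-alphanumeric)."""
    if i <= 0 or i >= len(text):
        return True
    return not text[i - 1].isalnum() or not text[i].isalnum()


def stub_annotate(text: str, lexicon: GeneLexicon) -> list[EntityMention]:
    """All non-overlapping longest lexicon matches, left to right.

    Case-insensitive, token-delimited substring matching.  Overlaps are
    resolved longest-match first and then leftmost, so a multi-word entry
    like ``"sigma factor SigK"`` shadows its embedded ``"SigK"``.
    Returned mentions are sorted by start offset, typed gene/protein with
    probability 1.0 (the stub acts as a gold oracle).
    """
    folded = text.casefold()
    candidates: list[tuple[int, int, str]] = []  # (start, end, norm_id)
    for surface, norm in lexicon.casefolded().items():
        start = 0
        while True:
            idx = folded.find(surface, start)
            if idx < 0:
                break
            end = idx + len(surface)
            if _is_boundary(text, idx) and _is_boundary(text, end):
                candidates.append((idx, end, norm))
            start = idx + 1
    # longest first, then leftmost; greedy non-overlapping selection
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    taken: list[tuple[int, int, str]] = []
    for start, end, norm in candidates:
        if all(end <= s or start >= e for s, e, _ in taken):
            taken.append((start, end, norm))
    taken.sort()
    return [
        EntityMention(
            start=s,
            end=e,
            surface=text[s:e],
            entity_type=GENE_TYPE,
            probability=1.0,
            normalized_id=n,
        )
        for s, e, n in taken
    ]


@dataclass(frozen=True)
class DictionaryNer:
    """Deterministic lexicon-backed provider satisfying :class:`NerProvider`."""

    lexicon: GeneLexicon

    def annotate(self, text: str) -> list[EntityMention]:
        return stub_annotate(text, self.lexicon)


def annotate_word(token: str, provider: NerProvider) -> Optional[EntityMention]:
    """Word-level recognition used by entity-name refinement.

    Returns a mention only when the provider recognizes the whole token
    as a gene/protein name; empty or whitespace-containing tokens and
    unrecognized words return ``None``.
    """
    if not token or any(ch.isspace() for ch in token):
        return None
    for mention in provider.annotate(token):
        if mention.is_gene and mention.start == 0 and mention.end == len(token):
            return mention
    return None


class NerServiceError(RuntimeError):
    """The external recognizer failed after the configured retries."""


@dataclass
class ServiceNer:
    """Adapter for an external RESTful gene/protein recognizer.

    Sends the sentence as JSON and maps the service's annotation list
    (entity phrase, entity type, probability score) onto
    :class:`EntityMention`.  Retries up to ``max_attempts`` times, then
    raises :class:`NerServiceError` so the caller can fail closed on the
    sentence.  Requires network access; never used by the test surface.
    """

    endpoint: str
    timeout: float = 10.0
    max_attempts: int = 3

    def annotate(self, text: str) -> list[EntityMention]:
        payload = json.dumps({"text": text}).encode("utf-8")
        last_exc: Exception | None = None
        for attempt in range(1, self.max_attempts + 1):
            try:
                req = urllib.request.Request(
                    self.endpoint, data=payload, headers={"Content-Type": "application/json"}
                )
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    body = json.loads(resp.read().decode("utf-8"))
                return self._parse(body, text)
            except Exception as exc:  # network errors, bad payloads
                last_exc = exc
                logger.warning("NER service attempt %d/%d failed: %s", attempt, self.max_attempts, exc)
        raise NerServiceError(f"NER service failed after {self.max_attempts} attempts: {last_exc}")

    @staticmethod
    def _parse(body: dict, text: str) -> list[EntityMention]:
        mentions = []
        for ann in body.get("annotations", []):
            start, end = int(ann["span"]["begin"]), int(ann["span"]["end"])
            mention = EntityMention(
                start=start,
                end=end,
                surface=text[start:end],
                entity_type=GENE_TYPE if ann.get("obj") in ("gene", "protein", GENE_TYPE) else str(ann.get("obj", "")),
                probability=float(ann.get("prob", 1.0)),
                normalized_id=normalize_name(ann.get("norm", text[start:end])),
            )
            mention.validate_against(text)
            mentions.append(mention)
        mentions.sort(key=lambda m: m.start)
        return mentions


def read_lexicon(path: str | Path) -> GeneLexicon:
    """Read a TSV lexicon (surface <TAB> norm_id; norm defaults to surface)."""
    pairs: list[tuple[str, str]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            surface = parts[0].strip()
            norm = parts[1].strip() if len(parts) > 1 and parts[1].strip() else normalize_name(surface)
            pairs.append((surface, norm))
    return GeneLexicon.from_pairs(pairs)


def write_lexicon(lexicon: GeneLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for surface, norm in lexicon.entries:
            fh.write(f"{surface}\t{norm}\n")
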