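"""Hermetic synthetic corpora for exercising every pipeline stage.

The generator plants a known directed gene network and writes abstracts
whose sentences instantiate templates with interaction trigger verbs, so
the rule-based scorers can recover the planted relations without any
external model or download.  Each noise knob maps onto one pipeline
stage:

* ``p_irrelevant_sentence`` — trigger-free sentences for eliminator 1;
* ``p_decoy_entity`` — third-party gene mentions exercising the masking
  schema and eliminator 2;
* ``p_multiword_phrase`` — entities rendered as descriptive phrases
  ("X suppressor protein") exercising name refinement;
* ``duplicate_sentence_rate`` — verbatim sentence repeats across
  abstracts exercising unique-sentence vote averaging;
* ``prior_coverage`` — fraction of the planted network present in the
  generated curated databases.

Relation sentences are allocated round-robin over the planted relations
(support counts differ by at most one) and each relation's successive
sentences cycle through distinct templates, so no two genuine supporting
sentences are textually identical.  Sentence templates are bundled data,
not code.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .ner import GeneLexicon, stub_annotate
from .refinement import default_english_lexicon, default_stoplist
from .preprocess import TRIGGER_STEMS
from .types import (
    AbstractRecord,
    PriorDatabase,
    PriorKnowledgeBase,
    SentenceRecord,
    ValidationError,
    normalize_name,
)

__all__ = ["SimConfig", "SimCorpus", "generate_corpus", "generate_prior_kb"]

_DESCRIPTORS = ("suppressor protein", "factor")

_CONSONANTS = "bcdfghjklmnpqrstvwxyz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate a small keyword-retrieved abstract set for one
    bacterial organism with a curated database covering the planted
    network (as a curated resource does for its own organism).
    """

    seed: int = 42
    n_genes: int = 30
    n_true_relations: int = 40
    n_abstracts: int = 50
    sentences_per_abstract: tuple[int, int] = (3, 5)
    p_irrelevant_sentence: float = 0.25
    p_decoy_entity: float = 0.2
    p_multiword_phrase: float = 0.2
    duplicate_sentence_rate: float = 0.1
    prior_coverage: float = 1.0
    n_databases: int = 1
    organism: str = "Bacillus subtilis"

    def __post_init__(self) -> None:
        for name in ("p_irrelevant_sentence", "p_decoy_entity",
                     "p_multiword_phrase", "duplicate_sentence_rate",
                     "prior_coverage"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("n_genes", "n_true_relations", "n_abstracts", "n_databases"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.sentences_per_abstract
        if not (1 <= lo <= hi):
            raise ValidationError("sentences_per_abstract must be a valid range")
        cap = self.n_genes * (self.n_genes - 1)
        if self.n_true_relations > cap:
            raise ValidationError(
                f"n_true_relations={self.n_true_relations} exceeds the "
                f"{cap} ordered pairs of {self.n_genes} genes"
            )


@dataclass
class SimCorpus:
    """Generator output: abstracts, gold sentences, lexicon, planted network."""

    abstracts: list[AbstractRecord]
    sentences: list[SentenceRecord]
    lexicon: GeneLexicon
    gold_network: set[tuple[str, str]]
    config: SimConfig


def _load_templates() -> dict[str, list[str]]:
    templates: dict[str, list[str]] = {}
    ref = resources.files("gix.data").joinpath("templates.tsv")
    for line in ref.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        kind, template = line.split("\t", 1)
        templates.setdefault(kind, []).append(template)
    return templates


def _gene_names(rng: random.Random, n: int) -> list[str]:
    """Unique gene-like symbols: three lowercase letters + capital.

    Names avoid the interaction trigger stems (a name must never make a
    trigger-free sentence look regulatory) and the bundled English
    lexicon/stoplist (a name must survive refinement).
    """
    forbidden = default_english_lexicon() | default_stoplist()
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        name = (
            rng.choice(_CONSONANTS)
            + rng.choice(_VOWELS)
            + rng.choice(_CONSONANTS)
            + rng.choice(string.ascii_uppercase)
        )
        folded = name.casefold()
        if folded in seen or folded in forbidden:
            continue
        if any(stem in folded for stem in TRIGGER_STEMS):
            continue
        names.append(name)
        seen.add(folded)
    return names


def _plant_relations(
    rng: random.Random, genes: Sequence[str], n: int
) -> list[tuple[str, str]]:
    """Sample n directed pairs, avoiding reverse duplicates when possible."""
    pairs = [(a, t) for a in genes for t in genes if a != t]
    rng.shuffle(pairs)
    chosen: list[tuple[str, str]] = []
    taken: set[tuple[str, str]] = set()
    for pair in pairs:
        if len(chosen) == n:
            break
        if (pair[1], pair[0]) in taken:
            continue
        chosen.append(pair)
        taken.add(pair)
    for pair in pairs:  # fall back to reverses only if we ran out
        if len(chosen) == n:
            break
        if pair not in taken:
            chosen.append(pair)
            taken.add(pair)
    return chosen


def generate_corpus(config: SimConfig) -> SimCorpus:
    """Generate abstracts, gold sentence corpus, lexicon and planted network.

    Deterministic: the same config (including seed) yields byte-identical
    output.  Relation sentences place the agent before the target with a
    trigger verb in between; irrelevant sentences contain no trigger (and
    sometimes two genes, to exercise the relevance eliminator rather than
    the entity-count eliminator).
    """
    rng = random.Random(config.seed)
    templates = _load_templates()
    genes = _gene_names(rng, config.n_genes)
    bare_norm = {g: normalize_name(g) for g in genes}
    relations = _plant_relations(rng, genes, config.n_true_relations)
    gold_network = {(bare_norm[a], bare_norm[t]) for a, t in relations}

    lexicon_entries: dict[str, str] = {g: bare_norm[g] for g in genes}

    # plan slots
    per_abstract = [
        rng.randint(*config.sentences_per_abstract) for _ in range(config.n_abstracts)
    ]
    slot_is_relation: list[list[bool]] = [
        [rng.random() >= config.p_irrelevant_sentence for _ in range(k)]
        for k in per_abstract
    ]
    n_relation_slots = sum(sum(flags) for flags in slot_is_relation)
    rel_order = list(relations)
    rng.shuffle(rel_order)

    rel_counter: dict[tuple[str, str], int] = {r: 0 for r in relations}
    rel_templates = templates.get("relation", [])
    decoy_templates = templates.get("relation_decoy", [])
    plain_templates = templates.get("irrelevant_plain", [])
    twogene_templates = templates.get("irrelevant_twogene", [])
    onegene_templates = templates.get("irrelevant_onegene", [])
    planted_ordered = set(relations)

    def render_entity(gene: str) -> tuple[str, str]:
        """Return (surface, lexicon surface) — possibly a descriptive phrase."""
        if rng.random() < config.p_multiword_phrase:
            descriptor = rng.choice(_DESCRIPTORS)
            phrase = f"{gene} {descriptor}"
            lexicon_entries.setdefault(phrase, normalize_name(phrase))
            return phrase, phrase
        return gene, gene

    def make_relation_sentence(rel_idx: int) -> tuple[str, tuple[str, str]]:
        agent, target = rel_order[rel_idx % len(rel_order)]
        c = rel_counter[(agent, target)]
        rel_counter[(agent, target)] += 1
        agent_surface, _ = render_entity(agent)
        target_surface, _ = render_entity(target)
        use_decoy = decoy_templates and rng.random() < config.p_decoy_entity
        if use_decoy:
            decoy = rng.choice([g for g in genes if g not in (agent, target)])
            template = decoy_templates[c % len(decoy_templates)]
            text = template.format(agent=agent_surface, target=target_surface, decoy=decoy)
        else:
            template = rel_templates[c % len(rel_templates)]
            text = template.format(agent=agent_surface, target=target_surface)
        pair = (normalize_name(agent_surface), normalize_name(target_surface))
        return text, pair

    def make_irrelevant_sentence(idx: int) -> str:
        # three flavours: no entities (dies at eliminator 1), two entities
        # without a trigger (eliminator 1), one entity with a trigger
        # (survives eliminator 1, dies at eliminator 2)
        roll = rng.random()
        if twogene_templates and roll < 1 / 3:
            while True:
                g1, g2 = rng.sample(genes, 2)
                if (g1, g2) not in planted_ordered and (g2, g1) not in planted_ordered:
                    break
            template = twogene_templates[idx % len(twogene_templates)]
            return template.format(g1=g1, g2=g2)
        if onegene_templates and roll < 2 / 3:
            template = onegene_templates[idx % len(onegene_templates)]
            return template.format(g1=rng.choice(genes))
        return plain_templates[idx % len(plain_templates)]

    # generate texts abstract by abstract
    texts: list[list[str]] = []
    gold_pairs_per_sentence: list[list[frozenset[tuple[str, str]]]] = []
    rel_slot = 0
    irr_slot = 0
    relation_sentence_index: list[tuple[int, int]] = []  # (abstract, position)
    for i, flags in enumerate(slot_is_relation):
        sent_texts: list[str] = []
        sent_gold: list[frozenset[tuple[str, str]]] = []
        for flag in flags:
            if flag and n_relation_slots:
                text, pair = make_relation_sentence(rel_slot)
                rel_slot += 1
                relation_sentence_index.append((i, len(sent_texts)))
                sent_gold.append(frozenset({pair}))
            else:
                text = make_irrelevant_sentence(irr_slot)
                irr_slot += 1
                sent_gold.append(frozenset())
            sent_texts.append(text)
        texts.append(sent_texts)
        gold_pairs_per_sentence.append(sent_gold)

    # verbatim duplicates into other abstracts
    for (src_abs, src_pos) in list(relation_sentence_index):
        if config.n_abstracts > 1 and rng.random() < config.duplicate_sentence_rate:
            dst = rng.choice([j for j in range(config.n_abstracts) if j != src_abs])
            texts[dst].append(texts[src_abs][src_pos])
            gold_pairs_per_sentence[dst].append(gold_pairs_per_sentence[src_abs][src_pos])

    lexicon = GeneLexicon.from_pairs(sorted(lexicon_entries.items()))

    abstracts: list[AbstractRecord] = []
    sentences: list[SentenceRecord] = []
    for i, sent_texts in enumerate(texts):
        pmid = f"SYN{i:04d}"
        abstracts.append(
            AbstractRecord(
                pmid=pmid,
                title=f"Regulation of gene networks in {config.organism}: study {i}.",
                abstract_text=" ".join(sent_texts),
            )
        )
        for j, text in enumerate(sent_texts):
            record = SentenceRecord(
                sentence_id=f"{pmid}:s{j}",
                pmid=pmid,
                text=text,
                mentions=tuple(stub_annotate(text, lexicon)),
                gold_pairs=gold_pairs_per_sentence[i][j],
            )
            record.validate()
            sentences.append(record)

    return SimCorpus(
        abstracts=abstracts,
        sentences=sentences,
        lexicon=lexicon,
        gold_network=gold_network,
        config=config,
    )


def generate_prior_kb(
    gold_network: set[tuple[str, str]], config: SimConfig
) -> PriorKnowledgeBase:
    """Curated databases covering a configured fraction of the network.

    Each database holds the same covered subset of the planted relations,
    with the covered relations' agents listed as known regulators.
    ``prior_coverage`` 0 yields databases with no relations (CF2 = 0 for
    every edge).
    """
    if not gold_network:
        raise ValidationError("gold network must be non-empty")
    rng = random.Random(config.seed + 1)
    ordered = sorted(gold_network)
    n_covered = round(config.prior_coverage * len(ordered))
    covered = frozenset(rng.sample(ordered, n_covered)) if n_covered else frozenset()
    regulators = frozenset(a for a, _ in covered)
    return PriorKnowledgeBase(
        databases=tuple(
            PriorDatabase(name=f"syndb{i}", regulators=regulators, relations=covered)
            for i in range(config.n_databases)
        )
    )
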