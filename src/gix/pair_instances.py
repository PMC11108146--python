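"""Stage 2 input construction: directed candidate pairs and anonymization.

For a sentence with *n* distinct gene/protein entities every ordered pair
of distinct entities is a candidate, so exactly ``n * (n - 1)`` instances
are produced.  Each instance renders the sentence with the labelling
schema: every mention of the agent becomes ``$GENE_AGENT#``, every
mention of the target ``$GENE_TARGET#``, and every other gene/protein
mention is masked as ``BLANK`` so the classifier sees exactly one pair in
an otherwise unchanged sentence.  The substitution is lossless: with the
mention spans in hand the original sentence can be reconstructed exactly.
"""

from __future__ import annotations

import numpy as np

from typing import Sequence

from .types import (
    AGENT_TAG,
    BLANK_TAG,
    TARGET_TAG,
    RelationInstance,
    SentenceRecord,
    ValidationError,
)

__all__ = [
    "enumerate_instances",
    "render_labelled_sentence",
    "detag_labelled_sentence",
    "build_re_finetune_dataset",
    "build_elim1_finetune_dataset",
    "make_kfold_splits",
]


def render_labelled_sentence(sentence: SentenceRecord, agent: str, target: str) -> str:
    """Render the anonymized sentence for one directed (agent, target) pair.

    Replacements are applied right-to-left so earlier offsets stay valid.
    Non-gene mentions and all non-mention text are left untouched.
    """
    if agent == target:
        raise ValidationError("agent and target must differ")
    ids = {m.normalized_id for m in sentence.mentions if m.is_gene}
    if agent not in ids or target not in ids:
        raise ValidationError(
            f"{sentence.sentence_id}: agent/target must both be mentioned"
        )
    text = sentence.text
    for m in sorted(sentence.mentions, key=lambda m: m.start, reverse=True):
        if not m.is_gene:
            continue
        if m.normalized_id == agent:
            tag = AGENT_TAG
        elif m.normalized_id == target:
            tag = TARGET_TAG
        else:
            tag = BLANK_TAG
        text = text[: m.start] + tag + text[m.end :]
    return text


def detag_labelled_sentence(
    labelled: str, sentence: SentenceRecord, agent: str, target: str
) -> str:
    """Invert :func:`render_labelled_sentence` using the mention spans.

    Walks the gene mentions in offset order, replacing each expected tag
    occurrence with the original surface.  Because the schema leaves all
    non-mention text untouched, the result equals the original sentence
    exactly — the anonymization does not alter the surrounding lexical
    structure.
    """
    out = labelled
    pos = 0
    for m in sorted(sentence.mentions, key=lambda m: m.start):
        if not m.is_gene:
            continue
        if m.normalized_id == agent:
            tag = AGENT_TAG
        elif m.normalized_id == target:
            tag = TARGET_TAG
        else:
            tag = BLANK_TAG
        idx = out.find(tag, pos)
        if idx < 0:
            raise ValidationError(f"expected tag {tag!r} not found in labelled text")
        out = out[:idx] + m.surface + out[idx + len(tag) :]
        pos = idx + len(m.surface)
    return out


def enumerate_instances(sentence: SentenceRecord) -> list[RelationInstance]:
    """All directed candidate pairs of one sentence, rendered and unscored.

    Exactly one instance per ordered pair of distinct normalized entities
    (n distinct entities -> n*(n-1) instances), emitted by first-mention
    offset of the agent, then of the target.
    """
    entities = sentence.gene_ids()
    if len(entities) < 2:
        raise ValidationError(
            f"{sentence.sentence_id}: need >= 2 distinct gene/protein entities "
            f"(got {len(entities)}); eliminator-2 contract violated"
        )
    instances = []
    for agent in entities:
        for target in entities:
            if agent == target:
                continue
            instances.append(
                RelationInstance(
                    instance_id=f"{sentence.sentence_id}|{agent}->{target}",
                    sentence_id=sentence.sentence_id,
                    agent=agent,
                    target=target,
                    labelled_text=render_labelled_sentence(sentence, agent, target),
                )
            )
    return instances


def build_re_finetune_dataset(corpus: Sequence[SentenceRecord]) -> list[RelationInstance]:
    """Labelled relation instances for classifier fine-tuning.

    Each enumerated instance gets label 1 iff its directed (agent, target)
    pair is among the sentence's gold pairs, else 0.  Sentences must be
    annotated (``gold_pairs`` not ``None``); an empty gold set labels all
    of the sentence's instances negative.
    """
    dataset = []
    for sentence in corpus:
        if sentence.gold_pairs is None:
            raise ValidationError(f"{sentence.sentence_id}: gold_pairs missing")
        if len(sentence.gene_ids()) < 2:
            continue  # no candidate pairs to label
        for inst in enumerate_instances(sentence):
            label = 1 if (inst.agent, inst.target) in sentence.gold_pairs else 0
            dataset.append(
                RelationInstance(
                    instance_id=inst.instance_id,
                    sentence_id=inst.sentence_id,
                    agent=inst.agent,
                    target=inst.target,
                    labelled_text=inst.labelled_text,
                    label=label,
                )
            )
    return dataset


def build_elim1_finetune_dataset(
    corpus: Sequence[SentenceRecord],
) -> list[tuple[str, int]]:
    """Sentence-level dataset for the relevance classifier.

    A sentence dictating at least one regulatory relationship (non-empty
    gold set) is positive; the rest are negative.
    """
    dataset = []
    for sentence in corpus:
        if sentence.gold_pairs is None:
            raise ValidationError(f"{sentence.sentence_id}: gold_pairs missing")
        dataset.append((sentence.text, 1 if sentence.gold_pairs else 0))
    return dataset


def make_kfold_splits(
    instances: Sequence[RelationInstance], k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold partitions grouped by sentence.

    The grouping unit is the unique sentence, so instances from one
    sentence never straddle train and test.  Sentence folds are disjoint,
    exhaustive and differ in size by at most one; the shuffle is
    deterministic given ``seed``.  Returns ``(train_idx, test_idx)``
    index arrays into ``instances`` for each fold.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    sentence_ids = list(dict.fromkeys(inst.sentence_id for inst in instances))
    if k > len(sentence_ids):
        raise ValidationError(
            f"k={k} exceeds the number of unique sentences ({len(sentence_ids)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sentence_ids))
    shuffled = [sentence_ids[i] for i in order]
    folds = np.array_split(np.arange(len(shuffled)), k)
    splits = []
    for fold in folds:
        test_sentences = {shuffled[i] for i in fold}
        test_idx = np.array(
            [i for i, inst in enumerate(instances) if inst.sentence_id in test_sentences],
            dtype=int,
        )
        train_idx = np.array(
            [i for i, inst in enumerate(instances) if inst.sentence_id not in test_sentences],
            dtype=int,
        )
        splits.append((train_idx, test_idx))
    return splits
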