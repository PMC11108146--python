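"""End-to-end orchestration of the three stages.

``run_pipeline`` wires together: organism filtering, sentence splitting,
the two sentence eliminators, candidate-pair enumeration and
anonymization, relation scoring and classification, entity-name
refinement, vote aggregation with the prior-knowledge confidence factor,
and γ thresholding.  It returns the kept edges together with per-stage
counts mirroring the flow reports of the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .confidence_network import (
    ConfidenceConfig,
    DirectedEdge,
    build_edges,
    filter_edges,
    select_gamma_roc,
)
from .ner import NerProvider
from .pair_instances import enumerate_instances
from .preprocess import (
    RelevanceScorer,
    eliminate_by_entity_count,
    eliminate_nonregulatory,
    filter_abstracts_by_organism,
    organism_name_forms,
    split_sentences,
)
from .refinement import RefinementConfig, refine_relations
from .relation_classifier import RelationScorer, classify, score_instances
from .types import AbstractRecord, PriorKnowledgeBase, SentenceRecord

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full extraction run."""

    organism: str
    elim1_cutoff: float = 0.5
    classify_cutoff: float = 0.5
    confidence: ConfidenceConfig = ConfidenceConfig()
    #: When set, γ is chosen by ROC analysis against this gold relation
    #: set instead of using ``confidence.gamma``.
    roc_gold: Optional[frozenset[tuple[str, str]]] = None


@dataclass
class PipelineResult:
    """Kept edges plus the per-stage flow counts."""

    edges: list[DirectedEdge]
    all_edges: list[DirectedEdge]
    gamma: float
    report: dict[str, int | float]
    sentences: dict[str, SentenceRecord] = field(default_factory=dict)


def run_pipeline(
    abstracts: Sequence[AbstractRecord],
    provider: NerProvider,
    relevance_scorer: RelevanceScorer,
    relation_scorer: RelationScorer,
    refinement: RefinementConfig,
    kb: PriorKnowledgeBase,
    config: PipelineConfig,
) -> PipelineResult:
    forms = organism_name_forms(config.organism)
    kept_abstracts = filter_abstracts_by_organism(abstracts, forms)

    sentences: list[SentenceRecord] = []
    for record in kept_abstracts:
        sentences.extend(split_sentences(record))

    kept1, removed1 = eliminate_nonregulatory(
        sentences, relevance_scorer, cutoff=config.elim1_cutoff
    )
    kept2, removed2 = eliminate_by_entity_count(kept1, provider)

    instances = []
    for sentence in kept2:
        instances.extend(enumerate_instances(sentence))
    scored = score_instances(instances, relation_scorer)
    positives = classify(scored, cutoff=config.classify_cutoff)
    refined = refine_relations(positives, refinement)

    by_id = {s.sentence_id: s for s in kept2}
    all_edges = build_edges(refined, by_id, kb, config.confidence)

    if config.roc_gold is not None and all_edges:
        gamma = select_gamma_roc(all_edges, set(config.roc_gold))
    else:
        gamma = config.confidence.gamma
    kept_edges = filter_edges(all_edges, gamma)

    report = {
        "abstracts_in": len(abstracts),
        "abstracts_kept": len(kept_abstracts),
        "sentences_total": len(sentences),
        "sentences_removed_elim1": len(removed1),
        "sentences_removed_elim2": len(removed2),
        "sentences_kept": len(kept2),
        "instances": len(instances),
        "positive_instances": len(positives),
        "refined_relations": len(refined),
        "edges_total": len(all_edges),
        "gamma": gamma,
        "edges_kept": len(kept_edges),
    }
    return PipelineResult(
        edges=kept_edges,
        all_edges=all_edges,
        gamma=gamma,
        report=report,
        sentences=by_id,
    )
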