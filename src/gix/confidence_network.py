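"""Stage 3 scoring and network output.

Each surviving directed relation e_a -> e_t is scored with a confidence
factor combining literature evidence and curated prior knowledge::

    CF = CF1 + K * CF2,   CF1 = sum_s v_s,   CF2 = sum_T P_T(e_a, e_t)

where the first sum runs over the n unique sentences predicting the
relation (v_s the averaged classifier vote of sentence s), the second
over the M curated databases, and the per-database prior P is 3 for a
known relation, 1 when the agent is a known regulator but the relation
is not curated, and 0 otherwise.  K balances the two components.

Relations with CF below a threshold γ are treated as false positives and
dropped (CF == γ is kept); γ may be supplied or chosen by ROC analysis
against a gold relation set, maximizing Youden's J = TPR − FPR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .types import (
    DirectedEdge,
    PriorDatabase,
    PriorKnowledgeBase,
    RelationInstance,
    SentenceRecord,
    ValidationError,
)

__all__ = [
    "ConfidenceConfig",
    "sentence_votes",
    "prior_score",
    "compute_cf",
    "build_edges",
    "select_gamma_roc",
    "filter_edges",
    "export_network",
    "edges_to_frame",
    "frame_to_edges",
]

EXPORT_FORMATS = ("tsv", "sif", "graphml")


@dataclass(frozen=True)
class ConfidenceConfig:
    """K, γ and the positive-vote cutoff.

    ``K`` balances prior knowledge against literature evidence (K = 0
    collapses CF to pure literature evidence).  ``gamma`` is the CF
    acceptance threshold; ``vote_cutoff`` the classifier-positive cutoff
    applied before votes are aggregated.
    """

    K: float = 1.0
    gamma: float = 0.0
    vote_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.K < 0 or self.gamma < 0:
            raise ValidationError("K and gamma must be non-negative")
        if not (0.0 <= self.vote_cutoff <= 1.0):
            raise ValidationError("vote_cutoff must be in [0, 1]")


def sentence_votes(
    instances: Sequence[RelationInstance],
    sentences: Mapping[str, SentenceRecord],
) -> dict[tuple[str, str], dict[str, float]]:
    """Average instance scores into one vote per unique sentence.

    Instances sharing (agent, target) and *identical sentence text* are
    arithmetic-mean averaged into a single vote — repeats of the same
    sentence across abstracts count once.  Unique-sentence identity is
    exact string equality of the sentence text.
    """
    sums: dict[tuple[str, str], dict[str, list[float]]] = {}
    for inst in instances:
        if inst.score is None:
            raise ValidationError(f"{inst.instance_id} is unscored")
        text = sentences[inst.sentence_id].text
        sums.setdefault((inst.agent, inst.target), {}).setdefault(text, []).append(
            inst.score
        )
    return {
        pair: {text: sum(vals) / len(vals) for text, vals in by_text.items()}
        for pair, by_text in sums.items()
    }


def prior_score(agent: str, target: str, db: PriorDatabase) -> int:
    """Per-database prior P for a directed pair: 3, 1 or 0.

    3 when the relation itself is curated (two entities plus the
    connecting arc), 1 when only the agent is a known regulator, 0
    otherwise.
    """
    if (agent, target) in db.relations:
        return 3
    if agent in db.regulators:
        return 1
    return 0


def compute_cf(
    agent: str,
    target: str,
    votes: Mapping[str, float],
    kb: PriorKnowledgeBase,
    config: ConfidenceConfig,
    support: Sequence[tuple[str, str]] = (),
) -> DirectedEdge:
    """Assemble one scored edge: CF1, CF2 and CF = CF1 + K * CF2."""
    if not votes:
        raise ValidationError("an edge must have at least one supporting sentence")
    cf1 = float(sum(votes.values()))
    cf2 = sum(prior_score(agent, target, db) for db in kb.databases)
    return DirectedEdge(
        agent=agent,
        target=target,
        votes=dict(votes),
        cf1=cf1,
        cf2=cf2,
        cf=cf1 + config.K * cf2,
        support=tuple(support),
    )


def build_edges(
    instances: Sequence[RelationInstance],
    sentences: Mapping[str, SentenceRecord],
    kb: PriorKnowledgeBase,
    config: ConfidenceConfig,
) -> list[DirectedEdge]:
    """Aggregate refined positive instances into scored directed edges."""
    votes = sentence_votes(instances, sentences)
    support: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for inst in instances:
        sent = sentences[inst.sentence_id]
        entry = (sent.pmid, sent.sentence_id)
        lst = support.setdefault((inst.agent, inst.target), [])
        if entry not in lst:
            lst.append(entry)
    return [
        compute_cf(agent, target, v, kb, config, support=support[(agent, target)])
        for (agent, target), v in votes.items()
    ]


def select_gamma_roc(
    edges: Sequence[DirectedEdge], gold: set[tuple[str, str]]
) -> float:
    """γ maximizing Youden's J = TPR − FPR over the distinct CF values.

    An edge is predicted positive when CF >= γ, matching the filtering
    rule.  Ties on J break toward the larger γ (fewer false positives).
    Raises when the gold labelling is degenerate (all edges gold, or
    none), since the ROC is undefined there.
    """
    if not edges:
        raise ValidationError("edges must be non-empty")
    if not gold:
        raise ValidationError("gold relation set must be non-empty")
    labels = np.array([1 if e.key in gold else 0 for e in edges])
    scores = np.array([e.cf for e in edges], dtype=float)
    if labels.all() or not labels.any():
        raise ValidationError("ROC undefined: edges are all gold or all non-gold")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    # drop the synthetic (max + 1)-style leading threshold; candidates are
    # the distinct observed CF values
    finite = np.isfinite(thresholds) & (thresholds <= scores.max())
    fpr, tpr, thresholds = fpr[finite], tpr[finite], thresholds[finite]
    j = tpr - fpr
    best = j.max()
    return float(max(thresholds[j >= best - 1e-12]))


def filter_edges(edges: Sequence[DirectedEdge], gamma: float) -> list[DirectedEdge]:
    """Keep edges with CF >= γ (relations with CF < γ are false positives)."""
    return [e for e in edges if e.cf >= gamma]


def edges_to_frame(edges: Sequence[DirectedEdge]) -> pd.DataFrame:
    """Tabular edge view: agent, target, n_sentences, CF1, CF2, CF, support."""
    return pd.DataFrame(
        {
            "agent": [e.agent for e in edges],
            "target": [e.target for e in edges],
            "n_sentences": [e.n for e in edges],
            "CF1": [e.cf1 for e in edges],
            "CF2": [e.cf2 for e in edges],
            "CF": [e.cf for e in edges],
            "support_pmids": [
                ";".join(dict.fromkeys(p for p, _ in e.support)) for e in edges
            ],
        }
    )


def frame_to_edges(frame: pd.DataFrame) -> list[DirectedEdge]:
    """Rebuild minimal edges (no per-sentence votes) from the table."""
    edges = []
    for row in frame.itertuples(index=False):
        n = int(row.n_sentences)
        # votes are not serialized per sentence; spread CF1 evenly so that
        # n and CF1 round-trip
        votes = {f"sentence {i}": row.CF1 / n for i in range(n)} if n else {}
        support = tuple(
            (p, "") for p in str(row.support_pmids).split(";") if p and p != "nan"
        )
        edges.append(
            DirectedEdge(
                agent=row.agent,
                target=row.target,
                votes=votes,
                cf1=float(row.CF1),
                cf2=int(row.CF2),
                cf=float(row.CF),
                support=support,
            )
        )
    return edges


def _to_graph(edges: Sequence[DirectedEdge]) -> nx.DiGraph:
    graph = nx.DiGraph()
    for e in edges:
        graph.add_edge(e.agent, e.target, weight=float(e.cf))
    for node in graph.nodes:
        graph.nodes[node]["in_degree"] = graph.in_degree(node)
    return graph


def export_network(
    edges: Sequence[DirectedEdge], format: str, path: str | Path
) -> None:
    """Write the confidence-weighted network.

    Formats: ``tsv`` (edge table, columns as :func:`edges_to_frame`),
    ``sif`` (``agent<TAB>regulates<TAB>target``), ``graphml`` (directed
    graph, edge attribute ``weight`` = CF, node attribute ``in_degree``
    so viewers can size nodes by regulatory in-degree).
    """
    path = Path(path)
    if format == "tsv":
        edges_to_frame(edges).to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for e in edges:
                fh.write(f"{e.agent}\tregulates\t{e.target}\n")
    elif format == "graphml":
        nx.write_graphml(_to_graph(edges), path)
    else:
        raise ValidationError(
            f"unknown format {format!r}; expected one of {EXPORT_FORMATS}"
        )
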