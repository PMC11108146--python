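"""Vote averaging, the confidence factor, γ selection and export."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from gix.confidence_network import (
    ConfidenceConfig,
    build_edges,
    compute_cf,
    edges_to_frame,
    export_network,
    filter_edges,
    frame_to_edges,
    prior_score,
    select_gamma_roc,
    sentence_votes,
)
from gix.types import (
    AGENT_TAG,
    TARGET_TAG,
    DirectedEdge,
    PriorDatabase,
    PriorKnowledgeBase,
    RelationInstance,
    SentenceRecord,
    ValidationError,
)


def make_instance(agent, target, score, sentence_id):
    return RelationInstance(
        instance_id=f"{sentence_id}|{agent}->{target}",
        sentence_id=sentence_id,
        agent=agent,
        target=target,
        labelled_text=f"{AGENT_TAG} binds {TARGET_TAG}.",
        score=score,
    )


def make_sentences(texts):
    return {
        f"s{i}": SentenceRecord(sentence_id=f"s{i}", pmid=f"p{i}", text=text)
        for i, text in enumerate(texts)
    }


class TestSentenceVotes:
    def test_identical_sentence_text_averages_into_one_vote(self):
        sentences = make_sentences(["TrpE raises trpR.", "TrpE raises trpR."])
        instances = [
            make_instance("trpe", "trpr", 0.8, "s0"),
            make_instance("trpe", "trpr", 0.6, "s1"),
        ]
        votes = sentence_votes(instances, sentences)
        assert votes == {("trpe", "trpr"): {"TrpE raises trpR.": pytest.approx(0.7)}}

    def test_singleton_mean(self):
        sentences = make_sentences(["TrpE raises trpR."])
        votes = sentence_votes([make_instance("trpe", "trpr", 0.9, "s0")], sentences)
        assert votes[("trpe", "trpr")] == {"TrpE raises trpR.": 0.9}

    def test_distinct_sentences_give_distinct_votes(self):
        sentences = make_sentences(["TrpE raises trpR.", "trpR needs TrpE."])
        instances = [
            make_instance("trpe", "trpr", 0.9, "s0"),
            make_instance("trpe", "trpr", 0.7, "s1"),
        ]
        assert len(sentence_votes(instances, sentences)[("trpe", "trpr")]) == 2

    def test_unscored_instance_rejected(self):
        sentences = make_sentences(["x y."])
        with pytest.raises(ValidationError):
            sentence_votes([make_instance("a", "b", None, "s0")], sentences)


class TestPriorScore:
    db = PriorDatabase(
        "regdb",
        regulators=frozenset({"cytr", "fnr"}),
        relations=frozenset({("cytr", "crp")}),
    )

    def test_known_relation_scores_three(self):
        assert prior_score("cytr", "crp", self.db) == 3

    def test_known_regulator_unknown_relation_scores_one(self):
        assert prior_score("cytr", "deoc", self.db) == 1
        assert prior_score("fnr", "crp", self.db) == 1

    def test_otherwise_zero(self):
        assert prior_score("deoc", "crp", self.db) == 0

    def test_direction_matters(self):
        assert prior_score("crp", "cytr", self.db) == 0


class TestComputeCF:
    kb2 = PriorKnowledgeBase(
        databases=(
            PriorDatabase("d1", relations=frozenset({("a", "b")})),
            PriorDatabase("d2", relations=frozenset({("a", "b")})),
        )
    )

    def test_single_vote_no_prior(self):
        edge = compute_cf("a", "b", {"s": 0.9}, PriorKnowledgeBase(), ConfidenceConfig(K=1))
        assert edge.cf == pytest.approx(0.9) and edge.cf2 == 0 and edge.n == 1

    def test_two_votes_relation_known_in_two_databases(self):
        edge = compute_cf("a", "b", {"s1": 0.9, "s2": 0.8}, self.kb2, ConfidenceConfig(K=1))
        assert edge.cf1 == pytest.approx(1.7)
        assert edge.cf2 == 6
        assert edge.cf == pytest.approx(7.7)

    def test_k_zero_collapses_to_literature_evidence(self):
        edge = compute_cf("a", "b", {"s1": 0.9, "s2": 0.8}, self.kb2, ConfidenceConfig(K=0))
        assert edge.cf == edge.cf1

    def test_empty_votes_rejected(self):
        with pytest.raises(ValidationError):
            compute_cf("a", "b", {}, PriorKnowledgeBase(), ConfidenceConfig())

    def test_identity_on_random_inputs_against_bruteforce(self):
        rng = random.Random(11)
        genes = [f"g{i}" for i in range(8)]
        for _ in range(200):
            agent, target = rng.sample(genes, 2)
            votes = {f"t{j}": rng.random() for j in range(rng.randint(1, 5))}
            dbs = []
            for d in range(rng.randint(0, 3)):
                regs = frozenset(rng.sample(genes, rng.randint(0, 4)))
                rels = frozenset(
                    tuple(rng.sample(genes, 2)) for _ in range(rng.randint(0, 5))
                )
                dbs.append(PriorDatabase(f"d{d}", regulators=regs, relations=rels))
            kb = PriorKnowledgeBase(databases=tuple(dbs))
            K = rng.choice([0.0, 0.5, 1.0, 2.0])
            edge = compute_cf(agent, target, votes, kb, ConfidenceConfig(K=K))
            cf1 = sum(votes.values())
            cf2 = 0
            for db in dbs:
                if (agent, target) in db.relations:
                    cf2 += 3
                elif agent in db.regulators:
                    cf2 += 1
            assert edge.cf1 == cf1
            assert edge.cf2 == cf2
            assert 0 <= edge.cf2 <= 3 * kb.M
            assert edge.cf == cf1 + K * cf2

    def test_monotone_in_votes_and_k(self):
        kb = self.kb2
        base = compute_cf("a", "b", {"s1": 0.5}, kb, ConfidenceConfig(K=1))
        more_votes = compute_cf("a", "b", {"s1": 0.5, "s2": 0.2}, kb, ConfidenceConfig(K=1))
        higher_vote = compute_cf("a", "b", {"s1": 0.7}, kb, ConfidenceConfig(K=1))
        bigger_k = compute_cf("a", "b", {"s1": 0.5}, kb, ConfidenceConfig(K=2))
        assert more_votes.cf >= base.cf
        assert higher_vote.cf >= base.cf
        assert bigger_k.cf >= base.cf


def edge(agent, target, cf):
    return DirectedEdge(agent=agent, target=target, votes={"s": cf}, cf1=cf, cf2=0, cf=cf)


def sweep_oracle(edges, gold):
    """Exhaustive threshold sweep maximizing TPR - FPR; ties to larger γ."""
    pos = [e.cf for e in edges if e.key in gold]
    neg = [e.cf for e in edges if e.key not in gold]
    best_gamma, best_j = None, -2.0
    for gamma in sorted({e.cf for e in edges}):
        tpr = sum(c >= gamma for c in pos) / len(pos)
        fpr = sum(c >= gamma for c in neg) / len(neg)
        j = tpr - fpr
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and gamma > best_gamma):
            best_gamma, best_j = gamma, j
    return best_gamma


class TestGammaSelection:
    def test_separable_case(self):
        edges = [edge("a", "b", 5), edge("a", "c", 6), edge("x", "y", 1), edge("x", "z", 2)]
        gold = {("a", "b"), ("a", "c")}
        assert select_gamma_roc(edges, gold) == 5

    def test_single_gold_above_all_non_gold_gives_perfect_j(self):
        edges = [edge("a", "b", 9), edge("x", "y", 1), edge("x", "z", 2)]
        gamma = select_gamma_roc(edges, {("a", "b")})
        assert gamma == 9
        assert [e.key for e in filter_edges(edges, gamma)] == [("a", "b")]

    def test_degenerate_gold_rejected(self):
        edges = [edge("a", "b", 5), edge("a", "c", 6)]
        with pytest.raises(ValidationError):
            select_gamma_roc(edges, {("a", "b"), ("a", "c")})
        with pytest.raises(ValidationError):
            select_gamma_roc(edges, {("q", "r")})

    def test_matches_exhaustive_sweep_on_random_configurations(self):
        rng = random.Random(23)
        for _ in range(100):
            n = rng.randint(4, 60)
            edges = [
                edge(f"a{i}", f"b{i}", round(rng.uniform(0, 8), 3)) for i in range(n)
            ]
            n_gold = rng.randint(1, n - 1)
            gold = {e.key for e in rng.sample(edges, n_gold)}
            assert select_gamma_roc(edges, gold) == pytest.approx(
                sweep_oracle(edges, gold)
            )


class TestFilterEdges:
    def test_below_gamma_dropped(self):
        assert filter_edges([edge("a", "b", 0.87)], gamma=0.88) == []

    def test_exactly_gamma_kept(self):
        kept = filter_edges([edge("a", "b", 0.88)], gamma=0.88)
        assert len(kept) == 1

    def test_gamma_zero_keeps_all(self):
        edges = [edge("a", "b", 0.1), edge("c", "d", 5.0)]
        assert filter_edges(edges, gamma=0.0) == edges


class TestExport:
    edges = [edge("A", "B", 1.5), edge("A", "C", 2.5)]

    def test_graphml_structure_and_weights(self, tmp_path):
        path = tmp_path / "net.graphml"
        export_network(self.edges, "graphml", path)
        graph = nx.read_graphml(path)
        assert graph.is_directed()
        assert sorted(graph.nodes) == ["A", "B", "C"]
        assert graph.edges["A", "B"]["weight"] == 1.5
        assert graph.nodes["B"]["in_degree"] == 1 and graph.nodes["A"]["in_degree"] == 0

    def test_sif_round_trip_counts(self, tmp_path):
        path = tmp_path / "net.sif"
        export_network(self.edges, "sif", path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert rows == [["A", "regulates", "B"], ["A", "regulates", "C"]]

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "edges.tsv"
        export_network(self.edges, "tsv", path)
        back = frame_to_edges(pd.read_csv(path, sep="\t"))
        assert [(e.agent, e.target, e.cf, e.n) for e in back] == [
            (e.agent, e.target, e.cf, e.n) for e in self.edges
        ]

    def test_empty_edge_set_valid_files(self, tmp_path):
        export_network([], "graphml", tmp_path / "e.graphml")
        assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
        export_network([], "sif", tmp_path / "e.sif")
        assert (tmp_path / "e.sif").read_text() == ""

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            export_network(self.edges, "gexf", tmp_path / "x")


def test_build_edges_aggregates_support(default_corpus):
    corpus, kb, provider, refinement = default_corpus
    from gix.pipeline import PipelineConfig, run_pipeline
    from gix.preprocess import TriggerRelevanceScorer
    from gix.relation_classifier import RuleRelationScorer

    result = run_pipeline(
        corpus.abstracts, provider, TriggerRelevanceScorer(), RuleRelationScorer(),
        refinement, kb, PipelineConfig(organism=corpus.config.organism),
    )
    for e in result.all_edges:
        assert e.n == len(e.votes) >= 1
        assert 0 <= e.cf1 <= e.n
        assert 0 <= e.cf2 <= 3 * kb.M
        assert e.cf == pytest.approx(e.cf1 + 1.0 * e.cf2)
        assert e.support
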