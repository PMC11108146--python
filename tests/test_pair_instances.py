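"""Candidate-pair enumeration and the anonymization labelling schema."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from gix.pair_instances import (
    build_elim1_finetune_dataset,
    build_re_finetune_dataset,
    detag_labelled_sentence,
    enumerate_instances,
    make_kfold_splits,
    render_labelled_sentence,
)
from gix.types import AGENT_TAG, BLANK_TAG, TARGET_TAG, RelationInstance, ValidationError

from conftest import make_sentence


def brute_force_pairs(entities):
    """Oracle: all ordered pairs of distinct entities via a double loop."""
    return [(a, t) for a in entities for t in entities if a != t]


class TestEnumerate:
    def test_two_entities_give_two_directed_candidates(self):
        sent = make_sentence("sigK activates ykvP now.", ["sigK", "ykvP"])
        pairs = [(i.agent, i.target) for i in enumerate_instances(sent)]
        assert pairs == [("sigk", "ykvp"), ("ykvp", "sigk")]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_count_matches_double_loop_oracle(self, n):
        names = [f"g{i}X" for i in range(n)]
        sent = make_sentence("The genes " + " and ".join(names) + " interact.", names)
        instances = enumerate_instances(sent)
        oracle = brute_force_pairs(sent.gene_ids())
        assert len(instances) == n * (n - 1) == len(oracle)
        assert {(i.agent, i.target) for i in instances} == set(oracle)

    def test_repeated_mentions_pair_by_distinct_entity(self):
        sent = make_sentence("sigK binds ykvP and sigK persists.", ["sigK", "ykvP"])
        assert len(enumerate_instances(sent)) == 2

    def test_fewer_than_two_entities_rejected(self):
        sent = make_sentence("sigK is expressed.", ["sigK"])
        with pytest.raises(ValidationError):
            enumerate_instances(sent)

    def test_emission_ordered_by_first_mention_offset(self):
        sent = make_sentence("gerE binds sigK and ykvP.", ["sigK", "ykvP", "gerE"])
        agents = [i.agent for i in enumerate_instances(sent)]
        assert agents == ["gere", "gere", "sigk", "sigk", "ykvp", "ykvp"]


class TestLabelling:
    def test_third_gene_masked(self):
        sent = make_sentence("SigK and GerE jointly control ykvP.", ["SigK", "GerE", "ykvP"])
        labelled = render_labelled_sentence(sent, "sigk", "ykvp")
        assert labelled == f"{AGENT_TAG} and {BLANK_TAG} jointly control {TARGET_TAG}."

    def test_two_gene_sentence_has_no_mask(self):
        sent = make_sentence("SigK controls ykvP.", ["SigK", "ykvP"])
        labelled = render_labelled_sentence(sent, "sigk", "ykvp")
        assert BLANK_TAG not in labelled

    def test_every_agent_mention_tagged(self):
        sent = make_sentence("sigK binds ykvP and sigK persists.", ["sigK", "ykvP"])
        labelled = render_labelled_sentence(sent, "sigk", "ykvp")
        assert labelled.count(AGENT_TAG) == 2 and labelled.count(TARGET_TAG) == 1
        assert "sigK" not in labelled and "ykvP" not in labelled

    def test_same_agent_and_target_rejected(self):
        sent = make_sentence("sigK binds ykvP.", ["sigK", "ykvP"])
        with pytest.raises(ValidationError):
            render_labelled_sentence(sent, "sigk", "sigk")

    def test_detagging_restores_original_exactly(self, default_corpus):
        corpus, *_ = default_corpus
        checked = 0
        for sent in corpus.sentences:
            if len(sent.gene_ids()) < 2:
                continue
            for inst in enumerate_instances(sent):
                restored = detag_labelled_sentence(
                    inst.labelled_text, sent, inst.agent, inst.target
                )
                assert restored == sent.text
                checked += 1
        assert checked > 100


class TestDatasetBuilders:
    def test_directed_membership_labels(self):
        sent = make_sentence(
            "sigK activates ykvP.", ["sigK", "ykvP"],
            gold_pairs=frozenset({("sigk", "ykvp")}),
        )
        labels = {(i.agent, i.target): i.label for i in build_re_finetune_dataset([sent])}
        assert labels == {("sigk", "ykvp"): 1, ("ykvp", "sigk"): 0}

    def test_no_gold_pairs_all_negative(self):
        sent = make_sentence(
            "sigK, gerE and ykvP interact.", ["sigK", "ykvP", "gerE"],
            gold_pairs=frozenset(),
        )
        dataset = build_re_finetune_dataset([sent])
        assert len(dataset) == 6 and all(i.label == 0 for i in dataset)

    def test_bidirectional_gold_labels_both(self):
        sent = make_sentence(
            "sigK and ykvP cross-activate.", ["sigK", "ykvP"],
            gold_pairs=frozenset({("sigk", "ykvp"), ("ykvp", "sigk")}),
        )
        assert all(i.label == 1 for i in build_re_finetune_dataset([sent]))

    def test_unannotated_corpus_rejected(self):
        sent = make_sentence("sigK activates ykvP.", ["sigK", "ykvP"])
        with pytest.raises(ValidationError):
            build_re_finetune_dataset([sent])

    def test_relevance_labels_follow_gold_presence(self):
        positive = make_sentence(
            "sigK activates ykvP.", ["sigK", "ykvP"],
            gold_pairs=frozenset({("sigk", "ykvp")}),
        )
        negative = make_sentence(
            "Cells were washed.", [], sentence_id="s2", gold_pairs=frozenset()
        )
        assert build_elim1_finetune_dataset([positive, negative]) == [
            ("sigK activates ykvP.", 1),
            ("Cells were washed.", 0),
        ]

    def test_empty_corpus_gives_empty_dataset(self):
        assert build_elim1_finetune_dataset([]) == []


def _instances_for_sentences(n_sentences, per_sentence=2):
    out = []
    for s in range(n_sentences):
        for j in range(per_sentence):
            out.append(
                RelationInstance(
                    instance_id=f"s{s}|i{j}",
                    sentence_id=f"s{s}",
                    agent=f"a{j}",
                    target=f"t{j}",
                    labelled_text=f"{AGENT_TAG} x {TARGET_TAG}",
                    label=j % 2,
                )
            )
    return out


class TestKFold:
    def test_exact_division_gives_singleton_sentence_folds(self):
        instances = _instances_for_sentences(10)
        splits = make_kfold_splits(instances, k=10, seed=0)
        for train, test in splits:
            assert {instances[i].sentence_id for i in test}.__len__() == 1
            assert len(test) == 2  # both instances of the sentence travel together

    def test_uneven_division_sizes_differ_by_at_most_one(self):
        instances = _instances_for_sentences(11, per_sentence=1)
        splits = make_kfold_splits(instances, k=10, seed=0)
        sizes = sorted(len(test) for _, test in splits)
        assert sizes == [1] * 9 + [2]

    def test_folds_disjoint_and_exhaustive(self):
        instances = _instances_for_sentences(7, per_sentence=3)
        splits = make_kfold_splits(instances, k=3, seed=5)
        all_test = list(itertools.chain.from_iterable(test for _, test in splits))
        assert sorted(all_test) == list(range(len(instances)))
        for train, test in splits:
            assert not (set(train) & set(test))
            assert sorted(set(train) | set(test)) == list(range(len(instances)))

    def test_sentences_never_straddle_train_and_test(self):
        instances = _instances_for_sentences(9, per_sentence=3)
        for train, test in make_kfold_splits(instances, k=4, seed=1):
            train_sents = {instances[i].sentence_id for i in train}
            test_sents = {instances[i].sentence_id for i in test}
            assert not (train_sents & test_sents)

    def test_same_seed_reproduces_partition(self):
        instances = _instances_for_sentences(12)
        a = make_kfold_splits(instances, k=5, seed=9)
        b = make_kfold_splits(instances, k=5, seed=9)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)

    def test_k_larger_than_corpus_rejected(self):
        with pytest.raises(ValidationError):
            make_kfold_splits(_instances_for_sentences(3), k=10, seed=0)
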