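from __future__ import annotations

import pytest

from gix.ner import DictionaryNer, GeneLexicon, stub_annotate
from gix.refinement import RefinementConfig
from gix.synthetic_fixtures import SimConfig, generate_corpus, generate_prior_kb
from gix.types import SentenceRecord


def make_sentence(
    text: str,
    lexicon_names,
    sentence_id: str = "s1",
    pmid: str = "p1",
    gold_pairs=None,
) -> SentenceRecord:
    """Annotate ``text`` with a dictionary lexicon built from ``lexicon_names``."""
    lexicon = GeneLexicon.from_names(lexicon_names)
    record = SentenceRecord(
        sentence_id=sentence_id,
        pmid=pmid,
        text=text,
        mentions=tuple(stub_annotate(text, lexicon)),
        gold_pairs=gold_pairs,
    )
    record.validate()
    return record


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic study: corpus, prior KB, NER provider, refinement."""
    config = SimConfig()
    corpus = generate_corpus(config)
    kb = generate_prior_kb(corpus.gold_network, config)
    provider = DictionaryNer(corpus.lexicon)
    refinement = RefinementConfig.default(provider)
    return corpus, kb, provider, refinement
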