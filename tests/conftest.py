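import io

import numpy as np
import pytest

from cidrex.corpus_io import Document, Mention, read_pubtator
from cidrex.model import ModelConfig


SMALL_BLOCK = (
    "9|t|A induces B.\n"
    "9|a|Text.\n"
    "9\t0\t1\tA\tChemical\tD000001\n"
    "9\t10\t11\tB\tDisease\tD000002\n"
    "9\tCID\tD000001\tD000002\n"
)


@pytest.fixture
def small_corpus_text():
    return SMALL_BLOCK


@pytest.fixture
def small_doc():
    return read_pubtator(io.StringIO(SMALL_BLOCK))[0]


def make_doc(doc_id, title, abstract, mention_specs, gold=()):
    """mention_specs: (surface, etype, concept_id); offsets located by search
    over title+' '+abstract, each surface found once."""
    text = title + " " + abstract
    mentions = []
    for surface, etype, cid in mention_specs:
        start = text.index(surface)
        mentions.append(
            Mention(start=start, end=start + len(surface), text=surface,
                    etype=etype, concept_id=cid)
        )
    return Document(doc_id=doc_id, title=title, abstract=abstract,
                    mentions=mentions, gold_relations=set(gold))


@pytest.fixture
def tiny_config():
    """A tiny but fully-formed model configuration for fast unit tests."""
    return ModelConfig(l1=6, l2=3, m=4, n1=6, n2=12, window=2, filters=5,
                       h1=4, h2=3, epochs=2, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
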