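import numpy as np
import pytest

from relexplain.brat import (AnnotatedDocument, EntityMention, EquivGroup,
                             RelationAnnotation, read_standoff)
from relexplain.examples import ModelConfig
from relexplain.synth import SynthConfig, generate_corpus
from relexplain.tokenization import WordPieceTokenizer

MINIMAL_TXT = "MDC1 binds APC."
MINIMAL_ANN = (
    "T1\tGene_or_gene_product 0 4\tMDC1\n"
    "T2\tComplex 11 14\tAPC\n"
    "R1\tComplex_formation Arg1:T1 Arg2:T2\n"
)


@pytest.fixture
def minimal_doc():
    return read_standoff(MINIMAL_TXT, MINIMAL_ANN, doc_id="minimal")


@pytest.fixture(scope="session")
def small_corpus():
    docs, gold = generate_corpus(SynthConfig(n_docs=25, seed=42))
    return docs, gold


@pytest.fixture(scope="session")
def small_tokenizer(small_corpus):
    docs, _ = small_corpus
    return WordPieceTokenizer.train([d.text for d in docs], min_word_freq=1)


@pytest.fixture
def protein_doc():
    """Hand-built document: three proteins, one relation, one Equiv alias."""
    text = "AAA1 ( also known as BBB2 ) binds CCC3 . DDD4 is unrelated ."
    doc = AnnotatedDocument(doc_id="prot", text=text)
    for tid, (s, e) in (("T1", (0, 4)), ("T2", (21, 25)), ("T3", (34, 38)), ("T4", (41, 45))):
        doc.entities[tid] = EntityMention(
            id=tid, type="Gene_or_gene_product", start=s, end=e, text=text[s:e]
        )
    doc.relations = [RelationAnnotation(id="R1", type="Complex_formation", arg1="T1", arg2="T3")]
    doc.equiv_groups = [EquivGroup(frozenset(("T1", "T2")))]
    doc.validate()
    return doc


@pytest.fixture
def tiny_model_config():
    return ModelConfig(encoder="tiny-2l-32d", msl=64, learning_rate=3e-3,
                       batch_size=8, epochs=3, seed=0)


def rng(seed=0):
    return np.random.default_rng(seed)
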