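import numpy as np
import pytest

from ddipath.corpus_io import build_instances
from ddipath.encoding import EmbeddingConfig, EmbeddingTables, build_vocab, index_instance
from ddipath.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_sentences=60, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def small_instances(small_corpus):
    return build_instances(small_corpus.sentences, small_corpus.parses)


@pytest.fixture(scope="session")
def small_emb_cfg():
    return EmbeddingConfig(d_word=16, d_pos=4, d_dis=4, clip=10, seed=3)


@pytest.fixture(scope="session")
def small_vocabs(small_instances, small_emb_cfg):
    return build_vocab(small_instances, min_count=small_emb_cfg.min_count,
                       noun_tag=small_emb_cfg.noun_tag)


@pytest.fixture(scope="session")
def small_tables(small_vocabs, small_emb_cfg):
    word_vocab, pos_vocab = small_vocabs
    return EmbeddingTables.initialize(word_vocab, pos_vocab, small_emb_cfg)


@pytest.fixture(scope="session")
def small_indexed(small_instances, small_vocabs, small_emb_cfg):
    word_vocab, pos_vocab = small_vocabs
    return [index_instance(i, word_vocab, pos_vocab, small_emb_cfg)
            for i in small_instances]


def random_tree_tokens(rng: np.random.Generator, n: int):
    """A random dependency tree over n abstract tokens (random recursive tree)."""
    from ddipath.corpus_io import Token
    order = rng.permutation(n)
    heads = {int(order[0]): None}
    for i in order[1:]:
        heads[int(i)] = int(rng.choice([j for j in heads]))
    return [Token(index=i, surface=f"t{i}", lemma=f"t{i}", pos="NN",
                  head=heads[i], deprel=f"r{i}") for i in range(n)]
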