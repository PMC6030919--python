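"""Vocabulary, embedding tables, position features, entity attention and
the five-part segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddipath.corpus_io import PairInstance
from ddipath.encoding import (EmbeddingTables, Vocab, attend,
                              attention_weights, build_vocab, embed_entity,
                              encode_instance, index_instance,
                              load_word_vectors, position_index)


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

def test_vocab_counts_and_min_count(small_instances):
    word_vocab, pos_vocab = build_vocab(small_instances, min_count=1)
    for special in ("drug0", "drug1", "drugn", "<pad>", "<unk>"):
        assert special in word_vocab
    assert "NN" in pos_vocab

    high, _ = build_vocab(small_instances, min_count=10_000)
    # everything below min_count maps to unk, placeholders survive
    assert len(high.itos) == 5  # pad, unk, drug0, drug1, drugn
    assert high.id("w3") == Vocab.unk_id


def test_build_vocab_empty_training_set_is_error():
    with pytest.raises(ValueError):
        build_vocab([], min_count=1)


def test_vocab_serialization_round_trip(tmp_path, small_instances):
    vocab, _ = build_vocab(small_instances, min_count=1)
    vocab.save(tmp_path / "v.json")
    back = Vocab.load(tmp_path / "v.json")
    assert back.itos == vocab.itos
    assert all(back.id(t) == vocab.id(t) for t in vocab.itos)


# ---------------------------------------------------------------------------
# Word vectors
# ---------------------------------------------------------------------------

def test_load_word_vectors_exact_hit_and_reproducible_miss(tmp_path):
    vocab = Vocab(["<pad>", "<unk>", "drug0", "drug1", "drugn", "alpha", "beta"])
    path = tmp_path / "vecs.txt"
    path.write_text("1 4\nalpha 0.5 -1.25 3.0 0.125\n")
    table, hits = load_word_vectors(path, vocab, d_word=4, seed=9)
    assert hits == 1
    np.testing.assert_allclose(table[vocab.id("alpha")], [0.5, -1.25, 3.0, 0.125])
    table2, _ = load_word_vectors(path, vocab, d_word=4, seed=9)
    np.testing.assert_array_equal(table, table2)     # misses are seeded
    table3, _ = load_word_vectors(path, vocab, d_word=4, seed=10)
    assert not np.allclose(table[vocab.id("beta")], table3[vocab.id("beta")])


def test_load_word_vectors_dim_mismatch(tmp_path):
    vocab = Vocab(["<pad>", "<unk>", "x"])
    path = tmp_path / "vecs.txt"
    path.write_text("1 3\nx 1 2 3\n")
    with pytest.raises(ValueError, match="dimension"):
        load_word_vectors(path, vocab, d_word=4)


def test_coverage_counts_vocab_file_intersection(tmp_path):
    vocab = Vocab(["<pad>", "<unk>", "a", "b", "c"])
    path = tmp_path / "vecs.txt"
    path.write_text("3 2\na 1 2\nzz 0 0\nc 3 4\n")
    _, hits = load_word_vectors(path, vocab, d_word=2)
    assert hits == len({"a", "c"})


# ---------------------------------------------------------------------------
# Position features
# ---------------------------------------------------------------------------

def test_position_index_basic_and_clipped():
    assert position_index(5, 5, clip=30) == 30          # distance 0 -> centre row
    assert position_index(50, 5, clip=30) == 60         # +45 clipped to +30
    assert position_index(0, 45, clip=30) == 0          # -45 clipped to -30


@given(st.integers(0, 200), st.integers(0, 200))
@settings(max_examples=200, deadline=None)
def test_position_distance_antisymmetry(i, j):
    clip = 30
    d_ij = position_index(i, j, clip) - clip
    d_ji = position_index(j, i, clip) - clip
    if abs(i - j) <= clip:
        assert d_ij == -d_ji
    else:
        assert d_ij == -np.sign(d_ji) * clip


# ---------------------------------------------------------------------------
# Entity embedding
# ---------------------------------------------------------------------------

def test_embed_entity_is_mean_of_original_word_vectors(small_tables, small_vocabs):
    word_vocab, pos_vocab = small_vocabs
    cfg = small_tables.config
    noun = pos_vocab.id(cfg.noun_tag)
    ids = [word_vocab.id("w1")]
    one = embed_entity(ids, 3, 7, small_tables, noun)
    np.testing.assert_allclose(one[:cfg.d_word], small_tables.word[ids[0]])

    ids2 = [word_vocab.id("w1"), word_vocab.id("w2")]
    two = embed_entity(ids2, 3, 7, small_tables, noun)
    np.testing.assert_allclose(
        two[:cfg.d_word],
        (small_tables.word[ids2[0]] + small_tables.word[ids2[1]]) / 2.0)
    # POS channel is the noun row; dis0 is the zero-distance row
    np.testing.assert_allclose(two[cfg.d_word:cfg.d_word + cfg.d_pos],
                               small_tables.pos[noun])
    np.testing.assert_allclose(
        two[cfg.d_word + cfg.d_pos:cfg.d_word + cfg.d_pos + cfg.d_dis],
        small_tables.dis[position_index(0, 0, cfg.clip)])


def test_oov_entity_mean_is_seed_reproducible(small_vocabs, small_emb_cfg):
    word_vocab, pos_vocab = small_vocabs
    t1 = EmbeddingTables.initialize(word_vocab, pos_vocab, small_emb_cfg)
    t2 = EmbeddingTables.initialize(word_vocab, pos_vocab, small_emb_cfg)
    ids = [Vocab.unk_id] * 3
    noun = pos_vocab.id(small_emb_cfg.noun_tag)
    np.testing.assert_array_equal(embed_entity(ids, 0, 1, t1, noun),
                                  embed_entity(ids, 0, 1, t2, noun))


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def _oracle_softmax(logits):
    e = np.exp(logits - logits.max())
    return e / e.sum()


def test_identical_word_vectors_give_uniform_weights():
    m = 7
    vecs = np.tile([0.3, -0.2, 1.0], (m, 1))
    w = attention_weights(vecs, np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
    np.testing.assert_allclose(w.theta0, np.full(m, 1 / m), atol=1e-12)
    np.testing.assert_allclose(w.theta1, np.full(m, 1 / m), atol=1e-12)
    np.testing.assert_allclose(w.joint, np.full(m, 1 / m), atol=1e-12)


def test_single_token_weight_is_one():
    w = attention_weights(np.array([[2.0, 3.0]]), np.array([1.0, 0]),
                          np.array([0, 1.0]))
    assert w.theta0[0] == 1.0 and w.theta1[0] == 1.0 and w.joint[0] == 1.0


def test_three_token_toy_matches_independent_oracle():
    vecs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    e0, e1 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    w = attention_weights(vecs, e0, e1)
    t0 = _oracle_softmax(vecs @ e0)
    t1 = _oracle_softmax(vecs @ e1)
    np.testing.assert_allclose(w.theta0, t0, atol=1e-10)
    np.testing.assert_allclose(w.theta1, t1, atol=1e-10)
    np.testing.assert_allclose(w.joint, (t0 + t1) / 2, atol=1e-10)


@given(st.integers(3, 20), st.integers(0, 2 ** 31 - 1))
@settings(max_examples=50, deadline=None)
def test_attention_normalization_and_shift_invariance(m, seed):
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((m, 5))
    e0, e1 = rng.standard_normal(5), rng.standard_normal(5)
    w = attention_weights(vecs, e0, e1)
    assert abs(w.theta0.sum() - 1) < 1e-6
    assert abs(w.theta1.sum() - 1) < 1e-6
    assert abs(w.joint.sum() - 1) < 1e-6
    assert (w.theta0 >= 0).all() and (w.theta1 >= 0).all()
    # softmax shift invariance: adding a constant to every logit via a
    # shifted entity direction component along a constant offset
    w2 = attention_weights(np.hstack([vecs, np.ones((m, 1))]),
                           np.append(e0, 5.0), np.append(e1, 5.0))
    np.testing.assert_allclose(w.joint, w2.joint, atol=1e-8)


def test_attend_scales_full_vector_by_joint_weight():
    rng = np.random.default_rng(0)
    z = rng.standard_normal((4, 6))
    vecs = rng.standard_normal((4, 3))
    w = attention_weights(vecs, rng.standard_normal(3), rng.standard_normal(3))
    out = attend(z, w)
    # independent accumulation loop
    for j in range(6):
        expected = sum(w.joint[i] * z[i, j] for i in range(4))
        assert abs(out[:, j].sum() - expected) < 1e-10
    uniform = attention_weights(np.ones((4, 3)), np.ones(3), np.ones(3))
    np.testing.assert_allclose(attend(z, uniform), z / 4.0)


def test_attend_length_mismatch_is_error():
    w = attention_weights(np.ones((3, 2)), np.ones(2), np.ones(2))
    with pytest.raises(ValueError):
        attend(np.ones((4, 5)), w)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def test_segmentation_partition_on_synthetic_instances(small_indexed, small_tables):
    for idx in small_indexed:
        enc = encode_instance(idx, small_tables)
        total = (len(enc.sub0) + len(enc.sub1) + len(enc.sub2) + 2)
        assert total == idx.n_tokens
        assert enc.sdp.shape[0] >= 2
        # no position is duplicated or dropped
        claimed = set(idx.sub0) | set(idx.sub1) | set(idx.sub2)
        claimed |= {idx.e0_index, idx.e1_index}
        assert claimed == set(range(idx.n_tokens))


def test_boundary_segments_are_empty_without_error(small_vocabs, small_emb_cfg,
                                                   small_tables):
    word_vocab, pos_vocab = small_vocabs
    d = {
        "sentence_id": "sX", "pair_id": "pX", "label": "Advice",
        "tokens": [
            {"surface": "drug0", "lemma": "drug0", "pos": "NN", "head": 1, "deprel": "nsubj"},
            {"surface": "drug1", "lemma": "drug1", "pos": "NN", "head": None, "deprel": "root"},
            {"surface": "w1", "lemma": "w1", "pos": "NN", "head": 1, "deprel": "dobj"},
        ],
        "e0": {"id": "e0", "type": "drug", "index": 0, "orig_words": ["a"]},
        "e1": {"id": "e1", "type": "drug", "index": 1, "orig_words": ["b"]},
        "sdp": [0, 1],
    }
    inst = PairInstance.from_dict(d)
    idx = index_instance(inst, word_vocab, pos_vocab, small_emb_cfg)
    enc = encode_instance(idx, small_tables)
    assert enc.sub0.shape[0] == 0      # entity-initial sentence
    assert enc.sub1.shape[0] == 0      # adjacent entities
    assert enc.sub2.shape[0] == 1


def test_encode_is_deterministic(small_indexed, small_tables):
    a = encode_instance(small_indexed[0], small_tables)
    b = encode_instance(small_indexed[0], small_tables)
    np.testing.assert_array_equal(a.sdp, b.sdp)
    np.testing.assert_array_equal(a.ent0, b.ent0)


def test_encoded_token_width_matches_config(small_indexed, small_tables):
    cfg = small_tables.config
    enc = encode_instance(small_indexed[0], small_tables)
    assert enc.sdp.shape[1] == cfg.d_token
    assert enc.ent0.shape == (cfg.d_token,)


def test_excluded_surfaces_leave_sdp_intact(small_instances, small_vocabs,
                                            small_emb_cfg):
    word_vocab, pos_vocab = small_vocabs
    positives = [i for i in small_instances if i.label != "Negative"]
    triggers = frozenset({"advise", "potentiate", "inhibit", "interact"})
    for inst in positives:
        idx = index_instance(inst, word_vocab, pos_vocab, small_emb_cfg,
                             exclude_surfaces=triggers)
        surfaces_in_subs = {inst.tokens[p].surface
                            for p in (*idx.sub0, *idx.sub1, *idx.sub2)}
        assert not (surfaces_in_subs & triggers)
        sdp_surfaces = {inst.tokens[p].surface for p in idx.sdp_positions}
        # on-path triggers stay visible to the SDP branch
        if sdp_surfaces & triggers:
            assert len(idx.sdp_word_ids) == len(idx.sdp_positions)
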