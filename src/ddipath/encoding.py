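"""Embedding-level input encoding for the hierarchical extractor.

Each token is represented by four concatenated channels: a word vector, a
POS-tag vector, and two position vectors indexed by the signed, clipped
token distance to the two targeted drug entities — 230 dimensions with the
defaults (200 + 10 + 2*10).  A targeted entity is represented by the
arithmetic mean of the word vectors of its original mention words, a noun
POS row, and its own position rows.

Entity attention assigns every token a scalar weight: the softmax (over the
sequence) of the dot product between the token's word vector and each
entity's word vector, averaged over the two entities; the weight scales the
token's full 230-dim vector.  The sentence sequence and the SDP sequence are
each normalized independently over their own length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (PLACEHOLDER_E0, PLACEHOLDER_E1, PLACEHOLDER_OTHER,
                        LABELS, PairInstance)

PAD = "<pad>"
UNK = "<unk>"
PLACEHOLDERS = (PLACEHOLDER_E0, PLACEHOLDER_E1, PLACEHOLDER_OTHER)


class Vocab:
    """Token <-> id mapping with reserved pad (0) and unk (1) slots."""

    def __init__(self, itos: list[str]):
        if itos[:2] != [PAD, UNK]:
            raise ValueError("vocabulary must start with the pad and unk symbols")
        self.itos = list(itos)
        self.stoi = {tok: i for i, tok in enumerate(self.itos)}
        if len(self.stoi) != len(self.itos):
            raise ValueError("duplicate tokens in vocabulary")

    pad_id = 0
    unk_id = 1

    def __len__(self) -> int:
        return len(self.itos)

    def __contains__(self, token: str) -> bool:
        return token in self.stoi

    def id(self, token: str) -> int:
        return self.stoi.get(token, self.unk_id)

    @classmethod
    def from_counts(cls, counts: dict[str, int], min_count: int = 1,
                    specials: tuple[str, ...] = ()) -> "Vocab":
        itos = [PAD, UNK, *specials]
        reserved = set(itos)
        for tok in sorted(counts):
            if tok not in reserved and counts[tok] >= min_count:
                itos.append(tok)
        return cls(itos)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.itos), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocab":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))


def build_vocab(instances: list[PairInstance], min_count: int = 1,
                noun_tag: str = "NN") -> tuple[Vocab, Vocab]:
    """Word and POS vocabularies from training instances.

    Placeholder surfaces are always in-vocabulary; the configured noun tag
    is forced into the POS vocabulary because collapsed entity tokens use it.
    """
    if not instances:
        raise ValueError("cannot build a vocabulary from an empty training set")
    word_counts: dict[str, int] = {}
    pos_counts: dict[str, int] = {}
    for inst in instances:
        for tok in inst.tokens:
            word_counts[tok.surface] = word_counts.get(tok.surface, 0) + 1
            pos_counts[tok.pos] = pos_counts.get(tok.pos, 0) + 1
        for word in inst.e0.orig_words + inst.e1.orig_words:
            word_counts[word] = word_counts.get(word, 0) + 1
    word_vocab = Vocab.from_counts(word_counts, min_count, specials=PLACEHOLDERS)
    pos_vocab = Vocab.from_counts(pos_counts, 1, specials=(noun_tag,))
    return word_vocab, pos_vocab


# ---------------------------------------------------------------------------
# Embedding tables
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingConfig:
    d_word: int = 200
    d_pos: int = 10
    d_dis: int = 10
    clip: int = 30
    min_count: int = 1
    noun_tag: str = "NN"
    seed: int = 0

    @property
    def d_token(self) -> int:
        return self.d_word + self.d_pos + 2 * self.d_dis

    @property
    def n_positions(self) -> int:
        # one row per clipped signed distance plus a dedicated pad row
        return 2 * self.clip + 2

    @property
    def pad_distance_id(self) -> int:
        return 2 * self.clip + 1


@dataclass
class EmbeddingTables:
    """Initial (pre-training) embedding matrices."""

    word: np.ndarray
    pos: np.ndarray
    dis: np.ndarray
    config: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    @classmethod
    def initialize(cls, word_vocab: Vocab, pos_vocab: Vocab,
                   config: EmbeddingConfig,
                   word_init: np.ndarray | None = None) -> "EmbeddingTables":
        rng = np.random.default_rng(config.seed)
        word = rng.standard_normal((len(word_vocab), config.d_word)) * 0.1
        pos = rng.standard_normal((len(pos_vocab), config.d_pos)) * 0.1
        # position vectors drawn from a standard normal
        dis = rng.standard_normal((config.n_positions, config.d_dis))
        word[Vocab.pad_id] = 0.0
        pos[Vocab.pad_id] = 0.0
        dis[config.pad_distance_id] = 0.0
        if word_init is not None:
            if word_init.shape != word.shape:
                raise ValueError("pretrained word table shape mismatch")
            word = word_init.copy()
            word[Vocab.pad_id] = 0.0
        return cls(word=word, pos=pos, dis=dis, config=config)


def load_word_vectors(path: str | Path, vocab: Vocab, d_word: int,
                      seed: int = 0) -> tuple[np.ndarray, int]:
    """Load word2vec-text vectors for a vocabulary.

    Tokens present in the file get the file vector; every other row
    (placeholders included) is drawn from a seeded standard normal scaled
    by 0.1, so absent-token rows are reproducible for a given seed and
    vocabulary.  Returns the table and the number of in-vocabulary tokens
    covered by the file.
    """
    rng = np.random.default_rng(seed)
    table = rng.standard_normal((len(vocab), d_word)) * 0.1
    table[Vocab.pad_id] = 0.0
    hits = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec text file must start with 'count dim' header")
        file_dim = int(header[1])
        if file_dim != d_word:
            raise ValueError(f"vector dimension {file_dim} != configured d_word {d_word}")
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            token = parts[0]
            if token in vocab:
                table[vocab.id(token)] = np.asarray(parts[1:], dtype=np.float64)
                hits += 1
    return table, hits


def position_index(i: int, ent_token: int, clip: int = 30) -> int:
    """Row id of the signed distance i - ent_token, clipped to [-clip, clip]."""
    d = max(-clip, min(clip, i - ent_token))
    return d + clip


# ---------------------------------------------------------------------------
# Attention (reference NumPy implementation; the model mirrors this math)
# ---------------------------------------------------------------------------

@dataclass
class AttentionWeights:
    theta0: np.ndarray
    theta1: np.ndarray

    @property
    def joint(self) -> np.ndarray:
        return 0.5 * (self.theta0 + self.theta1)


def attention_weights(word_vectors: np.ndarray, ent0_vec: np.ndarray,
                      ent1_vec: np.ndarray) -> AttentionWeights:
    """Per-token relevance to each entity: softmax over the sequence of
    word-vector dot products, numerically stabilized."""
    word_vectors = np.asarray(word_vectors)
    if word_vectors.ndim != 2 or word_vectors.shape[0] == 0:
        raise ValueError("word_vectors must be a nonempty (m, d) matrix")

    def softmax(logits: np.ndarray) -> np.ndarray:
        z = np.exp(logits - logits.max())
        return z / z.sum()

    return AttentionWeights(theta0=softmax(word_vectors @ ent0_vec),
                            theta1=softmax(word_vectors @ ent1_vec))


def attend(z: np.ndarray, weights: AttentionWeights) -> np.ndarray:
    """Scale each full token vector by its joint attention weight."""
    z = np.asarray(z)
    joint = weights.joint
    if z.shape[0] != joint.shape[0]:
        raise ValueError(f"{z.shape[0]} token vectors but {joint.shape[0]} weights")
    return joint[:, None] * z


def embed_entity(orig_word_ids: list[int], own_index: int, other_index: int,
                 tables: EmbeddingTables, noun_pos_id: int) -> np.ndarray:
    """Entity channel vector: mean of the original mention-word vectors,
    the noun POS row (entity POS is fixed to noun by convention), distance 0
    to itself and the signed distance to the other entity."""
    cfg = tables.config
    word = tables.word[np.asarray(orig_word_ids)].mean(axis=0)
    pos = tables.pos[noun_pos_id]
    dis0 = tables.dis[position_index(0, 0, cfg.clip)]
    dis1 = tables.dis[position_index(own_index, other_index, cfg.clip)]
    return np.concatenate([word, pos, dis0, dis1])


# ---------------------------------------------------------------------------
# Indexed and encoded instances
# ---------------------------------------------------------------------------

@dataclass
class IndexedInstance:
    """Purely numeric view of a pair instance, ready for batching.

    The SDP is carried as its own token sequence (ids re-gathered from the
    sentence, optionally interleaved with dependency-relation pseudo-tokens)
    because its attention is normalized independently of the sentence.
    """

    pair_id: str
    label_id: int
    n_tokens: int
    word_ids: np.ndarray        # (m,)
    pos_ids: np.ndarray         # (m,)
    dis0_ids: np.ndarray        # (m,)
    dis1_ids: np.ndarray        # (m,)
    e0_index: int
    e1_index: int
    sub0: np.ndarray            # token positions before e0
    sub1: np.ndarray            # token positions strictly between
    sub2: np.ndarray            # token positions after e1
    sdp_positions: np.ndarray   # sentence positions of SDP nodes (for reference)
    sdp_word_ids: np.ndarray
    sdp_pos_ids: np.ndarray
    sdp_dis0_ids: np.ndarray
    sdp_dis1_ids: np.ndarray
    ent0_word_ids: np.ndarray   # original mention-word ids
    ent1_word_ids: np.ndarray
    ent0_dis: tuple[int, int]   # (dis0 id, dis1 id) for the e0 slot
    ent1_dis: tuple[int, int]
    noun_pos_id: int


def index_instance(inst: PairInstance, word_vocab: Vocab, pos_vocab: Vocab,
                   config: EmbeddingConfig,
                   exclude_surfaces: frozenset[str] = frozenset(),
                   sdp_include_relations: bool = False) -> IndexedInstance:
    """Map an anonymized pair instance to id arrays.

    ``exclude_surfaces`` confines the given surfaces to the dependency-path
    branch: they are dropped from the three linear subsequences and blinded
    to the unknown id in the sentence-level channels (so they cannot leak
    through the attention normalization), while the SDP sequence keeps
    their real ids.
    """
    if inst.sdp is None:
        from . import dep_sdp
        graph = dep_sdp.build_graph(inst.tokens)
        inst.sdp = list(dep_sdp.shortest_path(
            graph, inst.e0.token_span[0], inst.e1.token_span[0]).node_indices)
    m = len(inst.tokens)
    e0, e1 = inst.e0.token_span[0], inst.e1.token_span[0]
    clip = config.clip
    raw_word_ids = np.array([word_vocab.id(t.surface) for t in inst.tokens],
                            dtype=np.int64)
    word_ids = raw_word_ids.copy()
    if exclude_surfaces:
        for i, tok in enumerate(inst.tokens):
            if tok.surface in exclude_surfaces:
                word_ids[i] = word_vocab.unk_id
    pos_ids = np.array([pos_vocab.id(t.pos) for t in inst.tokens], dtype=np.int64)
    dis0 = np.array([position_index(i, e0, clip) for i in range(m)], dtype=np.int64)
    dis1 = np.array([position_index(i, e1, clip) for i in range(m)], dtype=np.int64)

    def keep(i: int) -> bool:
        return inst.tokens[i].surface not in exclude_surfaces

    sub0 = np.array([i for i in range(0, e0) if keep(i)], dtype=np.int64)
    sub1 = np.array([i for i in range(e0 + 1, e1) if keep(i)], dtype=np.int64)
    sub2 = np.array([i for i in range(e1 + 1, m) if keep(i)], dtype=np.int64)

    sdp_pos = list(inst.sdp)
    sdp_word, sdp_postag, sdp_d0, sdp_d1 = [], [], [], []
    if sdp_include_relations:
        from . import dep_sdp
        graph = dep_sdp.build_graph(inst.tokens)
        path = dep_sdp.shortest_path(graph, e0, e1)
        seq: list[tuple[str, int | None]] = []
        for k, node in enumerate(path.node_indices):
            seq.append((inst.tokens[node].surface, node))
            if k < len(path.relations):
                seq.append((f"<rel:{path.relations[k]}>", None))
        for surface, node in seq:
            sdp_word.append(word_vocab.id(surface))
            if node is None:
                sdp_postag.append(Vocab.pad_id)
                sdp_d0.append(config.pad_distance_id)
                sdp_d1.append(config.pad_distance_id)
            else:
                sdp_postag.append(int(pos_ids[node]))
                sdp_d0.append(int(dis0[node]))
                sdp_d1.append(int(dis1[node]))
    else:
        for node in sdp_pos:
            sdp_word.append(int(raw_word_ids[node]))
            sdp_postag.append(int(pos_ids[node]))
            sdp_d0.append(int(dis0[node]))
            sdp_d1.append(int(dis1[node]))

    noun_id = pos_vocab.id(config.noun_tag)
    ent0_words = [word_vocab.id(w) for w in inst.e0.orig_words] or [word_vocab.unk_id]
    ent1_words = [word_vocab.id(w) for w in inst.e1.orig_words] or [word_vocab.unk_id]
    return IndexedInstance(
        pair_id=inst.pair_id,
        label_id=LABELS.index(inst.label),
        n_tokens=m,
        word_ids=word_ids, pos_ids=pos_ids, dis0_ids=dis0, dis1_ids=dis1,
        e0_index=e0, e1_index=e1,
        sub0=sub0, sub1=sub1, sub2=sub2,
        sdp_positions=np.array(sdp_pos, dtype=np.int64),
        sdp_word_ids=np.array(sdp_word, dtype=np.int64),
        sdp_pos_ids=np.array(sdp_postag, dtype=np.int64),
        sdp_dis0_ids=np.array(sdp_d0, dtype=np.int64),
        sdp_dis1_ids=np.array(sdp_d1, dtype=np.int64),
        ent0_word_ids=np.array(ent0_words, dtype=np.int64),
        ent1_word_ids=np.array(ent1_words, dtype=np.int64),
        ent0_dis=(position_index(0, 0, clip), position_index(e0, e1, clip)),
        ent1_dis=(position_index(0, 0, clip), position_index(e1, e0, clip)),
        noun_pos_id=noun_id,
    )


@dataclass
class EncodedInstance:
    """Attended embedding matrices for the five sentence parts plus the SDP."""

    sub0: np.ndarray
    ent0: np.ndarray
    sub1: np.ndarray
    ent1: np.ndarray
    sub2: np.ndarray
    sdp: np.ndarray
    label_id: int


def encode_instance(idx: IndexedInstance, tables: EmbeddingTables) -> EncodedInstance:
    """Reference (non-differentiable) full encode of one instance.

    Mirrors the model's embedding/attention/segmentation math exactly and is
    used for desk checks and the segmentation partition property.
    """
    cfg = tables.config
    word = tables.word[idx.word_ids]                      # (m, d_word)
    z = np.concatenate([word,
                        tables.pos[idx.pos_ids],
                        tables.dis[idx.dis0_ids],
                        tables.dis[idx.dis1_ids]], axis=1)
    ent0_word = tables.word[idx.ent0_word_ids].mean(axis=0)
    ent1_word = tables.word[idx.ent1_word_ids].mean(axis=0)
    w = attention_weights(word, ent0_word, ent1_word)
    z_att = attend(z, w)

    def ent_slot(ent_word, dis_ids, own_pos):
        vec = np.concatenate([ent_word,
                              tables.pos[idx.noun_pos_id],
                              tables.dis[dis_ids[0]],
                              tables.dis[dis_ids[1]]])
        return w.joint[own_pos] * vec

    sdp_word = tables.word[idx.sdp_word_ids]
    z_sdp = np.concatenate([sdp_word,
                            tables.pos[idx.sdp_pos_ids],
                            tables.dis[idx.sdp_dis0_ids],
                            tables.dis[idx.sdp_dis1_ids]], axis=1)
    w_sdp = attention_weights(sdp_word, ent0_word, ent1_word)
    return EncodedInstance(
        sub0=z_att[idx.sub0] if len(idx.sub0) else np.zeros((0, cfg.d_token)),
        ent0=ent_slot(ent0_word, idx.ent0_dis, idx.e0_index),
        sub1=z_att[idx.sub1] if len(idx.sub1) else np.zeros((0, cfg.d_token)),
        ent1=ent_slot(ent1_word, idx.ent1_dis, idx.e1_index),
        sub2=z_att[idx.sub2] if len(idx.sub2) else np.zeros((0, cfg.d_token)),
        sdp=attend(z_sdp, w_sdp),
        label_id=idx.label_id,
    )
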