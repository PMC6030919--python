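"""Hierarchical bidirectional recurrent extractor.

Architecture: the anonymized sentence is split into five parts around the
two targeted drug tokens (subsequence 0, e0, subsequence 1, e1,
subsequence 2).  A bottom bidirectional recurrent encoder (shared by the
three subsequences by default) and a second one for the shortest dependency
path each reduce an attended embedding matrix to the concatenation of their
final forward/backward hidden states.  The two entity embedding vectors are
linearly projected to the same width.  A top bidirectional encoder reads the
six resulting slot vectors in order [sub0, e0, sub1, e1, sub2, SDP] and its
final states feed a softmax classifier over the five relation classes.

Training minimizes mean cross-entropy with RMSProp; dropout is applied to
the embedding-level outputs (default rate 0.7) and to the top representation
before the classifier (default 0.5), at train time only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ag
from .autodiff import Tensor
from .corpus_io import LABELS
from .encoding import EmbeddingConfig, EmbeddingTables, IndexedInstance, Vocab


@dataclass
class ModelConfig:
    bottom_hidden: int = 100
    top_hidden: int = 100
    cell: str = "lstm"  # lstm | gru | simple
    n_classes: int = 5
    dropout_embed: float = 0.7
    dropout_output: float = 0.5
    share_bottom_across_subsequences: bool = True
    entity_projection: bool = True
    bottom_pooling: str = "final"  # final | max
    ablate_sdp: bool = False

    def __post_init__(self):
        if self.cell not in ("lstm", "gru", "simple"):
            raise ValueError(f"unknown cell type {self.cell!r}")
        if not (0 <= self.dropout_embed < 1 and 0 <= self.dropout_output < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.bottom_hidden <= 0 or self.top_hidden <= 0:
            raise ValueError("hidden sizes must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    rho: float = 0.9
    eps: float = 1e-7

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# Recurrent cells
# ---------------------------------------------------------------------------

class _Cell:
    """One direction of a recurrent encoder; subclasses define the gating."""

    n_state = 1

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator, prefix: str):
        self.h = d_hidden
        g = self.n_gates(d_hidden)
        self.W = ag.parameter(_glorot(rng, (d_in, g)))
        self.U = ag.parameter(_glorot(rng, (d_hidden, g)))
        self.b = ag.parameter(self._bias_init(d_hidden))
        self.prefix = prefix

    def params(self) -> dict[str, Tensor]:
        return {f"{self.prefix}.W": self.W, f"{self.prefix}.U": self.U,
                f"{self.prefix}.b": self.b}

    @staticmethod
    def n_gates(h: int) -> int:
        raise NotImplementedError

    def _bias_init(self, h: int) -> np.ndarray:
        return np.zeros(self.n_gates(h))

    def init_state(self, batch: int) -> tuple[Tensor, ...]:
        return tuple(ag.zeros((batch, self.h)) for _ in range(self.n_state))

    def input_proj(self, x2d: Tensor) -> Tensor:
        # gate bias folded in here so the recurrent step stays lean
        return ag.matmul(x2d, self.W) + self.b

    def step(self, xw_t: Tensor, state: tuple) -> tuple:
        """Advance one step; `xw_t` is the bias-included input projection."""
        raise NotImplementedError


class LSTMCell(_Cell):
    n_state = 2  # (h, c)

    @staticmethod
    def n_gates(h: int) -> int:
        return 4 * h

    def _bias_init(self, h: int) -> np.ndarray:
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget-gate bias
        return b

    def step(self, xw_t, state):
        h_prev, c_prev = state
        pre = xw_t + ag.matmul(h_prev, self.U)
        H = self.h
        i = ag.sigmoid(pre[:, 0 * H:1 * H])
        f = ag.sigmoid(pre[:, 1 * H:2 * H])
        g = ag.tanh(pre[:, 2 * H:3 * H])
        o = ag.sigmoid(pre[:, 3 * H:4 * H])
        c = f * c_prev + i * g
        h = o * ag.tanh(c)
        return (h, c)


class GRUCell(_Cell):
    @staticmethod
    def n_gates(h: int) -> int:
        return 3 * h

    def step(self, xw_t, state):
        (h_prev,) = state
        hU = ag.matmul(h_prev, self.U)
        pre = xw_t
        H = self.h
        z = ag.sigmoid(pre[:, 0 * H:1 * H] + hU[:, 0 * H:1 * H])
        r = ag.sigmoid(pre[:, 1 * H:2 * H] + hU[:, 1 * H:2 * H])
        n = ag.tanh(pre[:, 2 * H:3 * H] + r * hU[:, 2 * H:3 * H])
        h = (1.0 - z) * n + z * h_prev
        return (h,)


class SimpleCell(_Cell):
    @staticmethod
    def n_gates(h: int) -> int:
        return h

    def step(self, xw_t, state):
        (h_prev,) = state
        h = ag.tanh(xw_t + ag.matmul(h_prev, self.U))
        return (h,)


_CELLS = {"lstm": LSTMCell, "gru": GRUCell, "simple": SimpleCell}


class BiEncoder:
    """Bidirectional recurrent encoder reducing (B, L, D) to (B, 2H)."""

    def __init__(self, d_in: int, d_hidden: int, cell: str,
                 rng: np.random.Generator, prefix: str, pooling: str = "final"):
        cls = _CELLS[cell]
        self.fwd = cls(d_in, d_hidden, rng, f"{prefix}.fwd")
        self.bwd = cls(d_in, d_hidden, rng, f"{prefix}.bwd")
        self.h = d_hidden
        self.pooling = pooling

    def params(self) -> dict[str, Tensor]:
        return {**self.fwd.params(), **self.bwd.params()}

    def _run(self, cell: _Cell, xw3, mask: np.ndarray, order) -> Tensor:
        B, L = mask.shape
        state = cell.init_state(B)
        pooled = None
        for t in order:
            new_state = cell.step(xw3[:, t, :], state)
            m = ag.constant(mask[:, t:t + 1])
            state = tuple(ns * m + s * (1.0 - m) for ns, s in zip(new_state, state))
            if self.pooling == "max":
                visible = state[0] * m + ag.constant(
                    np.full((B, 1), -1e9, dtype=np.float32)) * (1.0 - m)
                pooled = visible if pooled is None else ag.maximum(pooled, visible)
        if self.pooling == "max" and pooled is not None:
            any_tok = (mask.sum(axis=1, keepdims=True) > 0).astype(np.float32)
            return pooled * ag.constant(any_tok)
        return state[0]

    def encode(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L = mask.shape
        if L == 0:
            return ag.zeros((B, 2 * self.h))
        D = x.shape[2]
        x2d = ag.reshape(x, (B * L, D))
        out = []
        for cell, order in ((self.fwd, range(L)), (self.bwd, range(L - 1, -1, -1))):
            xw3 = ag.reshape(cell.input_proj(x2d), (B, L, cell.n_gates(self.h)))
            out.append(self._run(cell, xw3, mask, order))
        return ag.concat(out, axis=1)

    def _run_packed(self, cell: _Cell, xw3, order, counts: np.ndarray) -> Tensor:
        """Recurrence over length-sorted rows: at step t only the prefix of
        rows whose sequence extends past t is advanced; final pooling only."""
        R = xw3.shape[0]
        state = cell.init_state(R)
        for t in order:
            k = int(counts[t])
            if k == 0:
                continue
            if k == R:
                state = cell.step(xw3[:, t, :], state)
            else:
                active = cell.step(xw3[:k, t, :], tuple(s[:k] for s in state))
                state = tuple(ag.concat([a, s[k:]], axis=0)
                              for a, s in zip(active, state))
        return state[0]

    def encode_packed(self, z_pack: Tensor, rows: np.ndarray, cols: np.ndarray,
                      shape: tuple[int, int], lengths: np.ndarray) -> Tensor:
        """Encode ragged sequences given as packed token rows.

        ``z_pack`` holds the real token vectors (N, D); token k belongs to
        sequence ``rows[k]`` at step ``cols[k]``.  Sequences must be sorted
        by decreasing length; ``lengths`` gives the sorted lengths.  Returns
        (R, 2H) final-state concatenations (zero rows for empty sequences).
        Supports final-state pooling only.
        """
        R, L = shape
        if L == 0 or z_pack.shape[0] == 0:
            return ag.zeros((R, 2 * self.h))
        counts = (lengths[:, None] > np.arange(L)[None, :]).sum(axis=0)
        out = []
        for cell, order in ((self.fwd, range(L)), (self.bwd, range(L - 1, -1, -1))):
            xw3 = ag.scatter_rows(cell.input_proj(z_pack), rows, cols, shape)
            out.append(self._run_packed(cell, xw3, order, counts))
        return ag.concat(out, axis=1)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

def _pad2(arrs: list[np.ndarray], pad_value: int) -> tuple[np.ndarray, np.ndarray]:
    L = max((len(a) for a in arrs), default=0)
    out = np.full((len(arrs), L), pad_value, dtype=np.int64)
    mask = np.zeros((len(arrs), L), dtype=np.float32)
    for i, a in enumerate(arrs):
        out[i, :len(a)] = a
        mask[i, :len(a)] = 1.0
    return out, mask


def collate(instances: list[IndexedInstance], emb_cfg: EmbeddingConfig) -> dict:
    """Pad a list of indexed instances into dense batch arrays."""
    pad_d = emb_cfg.pad_distance_id
    batch: dict = {"n": len(instances)}
    batch["labels"] = np.array([x.label_id for x in instances], dtype=np.int64)
    batch["pair_ids"] = [x.pair_id for x in instances]

    batch["sent_word"], batch["sent_mask"] = _pad2([x.word_ids for x in instances], 0)

    for name in ("sub0", "sub1", "sub2"):
        positions = [getattr(x, name) for x in instances]
        pos_padded, mask = _pad2(positions, 0)
        seg = {"mask": mask, "positions": pos_padded}
        for ch, src, pad in (("word", "word_ids", 0), ("pos", "pos_ids", 0),
                             ("dis0", "dis0_ids", pad_d), ("dis1", "dis1_ids", pad_d)):
            seg[ch], _ = _pad2([getattr(x, src)[p] for x, p in zip(instances, positions)], pad)
        batch[name] = seg

    # the three subsequences stacked along the batch axis (3B ragged rows,
    # sorted by decreasing length) so a shared bottom encoder can process
    # the real tokens in one packed call
    B = len(instances)
    all_pos = ([x.sub0 for x in instances] + [x.sub1 for x in instances]
               + [x.sub2 for x in instances])
    lengths = np.array([len(p) for p in all_pos], dtype=np.int64)
    perm = np.argsort(-lengths, kind="stable")
    inv_perm = np.argsort(perm)
    lengths_sorted = lengths[perm]
    rows = np.repeat(np.arange(len(all_pos)), lengths_sorted)
    cols = np.concatenate([np.arange(n) for n in lengths_sorted]) if rows.size \
        else np.zeros(0, dtype=np.int64)
    combined = {
        "rows": rows, "cols": cols,
        "shape": (len(all_pos), int(lengths_sorted[0]) if len(all_pos) else 0),
        "lengths_sorted": lengths_sorted, "inv_perm": inv_perm,
    }
    triple = instances * 3

    def packed(src: str) -> np.ndarray:
        parts = [getattr(triple[r], src)[all_pos[r]] for r in perm]
        return (np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64))

    combined["word"] = packed("word_ids")
    combined["pos"] = packed("pos_ids")
    combined["dis0"] = packed("dis0_ids")
    combined["dis1"] = packed("dis1_ids")
    combined["joint_rows"] = np.repeat(perm % B, lengths_sorted)
    combined["joint_cols"] = (np.concatenate([all_pos[r] for r in perm])
                              if rows.size else np.zeros(0, dtype=np.int64))
    batch["subs_combined"] = combined

    sdp = {}
    sdp["word"], sdp["mask"] = _pad2([x.sdp_word_ids for x in instances], 0)
    sdp["pos"], _ = _pad2([x.sdp_pos_ids for x in instances], 0)
    sdp["dis0"], _ = _pad2([x.sdp_dis0_ids for x in instances], pad_d)
    sdp["dis1"], _ = _pad2([x.sdp_dis1_ids for x in instances], pad_d)
    batch["sdp"] = sdp

    for k, (ids_attr, dis_attr, pos_attr) in {
        "ent0": ("ent0_word_ids", "ent0_dis", "e0_index"),
        "ent1": ("ent1_word_ids", "ent1_dis", "e1_index"),
    }.items():
        ids, mask = _pad2([getattr(x, ids_attr) for x in instances], 0)
        batch[k] = {
            "word_ids": ids, "mask": mask,
            "dis": np.array([getattr(x, dis_attr) for x in instances], dtype=np.int64),
            "position": np.array([getattr(x, pos_attr) for x in instances], dtype=np.int64),
        }
    batch["noun_pos_id"] = instances[0].noun_pos_id
    return batch


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class HierarchicalExtractor:
    """Hierarchical bidirectional recurrent DDI extractor."""

    def __init__(self, model_cfg: ModelConfig, emb_cfg: EmbeddingConfig,
                 word_vocab: Vocab, pos_vocab: Vocab, seed: int = 0,
                 word_init: np.ndarray | None = None):
        self.cfg = model_cfg
        self.emb_cfg = emb_cfg
        self.word_vocab = word_vocab
        self.pos_vocab = pos_vocab
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed))

        tables = EmbeddingTables.initialize(word_vocab, pos_vocab, emb_cfg, word_init)
        self.word_table = ag.parameter(tables.word)
        self.pos_table = ag.parameter(tables.pos)
        self.dis_table = ag.parameter(tables.dis)

        d_tok = emb_cfg.d_token
        bh, th = model_cfg.bottom_hidden, model_cfg.top_hidden
        n_sub = 1 if model_cfg.share_bottom_across_subsequences else 3
        self.sub_encoders = [BiEncoder(d_tok, bh, model_cfg.cell, rng, f"sub{i}",
                                       model_cfg.bottom_pooling)
                             for i in range(n_sub)]
        self.sdp_encoder = BiEncoder(d_tok, bh, model_cfg.cell, rng, "sdp",
                                     model_cfg.bottom_pooling)
        if model_cfg.entity_projection:
            self.ent_W = ag.parameter(_glorot(rng, (d_tok, 2 * bh)))
            self.ent_b = ag.parameter(np.zeros(2 * bh))
        elif d_tok != 2 * bh:
            raise ValueError("entity_projection=false requires d_token == 2*bottom_hidden")
        self.top_encoder = BiEncoder(2 * bh, th, model_cfg.cell, rng, "top")
        self.head_W = ag.parameter(_glorot(rng, (2 * th, model_cfg.n_classes)))
        self.head_b = ag.parameter(np.zeros(model_cfg.n_classes))

    # -- parameter registry ------------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        named = {"emb.word": self.word_table, "emb.pos": self.pos_table,
                 "emb.dis": self.dis_table}
        for i, enc in enumerate(self.sub_encoders):
            named.update(enc.params())
        named.update(self.sdp_encoder.params())
        named.update(self.top_encoder.params())
        if self.cfg.entity_projection:
            named["ent.W"] = self.ent_W
            named["ent.b"] = self.ent_b
        named["head.W"] = self.head_W
        named["head.b"] = self.head_b
        return named

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    # -- forward -------------------------------------------------------------
    def _masked_softmax(self, logits: Tensor, mask: np.ndarray) -> Tensor:
        shift = ag.constant(logits.data.max(axis=1, keepdims=True))
        e = ag.exp(logits - shift) * ag.constant(mask)
        denom = ag.tsum(e, axis=1, keepdims=True)
        return ag.div(e, denom)

    def _entity_word_mean(self, ent: dict) -> Tensor:
        vecs = ag.embedding(self.word_table, ent["word_ids"])        # (B, l, d)
        m = ag.constant(ent["mask"][:, :, None])
        total = ag.tsum(vecs * m, axis=1)
        counts = ag.constant(ent["mask"].sum(axis=1, keepdims=True))
        return ag.div(total, counts)

    def _segment_z(self, seg: dict) -> Tensor:
        return ag.concat([
            ag.embedding(self.word_table, seg["word"]),
            ag.embedding(self.pos_table, seg["pos"]),
            ag.embedding(self.dis_table, seg["dis0"]),
            ag.embedding(self.dis_table, seg["dis1"]),
        ], axis=2)

    def forward(self, batch: dict, train: bool = False,
                rng: np.random.Generator | None = None,
                return_aux: bool = False):
        cfg = self.cfg
        drop = cfg.dropout_embed if train else 0.0
        if train and rng is None:
            raise ValueError("training forward pass needs an RNG for dropout")

        B = batch["n"]
        sent_mask = batch["sent_mask"]
        sent_wv = ag.embedding(self.word_table, batch["sent_word"])   # (B, M, dw)

        ent0_w = self._entity_word_mean(batch["ent0"])                # (B, dw)
        ent1_w = self._entity_word_mean(batch["ent1"])

        def attn_joint(word_vecs: Tensor, mask: np.ndarray) -> Tensor:
            t0 = self._masked_softmax(
                ag.tsum(word_vecs * ag.reshape(ent0_w, (B, 1, -1)), axis=2), mask)
            t1 = self._masked_softmax(
                ag.tsum(word_vecs * ag.reshape(ent1_w, (B, 1, -1)), axis=2), mask)
            return (t0 + t1) * 0.5                                    # (B, M)

        joint = attn_joint(sent_wv, sent_mask)
        joint3 = ag.reshape(joint, (B, joint.shape[1], 1))

        def encode_sub(seg: dict, encoder: BiEncoder, weights: Tensor) -> Tensor:
            if seg["mask"].shape[1] == 0:
                return ag.zeros((seg["mask"].shape[0], 2 * cfg.bottom_hidden))
            z = self._segment_z(seg)
            w = ag.batch_gather(weights, seg["positions"])            # (B, L, 1)
            z = z * (w * ag.constant(seg["mask"][:, :, None]))
            z = ag.dropout(z, drop, rng, train)
            return encoder.encode(z, seg["mask"])

        subs = self.sub_encoders
        if len(subs) == 1 and cfg.bottom_pooling == "final":
            # one packed call over the real tokens of the 3B stacked rows
            c = batch["subs_combined"]
            z_pack = ag.concat([
                ag.embedding(self.word_table, c["word"]),
                ag.embedding(self.pos_table, c["pos"]),
                ag.embedding(self.dis_table, c["dis0"]),
                ag.embedding(self.dis_table, c["dis1"]),
            ], axis=1)
            w_pack = ag.gather2d(joint, c["joint_rows"], c["joint_cols"])
            z_pack = z_pack * ag.reshape(w_pack, (-1, 1))
            z_pack = ag.dropout(z_pack, drop, rng, train)
            v_sorted = subs[0].encode_packed(z_pack, c["rows"], c["cols"],
                                             c["shape"], c["lengths_sorted"])
            v_all = v_sorted[c["inv_perm"]]
            v_sub0 = v_all[0 * B:1 * B]
            v_sub1 = v_all[1 * B:2 * B]
            v_sub2 = v_all[2 * B:3 * B]
        else:
            v_sub0 = encode_sub(batch["sub0"], subs[0], joint3)
            v_sub1 = encode_sub(batch["sub1"], subs[1], joint3)
            v_sub2 = encode_sub(batch["sub2"], subs[2], joint3)

        # SDP: its own embedding sequence with independently normalized attention
        sdp = batch["sdp"]
        sdp_wv = ag.embedding(self.word_table, sdp["word"])
        joint_sdp = attn_joint(sdp_wv, sdp["mask"])
        z_sdp = ag.concat([
            sdp_wv,
            ag.embedding(self.pos_table, sdp["pos"]),
            ag.embedding(self.dis_table, sdp["dis0"]),
            ag.embedding(self.dis_table, sdp["dis1"]),
        ], axis=2)
        z_sdp = z_sdp * (ag.reshape(joint_sdp, (B, -1, 1))
                         * ag.constant(sdp["mask"][:, :, None]))
        z_sdp = ag.dropout(z_sdp, drop, rng, train)
        v_sdp = self.sdp_encoder.encode(z_sdp, sdp["mask"])
        if cfg.ablate_sdp:
            v_sdp = v_sdp * 0.0

        def ent_slot(ent: dict, ent_word: Tensor) -> Tensor:
            noun = ag.embedding(self.pos_table,
                                np.full(B, batch["noun_pos_id"], dtype=np.int64))
            d0 = ag.embedding(self.dis_table, ent["dis"][:, 0])
            d1 = ag.embedding(self.dis_table, ent["dis"][:, 1])
            z_e = ag.concat([ent_word, noun, d0, d1], axis=1)         # (B, 230)
            w = ag.reshape(ag.batch_gather(joint3, ent["position"][:, None]), (B, 1))
            z_e = z_e * w
            z_e = ag.dropout(z_e, drop, rng, train)
            if cfg.entity_projection:
                return ag.matmul(z_e, self.ent_W) + self.ent_b
            return z_e

        v_e0 = ent_slot(batch["ent0"], ent0_w)
        v_e1 = ent_slot(batch["ent1"], ent1_w)

        slots = ag.stack([v_sub0, v_e0, v_sub1, v_e1, v_sub2, v_sdp], axis=1)
        s = self.top_encoder.encode(slots, np.ones((B, 6), dtype=np.float32))
        s = ag.dropout(s, cfg.dropout_output if train else 0.0, rng, train)
        logits = ag.matmul(s, self.head_W) + self.head_b
        if return_aux:
            return logits, {"joint": joint.data.copy(),
                            "joint_sdp": joint_sdp.data.copy(),
                            "s": s.data.copy()}
        return logits

    # -- persistence ---------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "params.npz",
                 **{k: v.data for k, v in self.named_parameters().items()})
        meta = {"model": asdict(self.cfg), "embedding": asdict(self.emb_cfg),
                "seed": self.seed, "labels": list(LABELS)}
        (out / "config.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
        self.word_vocab.save(out / "vocab.json")
        self.pos_vocab.save(out / "pos_vocab.json")

    @classmethod
    def load(cls, in_dir: str | Path) -> "HierarchicalExtractor":
        src = Path(in_dir)
        meta = json.loads((src / "config.json").read_text(encoding="utf-8"))
        model = cls(ModelConfig(**meta["model"]), EmbeddingConfig(**meta["embedding"]),
                    Vocab.load(src / "vocab.json"), Vocab.load(src / "pos_vocab.json"),
                    seed=meta["seed"])
        with np.load(src / "params.npz") as data:
            for name, tensor in model.named_parameters().items():
                tensor.data = data[name].astype(ag.DTYPE)
        return model


# ---------------------------------------------------------------------------
# Classification helpers, training loop, inference
# ---------------------------------------------------------------------------

def classify(s: np.ndarray, W_o: np.ndarray, b_o: np.ndarray) -> np.ndarray:
    """Softmax(W_o·s + b_o) for a single representation or a batch."""
    logits = np.atleast_2d(s) @ W_o.T + b_o
    z = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = z / z.sum(axis=1, keepdims=True)
    return probs[0] if np.asarray(s).ndim == 1 else probs


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


def predict(model: HierarchicalExtractor, instances: list[IndexedInstance],
            batch_size: int = 64) -> tuple[list[str], np.ndarray]:
    """Deterministic inference (dropout disabled): labels and class probabilities."""
    probs = []
    for i in range(0, len(instances), batch_size):
        batch = collate(instances[i:i + batch_size], model.emb_cfg)
        logits = model.forward(batch, train=False)
        probs.append(_softmax_rows(logits.data))
    probs = np.concatenate(probs, axis=0) if probs else np.zeros((0, model.cfg.n_classes))
    labels = [LABELS[i] for i in probs.argmax(axis=1)]
    return labels, probs


def fit(model: HierarchicalExtractor, train_instances: list[IndexedInstance],
        dev_instances: list[IndexedInstance] | None,
        train_cfg: TrainConfig, verbose: bool = False) -> list[dict]:
    """Mini-batch RMSProp training; keeps the best-dev-micro-F parameters.

    Returns the per-epoch log (mean loss and, when a dev set is given, dev
    micro-F over the four positive classes).
    """
    from .evaluation import score  # deferred to avoid an import cycle

    ss = np.random.SeedSequence(train_cfg.seed)
    shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    opt = ag.RMSProp(model.parameters(), lr=train_cfg.learning_rate,
                     rho=train_cfg.rho, eps=train_cfg.eps)
    log: list[dict] = []
    best_f = -1.0
    best_params: dict[str, np.ndarray] | None = None

    dev_gold = None
    if dev_instances:
        dev_gold = {x.pair_id: LABELS[x.label_id] for x in dev_instances}

    n = len(train_instances)
    for epoch in range(train_cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            chunk = [train_instances[j] for j in order[start:start + train_cfg.batch_size]]
            batch = collate(chunk, model.emb_cfg)
            logits = model.forward(batch, train=True, rng=drop_rng)
            loss = ag.softmax_cross_entropy(logits, batch["labels"])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss in epoch {epoch}, batch starting at {start}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if dev_instances:
            pred_labels, _ = predict(model, dev_instances, train_cfg.batch_size)
            preds = {x.pair_id: lab for x, lab in zip(dev_instances, pred_labels)}
            report = score(preds, dev_gold)
            entry["dev_micro_f"] = report.micro["f"]
            if report.micro["f"] > best_f:
                best_f = report.micro["f"]
                best_params = {k: v.data.copy()
                               for k, v in model.named_parameters().items()}
        log.append(entry)
        if verbose:
            print(json.dumps(entry))
    if best_params is not None:
        for k, v in model.named_parameters().items():
            v.data = best_params[k]
    return log
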