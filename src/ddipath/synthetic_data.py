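"""Desk-scale synthetic corpora with a planted, SDP-localized class signal.

Each generated sentence contains two drug-name tokens joined by a random
dependency tree.  For a positive relation class, a class-specific trigger
lemma is planted on the dependency path between the two drug tokens (with
probability ``p_trigger_on_sdp``; otherwise it hangs off the path as a
leaf).  Negative sentences carry no trigger on the path — by default no
trigger at all, optionally an off-path decoy.  Because the label is a
deterministic function of the trigger, a correct preprocessing + model
pipeline can recover it, and confining the trigger to the dependency-path
branch isolates the contribution of the SDP encoder.

Class priors default to a Negative-dominant mix mirroring the strong class
imbalance of real pharmacological corpora.  The generator emits the same
artifacts a real study would consume: an annotated XML corpus with character
offsets, a CoNLL-U parse file, and a gold label list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (LABELS, POSITIVE_LABELS, EntityMention,
                        SentenceAnnotation, Token, write_corpus_xml)

_FILLER_POS = ("NN", "JJ", "RB", "DT", "IN")
_PATH_DEPRELS = ("nsubj", "dobj", "nmod")
_LEAF_DEPRELS = ("amod", "det", "case", "advmod", "conj", "obl")


def default_trigger_map() -> dict[str, str]:
    return {"Advice": "advise", "Effect": "potentiate",
            "Mechanism": "inhibit", "Int": "interact"}


@dataclass
class SyntheticSpec:
    n_sentences: int = 2000
    vocab_size: int = 120
    max_len: int = 25
    class_priors: tuple[float, ...] = (0.8, 0.05, 0.05, 0.05, 0.05)  # LABELS order
    trigger_map: dict[str, str] = field(default_factory=default_trigger_map)
    p_trigger_on_sdp: float = 1.0
    p_decoy_trigger: float = 0.0   # off-path trigger in Negative sentences
    p_extra_entity: float = 0.15   # third, non-targeted drug mention
    seed: int = 7

    def __post_init__(self):
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if self.max_len < 6:
            raise ValueError("max_len must be >= 6 to fit entities, trigger and path")
        triggers = list(self.trigger_map.values())
        if len(set(triggers)) != len(POSITIVE_LABELS):
            raise ValueError("trigger lemmas must be distinct, one per positive class")


@dataclass
class GeneratedCorpus:
    xml_path: Path | None
    conllu_path: Path | None
    sentences: list[SentenceAnnotation]
    parses: dict[str, list[Token]]
    gold: list[dict]


def _build_sentence(spec: SyntheticSpec, rng: np.random.Generator,
                    sid: str, label: str) -> tuple[SentenceAnnotation, list[Token]]:
    length = int(rng.integers(6, spec.max_len + 1))
    positions = list(rng.permutation(length))
    e0_pos, e1_pos = sorted(positions[:2])
    cursor = 2

    def next_pos() -> int:
        nonlocal cursor
        p = positions[cursor]
        cursor += 1
        return int(p)

    surfaces = [None] * length
    pos_tags = [None] * length
    heads: dict[int, int | None] = {}
    deprels: dict[int, str] = {}
    drug_pool = rng.choice(30, size=3, replace=False)
    surfaces[e0_pos], surfaces[e1_pos] = f"cpd{drug_pool[0]}", f"cpd{drug_pool[1]}"
    pos_tags[e0_pos] = pos_tags[e1_pos] = "NN"

    trigger_pos = None
    on_path = False
    if label != "Negative":
        trigger_pos = next_pos()
        surfaces[trigger_pos] = spec.trigger_map[label]
        pos_tags[trigger_pos] = "VB"
        on_path = rng.random() < spec.p_trigger_on_sdp
    elif rng.random() < spec.p_decoy_trigger:
        trigger_pos = next_pos()
        surfaces[trigger_pos] = spec.trigger_map[
            POSITIVE_LABELS[int(rng.integers(len(POSITIVE_LABELS)))]]
        pos_tags[trigger_pos] = "VB"

    placed: list[int]
    if on_path:
        # entity -- trigger -- entity chain, optionally one more interior filler
        interior = [trigger_pos]
        if rng.random() < 0.5:
            extra = next_pos()
            surfaces[extra] = f"w{int(rng.integers(spec.vocab_size))}"
            pos_tags[extra] = str(rng.choice(_FILLER_POS))
            interior.append(extra)
            heads[extra] = trigger_pos
            deprels[extra] = str(rng.choice(_PATH_DEPRELS))
        heads[interior[0]] = None
        deprels[interior[0]] = "root"
        heads[e0_pos] = interior[0]
        deprels[e0_pos] = str(rng.choice(_PATH_DEPRELS))
        heads[e1_pos] = interior[-1]
        deprels[e1_pos] = str(rng.choice(_PATH_DEPRELS))
        placed = [interior[0], e0_pos, e1_pos] + interior[1:]
    else:
        # connector filler joins the two entities; any trigger hangs off as a leaf
        connector = next_pos()
        surfaces[connector] = f"w{int(rng.integers(spec.vocab_size))}"
        pos_tags[connector] = str(rng.choice(_FILLER_POS))
        heads[connector] = None
        deprels[connector] = "root"
        heads[e0_pos] = connector
        deprels[e0_pos] = str(rng.choice(_PATH_DEPRELS))
        heads[e1_pos] = connector
        deprels[e1_pos] = str(rng.choice(_PATH_DEPRELS))
        placed = [connector, e0_pos, e1_pos]
        if trigger_pos is not None:
            heads[trigger_pos] = int(rng.choice(placed))
            deprels[trigger_pos] = str(rng.choice(_LEAF_DEPRELS))
            placed.append(trigger_pos)

    extra_entity_pos = None
    if rng.random() < spec.p_extra_entity and cursor < length:
        extra_entity_pos = next_pos()
        surfaces[extra_entity_pos] = f"cpd{drug_pool[2]}"
        pos_tags[extra_entity_pos] = "NN"
        heads[extra_entity_pos] = int(rng.choice(placed))
        deprels[extra_entity_pos] = str(rng.choice(_LEAF_DEPRELS))
        placed.append(extra_entity_pos)

    while cursor < length:
        p = next_pos()
        surfaces[p] = f"w{int(rng.integers(spec.vocab_size))}"
        pos_tags[p] = str(rng.choice(_FILLER_POS))
        heads[p] = int(rng.choice(placed))
        deprels[p] = str(rng.choice(_LEAF_DEPRELS))
        placed.append(p)

    text = " ".join(surfaces)
    offsets = []
    start = 0
    for s in surfaces:
        offsets.append((start, start + len(s)))
        start += len(s) + 1
    tokens = [Token(index=i, surface=surfaces[i], lemma=surfaces[i], pos=pos_tags[i],
                    head=heads[i], deprel=deprels[i],
                    char_start=offsets[i][0], char_end=offsets[i][1])
              for i in range(length)]

    entities = [
        EntityMention(id=f"{sid}.e0", type="drug", text=surfaces[e0_pos],
                      char_start=offsets[e0_pos][0], char_end=offsets[e0_pos][1]),
        EntityMention(id=f"{sid}.e1", type="drug", text=surfaces[e1_pos],
                      char_start=offsets[e1_pos][0], char_end=offsets[e1_pos][1]),
    ]
    if extra_entity_pos is not None:
        entities.append(EntityMention(
            id=f"{sid}.e2", type="drug", text=surfaces[extra_entity_pos],
            char_start=offsets[extra_entity_pos][0],
            char_end=offsets[extra_entity_pos][1]))
    pairs = [(f"{sid}.p0", f"{sid}.e0", f"{sid}.e1", label)]
    return SentenceAnnotation(sid, text, entities, pairs), tokens


def generate(spec: SyntheticSpec, out_dir: str | Path | None = None) -> GeneratedCorpus:
    """Generate a corpus; optionally write corpus.xml / parses.conllu / gold.jsonl."""
    rng = np.random.default_rng(spec.seed)
    sentences: list[SentenceAnnotation] = []
    parses: dict[str, list[Token]] = {}
    gold: list[dict] = []
    labels = list(LABELS)
    draws = rng.choice(len(labels), size=spec.n_sentences, p=list(spec.class_priors))
    for i in range(spec.n_sentences):
        sid = f"synth.s{i}"
        label = labels[int(draws[i])]
        sent, tokens = _build_sentence(spec, rng, sid, label)
        sentences.append(sent)
        parses[sid] = tokens
        gold.append({"pair_id": f"{sid}.p0", "label": label})

    xml_path = conllu_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        xml_path = out / "corpus.xml"
        conllu_path = out / "parses.conllu"
        write_corpus_xml(sentences, xml_path, document_id="synth")
        write_conllu(parses, conllu_path, texts={s.sentence_id: s.text for s in sentences})
        with open(out / "gold.jsonl", "w", encoding="utf-8") as fh:
            for rec in gold:
                fh.write(json.dumps(rec) + "\n")
    return GeneratedCorpus(xml_path, conllu_path, sentences, parses, gold)


def write_conllu(parses: dict[str, list[Token]], path: str | Path,
                 texts: dict[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, tokens in parses.items():
            fh.write(f"# sent_id = {sid}\n")
            if texts and sid in texts:
                fh.write(f"# text = {texts[sid]}\n")
            for t in tokens:
                head1 = 0 if t.head is None else t.head + 1
                fh.write("\t".join([str(t.index + 1), t.surface, t.lemma, t.pos, "_",
                                    "_", str(head1), t.deprel, "_", "_"]) + "\n")
            fh.write("\n")


def make_toy_vectors(tokens: list[str], dim: int, seed: int,
                     trigger_lemmas: list[str], path: str | Path) -> Path:
    """Write a word2vec-text file over `tokens`.

    Trigger lemmas receive exactly orthogonal dense sign patterns (tiled
    Hadamard rows with entries ±0.125, so pairwise dot products cancel
    exactly in floating point); every other token gets a seeded random
    vector.  Dense trigger directions keep the class signal visible under
    heavy embedding dropout.
    """
    if dim % 4 != 0:
        raise ValueError("dim must be a multiple of 4 for the orthogonal triggers")
    if len(trigger_lemmas) > 4:
        raise ValueError("at most 4 orthogonal trigger directions are constructed")
    h4 = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]])
    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {dim}\n")
        for tok in tokens:
            if tok in trigger_lemmas:
                row = np.tile(h4[trigger_lemmas.index(tok)], dim // 4) * 0.125
            else:
                row = rng.standard_normal(dim) * 0.1
            fh.write(tok + " " + " ".join(f"{v:.6f}" for v in row) + "\n")
    return path
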