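"""Corpus I/O: annotated DDI XML, CoNLL-U parses, and pair instances.

The corpus dialect is the one used by the DDIExtraction-2013 shared task:
``document`` elements contain ``sentence`` elements carrying the sentence
text, ``entity`` children with inclusive character offsets ("a-b", possibly
";"-separated for discontinuous mentions), and ``pair`` children referencing
two entity ids with ``ddi="true|false"`` plus a ``type`` when true.
Dependency parses arrive separately as CoNLL-U keyed by sentence id.

This module aligns character offsets to tokens, builds one labelled
:class:`PairInstance` per ``pair`` element, and blinds drug mentions:
the two targeted entities become single ``drug0``/``drug1`` placeholder
tokens (multi-token mentions are collapsed onto the span token closest to
the root, keeping the parse a tree) and, optionally, any other drug mention
in the sentence becomes ``drugn``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)

LABELS = ("Negative", "Advice", "Effect", "Mechanism", "Int")
POSITIVE_LABELS = LABELS[1:]

PLACEHOLDER_E0 = "drug0"
PLACEHOLDER_E1 = "drug1"
PLACEHOLDER_OTHER = "drugn"


class CorpusError(ValueError):
    """Hard error while reading or assembling corpus data."""


@dataclass
class Token:
    """One token of a dependency-parsed sentence.

    ``head`` is a 0-based token index, or ``None`` for the root.
    Character offsets are 0-based half-open into the sentence text and are
    ``None`` once anonymization has invalidated them.
    """

    index: int
    surface: str
    lemma: str
    pos: str
    head: int | None
    deprel: str
    char_start: int | None = None
    char_end: int | None = None


@dataclass
class EntityMention:
    id: str
    type: str
    text: str
    char_start: int | None = None
    char_end: int | None = None  # half-open
    token_span: tuple[int, int] | None = None  # inclusive token index range
    orig_words: list[str] = field(default_factory=list)


@dataclass
class SentenceAnnotation:
    sentence_id: str
    text: str
    entities: list[EntityMention]
    # (pair_id, e1_id, e2_id, label)
    pairs: list[tuple[str, str, str, str]]


@dataclass
class PairInstance:
    """One candidate drug pair in one sentence.

    After :func:`anonymize`, ``tokens`` are the blinded sentence with both
    targeted entities collapsed to single placeholder tokens; ``e0`` precedes
    ``e1`` in token order and each retains the original mention words in
    ``orig_words`` (needed for the averaged entity embedding).
    """

    sentence_id: str
    pair_id: str
    tokens: list[Token]
    e0: EntityMention
    e1: EntityMention
    label: str
    sdp: list[int] | None = None

    def to_dict(self) -> dict:
        return {
            "sentence_id": self.sentence_id,
            "pair_id": self.pair_id,
            "label": self.label,
            "tokens": [
                {"surface": t.surface, "lemma": t.lemma, "pos": t.pos,
                 "head": t.head, "deprel": t.deprel}
                for t in self.tokens
            ],
            "e0": {"id": self.e0.id, "type": self.e0.type,
                   "index": self.e0.token_span[0], "orig_words": self.e0.orig_words},
            "e1": {"id": self.e1.id, "type": self.e1.type,
                   "index": self.e1.token_span[0], "orig_words": self.e1.orig_words},
            "sdp": self.sdp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairInstance":
        tokens = [
            Token(index=i, surface=t["surface"], lemma=t["lemma"], pos=t["pos"],
                  head=t["head"], deprel=t["deprel"])
            for i, t in enumerate(d["tokens"])
        ]

        def ent(e):
            return EntityMention(id=e["id"], type=e["type"], text=" ".join(e["orig_words"]),
                                 token_span=(e["index"], e["index"]),
                                 orig_words=list(e["orig_words"]))

        return cls(sentence_id=d["sentence_id"], pair_id=d["pair_id"], tokens=tokens,
                   e0=ent(d["e0"]), e1=ent(d["e1"]), label=d["label"], sdp=d.get("sdp"))


# ---------------------------------------------------------------------------
# XML corpus
# ---------------------------------------------------------------------------

def _parse_char_offset(raw: str, entity_id: str) -> tuple[int, int]:
    """Inclusive "a-b" (possibly ';'-joined) -> 0-based half-open span."""
    spans = raw.split(";")
    if len(spans) > 1:
        warnings.warn(
            f"entity {entity_id}: discontinuous charOffset {raw!r}; keeping first span",
            stacklevel=3,
        )
    a, b = spans[0].split("-")
    return int(a), int(b) + 1


def parse_corpus_xml(path: str | Path) -> list[SentenceAnnotation]:
    """Read one annotated corpus file into sentence annotations."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message path
        raise CorpusError(f"malformed XML in {path}: {exc}") from exc
    sentences = []
    for sent in tree.iter("sentence"):
        sid = sent.get("id")
        text = sent.get("text", "")
        entities: list[EntityMention] = []
        by_id: dict[str, EntityMention] = {}
        for ent in sent.iter("entity"):
            eid = ent.get("id")
            start, end = _parse_char_offset(ent.get("charOffset"), eid)
            mention = EntityMention(id=eid, type=ent.get("type", "drug"),
                                    text=ent.get("text", text[start:end]),
                                    char_start=start, char_end=end)
            entities.append(mention)
            by_id[eid] = mention
        for a in entities:
            for b in entities:
                if a.id < b.id and a.char_start < b.char_end and b.char_start < a.char_end:
                    warnings.warn(
                        f"sentence {sid}: overlapping entities {a.id}/{b.id}; both kept",
                        stacklevel=2,
                    )
        pairs = []
        for pair in sent.iter("pair"):
            pid, e1, e2 = pair.get("id"), pair.get("e1"), pair.get("e2")
            for eid in (e1, e2):
                if eid not in by_id:
                    raise CorpusError(
                        f"pair {pid} in sentence {sid} references unknown entity {eid}")
            if pair.get("ddi", "false").lower() == "true":
                label = pair.get("type", "Int").capitalize()
                if label not in LABELS:
                    raise CorpusError(f"pair {pid}: unknown DDI type {pair.get('type')!r}")
            else:
                label = "Negative"
            pairs.append((pid, e1, e2, label))
        sentences.append(SentenceAnnotation(sid, text, entities, pairs))
    return sentences


def write_corpus_xml(sentences: list[SentenceAnnotation], path: str | Path,
                     document_id: str = "d0") -> None:
    """Serialize sentence annotations back to the XML dialect."""
    root = etree.Element("document", id=document_id)
    for sent in sentences:
        s = etree.SubElement(root, "sentence", id=sent.sentence_id, text=sent.text)
        for ent in sent.entities:
            etree.SubElement(
                s, "entity", id=ent.id, type=ent.type, text=ent.text,
                charOffset=f"{ent.char_start}-{ent.char_end - 1}")
        for pid, e1, e2, label in sent.pairs:
            attrs = {"id": pid, "e1": e1, "e2": e2}
            if label == "Negative":
                attrs["ddi"] = "false"
            else:
                attrs["ddi"] = "true"
                attrs["type"] = label.lower()
            etree.SubElement(s, "pair", **attrs)
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)


def parse_corpus_dir(xml_dir: str | Path) -> list[SentenceAnnotation]:
    """Read every ``*.xml`` file in a directory (sorted by name)."""
    sentences: list[SentenceAnnotation] = []
    for path in sorted(Path(xml_dir).glob("*.xml")):
        sentences.extend(parse_corpus_xml(path))
    return sentences


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

def read_conllu(path: str | Path) -> dict[str, list[Token]]:
    """Read CoNLL-U parses keyed by ``# sent_id``.

    Multiword-token ranges ("3-4") and empty nodes ("3.1") are skipped;
    1-based heads become 0-based with the root mapped to ``None``.  When a
    ``# text`` comment is present, token character offsets are recovered by
    scanning that text left to right.
    """
    parses: dict[str, list[Token]] = {}
    sent_id: str | None = None
    text: str | None = None
    rows: list[tuple] = []

    def flush():
        nonlocal rows, sent_id, text
        if sent_id is None and not rows:
            rows = []
            text = None
            return
        if sent_id is None:
            raise CorpusError(f"{path}: sentence block without a sent_id comment")
        tokens: list[Token] = []
        for new_index, (form, lemma, upos, head1, deprel) in enumerate(rows):
            head = None if head1 == 0 else head1 - 1
            tokens.append(Token(index=new_index, surface=form, lemma=lemma,
                                pos=upos, head=head, deprel=deprel))
        if text is not None:
            cursor = 0
            for tok in tokens:
                pos = text.find(tok.surface, cursor)
                if pos >= 0:
                    tok.char_start, tok.char_end = pos, pos + len(tok.surface)
                    cursor = pos + len(tok.surface)
        _check_tree(tokens, sent_id)
        parses[sent_id] = tokens
        rows = []
        sent_id = None
        text = None

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                flush()
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sent_id"):
                    sent_id = body.split("=", 1)[1].strip()
                elif body.startswith("text"):
                    text = body.split("=", 1)[1].strip()
                continue
            cols = line.split("\t")
            tid = cols[0]
            if "-" in tid or "." in tid:
                continue  # multiword range / empty node
            form, lemma, upos = cols[1], cols[2], cols[3]
            head1 = int(cols[6])
            deprel = cols[7]
            rows.append((form, lemma, upos, head1, deprel))
    flush()
    return parses


def _check_tree(tokens: list[Token], sent_id: str) -> None:
    roots = [t for t in tokens if t.head is None]
    if len(roots) != 1:
        raise CorpusError(f"sentence {sent_id}: {len(roots)} roots (expected 1)")
    for tok in tokens:
        seen = set()
        cur = tok
        while cur.head is not None:
            if cur.index in seen:
                raise CorpusError(f"sentence {sent_id}: cyclic head structure at "
                                  f"token {tok.index}")
            seen.add(cur.index)
            cur = tokens[cur.head]


# ---------------------------------------------------------------------------
# Offset alignment and anonymization
# ---------------------------------------------------------------------------

def align_offsets(sentence_text: str, entities: list[EntityMention],
                  tokens: list[Token], sentence_id: str = "?") -> list[EntityMention]:
    """Resolve each entity's character span to the minimal covering token span."""
    resolved = []
    for ent in entities:
        covering = [t.index for t in tokens
                    if t.char_start is not None
                    and t.char_end > ent.char_start and t.char_start < ent.char_end]
        if not covering:
            raise CorpusError(
                f"sentence {sentence_id}: entity {ent.id} offsets "
                f"[{ent.char_start},{ent.char_end}) not covered by any token")
        span = (min(covering), max(covering))
        resolved.append(replace(ent, token_span=span,
                                orig_words=[tokens[i].surface
                                            for i in range(span[0], span[1] + 1)]))
    return resolved


def _collapse_span(tokens: list[Token], span: tuple[int, int],
                   placeholder: str, noun_tag: str = "NN") -> tuple[list[Token], int]:
    """Collapse the inclusive token span onto a single placeholder token.

    The surviving node is the span token closest to the root, which
    guarantees the contracted structure is still a tree; heads pointing
    anywhere into the span are redirected to it.  Returns the new token
    list and the placeholder's new index.
    """
    a, b = span
    in_span = set(range(a, b + 1))

    def depth(i: int) -> int:
        d = 0
        while tokens[i].head is not None:
            i = tokens[i].head
            d += 1
        return d

    keep = min(in_span, key=depth)
    head_of_span = tokens[keep].head
    deprel_of_span = tokens[keep].deprel

    index_map: dict[int, int] = {}
    new_tokens: list[Token] = []
    for tok in tokens:
        if tok.index in in_span and tok.index != a:
            index_map[tok.index] = a  # merged into the placeholder slot
            continue
        new_index = len(new_tokens)
        index_map[tok.index] = new_index
        new_tokens.append(tok)
    # all span members map to the placeholder's slot
    for i in in_span:
        index_map[i] = index_map[a]

    out: list[Token] = []
    for tok in new_tokens:
        if tok.index == a:
            head = None if head_of_span is None else index_map[head_of_span]
            out.append(Token(index=index_map[a], surface=placeholder,
                             lemma=placeholder, pos=noun_tag, head=head,
                             deprel=deprel_of_span))
        else:
            head = tok.head
            if head is not None:
                head = index_map[head] if head not in in_span else index_map[a]
            out.append(Token(index=index_map[tok.index], surface=tok.surface,
                             lemma=tok.lemma, pos=tok.pos, head=head,
                             deprel=tok.deprel))
    return out, index_map[a]


def anonymize(instance: PairInstance, other_entities: list[EntityMention] = (),
              anonymize_others: bool = True, noun_tag: str = "NN") -> PairInstance:
    """Blind drug mentions: e0 -> drug0, e1 -> drug1, others -> drugn.

    Both targeted spans are collapsed to single tokens; other drug mentions
    keep their token count but have every surface replaced.  Character
    offsets are invalidated.
    """
    tokens = [replace(t, char_start=None, char_end=None) for t in instance.tokens]

    if anonymize_others:
        targeted = set(range(instance.e0.token_span[0], instance.e0.token_span[1] + 1))
        targeted |= set(range(instance.e1.token_span[0], instance.e1.token_span[1] + 1))
        for ent in other_entities:
            if ent.token_span is None:
                continue
            for i in range(ent.token_span[0], ent.token_span[1] + 1):
                if i not in targeted:
                    tokens[i] = replace(tokens[i], surface=PLACEHOLDER_OTHER,
                                        lemma=PLACEHOLDER_OTHER)

    # collapse the later span first so the earlier span's indices stay valid
    tokens, e1_idx = _collapse_span(tokens, instance.e1.token_span,
                                    PLACEHOLDER_E1, noun_tag)
    tokens, e0_idx = _collapse_span(tokens, instance.e0.token_span,
                                    PLACEHOLDER_E0, noun_tag)
    # collapsing e0 removed (b0 - a0) tokens, all of them before e1's slot
    e1_idx -= instance.e0.token_span[1] - instance.e0.token_span[0]
    _check_tree(tokens, instance.sentence_id)

    e0 = replace(instance.e0, token_span=(e0_idx, e0_idx),
                 char_start=None, char_end=None)
    e1 = replace(instance.e1, token_span=(e1_idx, e1_idx),
                 char_start=None, char_end=None)
    return replace(instance, tokens=tokens, e0=e0, e1=e1)


# ---------------------------------------------------------------------------
# Instance assembly
# ---------------------------------------------------------------------------

def build_instances(sentences: list[SentenceAnnotation],
                    parses: dict[str, list[Token]],
                    anonymize_others: bool = True,
                    noun_tag: str = "NN",
                    attach_sdp: bool = True) -> list[PairInstance]:
    """Assemble one anonymized :class:`PairInstance` per pair element."""
    from . import dep_sdp  # local import to avoid a cycle

    missing = [s.sentence_id for s in sentences if s.pairs and s.sentence_id not in parses]
    if missing:
        raise CorpusError(f"no CoNLL-U parse for sentence ids: {', '.join(missing)}")

    instances: list[PairInstance] = []
    for sent in sentences:
        if not sent.pairs:
            continue
        tokens = parses[sent.sentence_id]
        if tokens and tokens[0].char_start is None:
            _assign_offsets_from_text(sent.text, tokens)
        entities = align_offsets(sent.text, sent.entities, tokens, sent.sentence_id)
        by_id = {e.id: e for e in entities}
        for pid, e1_id, e2_id, label in sent.pairs:
            first, second = by_id[e1_id], by_id[e2_id]
            if first.token_span[0] > second.token_span[0]:
                first, second = second, first
            others = [e for e in entities if e.id not in (e1_id, e2_id)]
            inst = PairInstance(sentence_id=sent.sentence_id, pair_id=pid,
                                tokens=tokens, e0=first, e1=second, label=label)
            inst = anonymize(inst, others, anonymize_others=anonymize_others,
                             noun_tag=noun_tag)
            if attach_sdp:
                graph = dep_sdp.build_graph(inst.tokens)
                path = dep_sdp.shortest_path(graph, inst.e0.token_span[0],
                                             inst.e1.token_span[0])
                inst.sdp = list(path.node_indices)
            instances.append(inst)
    return instances


def _assign_offsets_from_text(text: str, tokens: list[Token]) -> None:
    cursor = 0
    for tok in tokens:
        pos = text.find(tok.surface, cursor)
        if pos < 0:
            raise CorpusError(f"token {tok.surface!r} not found in sentence text")
        tok.char_start, tok.char_end = pos, pos + len(tok.surface)
        cursor = pos + len(tok.surface)


# ---------------------------------------------------------------------------
# JSONL instance records
# ---------------------------------------------------------------------------

def write_instances_jsonl(instances: list[PairInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(json.dumps(inst.to_dict()) + "\n")


def read_instances_jsonl(path: str | Path) -> list[PairInstance]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(PairInstance.from_dict(json.loads(line)))
    return out
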