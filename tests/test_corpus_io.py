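"""Corpus reading, offset alignment, anonymization and round-trips."""

import textwrap

import pytest

from ddipath.corpus_io import (CorpusError, EntityMention, PairInstance, Token,
                               align_offsets, anonymize, build_instances,
                               parse_corpus_xml, read_conllu,
                               read_instances_jsonl, write_corpus_xml,
                               write_instances_jsonl)
from ddipath.synthetic_data import SyntheticSpec, generate

XML_ONE = """<?xml version='1.0' encoding='UTF-8'?>
<document id="d1">
  <sentence id="d1.s0" text="aspirin may reduce warfarin effect">
    <entity id="d1.s0.e0" type="drug" text="aspirin" charOffset="0-6"/>
    <entity id="d1.s0.e1" type="drug" text="warfarin" charOffset="19-26"/>
    <pair id="d1.s0.p0" e1="d1.s0.e0" e2="d1.s0.e1" ddi="false"/>
  </sentence>
</document>
"""


def test_parse_single_negative_pair(tmp_path):
    path = tmp_path / "one.xml"
    path.write_text(XML_ONE)
    sents = parse_corpus_xml(path)
    assert len(sents) == 1
    sent = sents[0]
    assert [p[3] for p in sent.pairs] == ["Negative"]
    e0 = sent.entities[0]
    assert (e0.char_start, e0.char_end) == (0, 7)  # inclusive -> half-open


def test_three_entities_three_pairs(tmp_path):
    xml = textwrap.dedent("""\
        <document id="d2">
          <sentence id="d2.s0" text="a b c d e f">
            <entity id="e0" type="drug" text="a" charOffset="0-0"/>
            <entity id="e1" type="drug" text="c" charOffset="4-4"/>
            <entity id="e2" type="drug" text="e" charOffset="8-8"/>
            <pair id="p0" e1="e0" e2="e1" ddi="true" type="effect"/>
            <pair id="p1" e1="e0" e2="e2" ddi="true" type="advice"/>
            <pair id="p2" e1="e1" e2="e2" ddi="false"/>
          </sentence>
        </document>
    """)
    path = tmp_path / "three.xml"
    path.write_text(xml)
    sent = parse_corpus_xml(path)[0]
    assert len(sent.pairs) == 3
    assert sorted(p[3] for p in sent.pairs) == ["Advice", "Effect", "Negative"]


def test_unknown_entity_reference_is_hard_error(tmp_path):
    xml = XML_ONE.replace('e2="d1.s0.e1"', 'e2="d1.s0.e9"')
    path = tmp_path / "bad.xml"
    path.write_text(xml)
    with pytest.raises(CorpusError, match="d1.s0.e9"):
        parse_corpus_xml(path)


def test_discontinuous_offset_keeps_first_span_with_warning(tmp_path):
    xml = XML_ONE.replace('charOffset="0-6"', 'charOffset="0-6;19-26"')
    path = tmp_path / "disc.xml"
    path.write_text(xml)
    with pytest.warns(UserWarning, match="discontinuous"):
        sent = parse_corpus_xml(path)[0]
    assert (sent.entities[0].char_start, sent.entities[0].char_end) == (0, 7)


def test_xml_round_trip_preserves_annotation_attributes(tmp_path):
    gen = generate(SyntheticSpec(n_sentences=10, seed=5), tmp_path)
    first = parse_corpus_xml(gen.xml_path)
    write_corpus_xml(first, tmp_path / "again.xml", document_id="synth")
    second = parse_corpus_xml(tmp_path / "again.xml")

    def canon(sents):
        return [(s.sentence_id, s.text,
                 sorted((e.id, e.type, e.text, e.char_start, e.char_end)
                        for e in s.entities),
                 sorted(s.pairs))
                for s in sents]

    assert canon(first) == canon(second)


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

CONLLU = textwrap.dedent("""\
    # sent_id = s1
    # text = a b c
    1\ta\ta\tDT\t_\t_\t2\tdet\t_\t_
    2\tb\tb\tNN\t_\t_\t0\troot\t_\t_
    3\tc\tc\tNN\t_\t_\t2\tdobj\t_\t_

""")


def test_read_conllu_shifts_heads_to_zero_based(tmp_path):
    path = tmp_path / "p.conllu"
    path.write_text(CONLLU)
    parses = read_conllu(path)
    heads = [t.head for t in parses["s1"]]
    assert heads == [1, None, 1]
    # offsets recovered from the text comment
    assert [(t.char_start, t.char_end) for t in parses["s1"]] == [(0, 1), (2, 3), (4, 5)]


def test_read_conllu_skips_ranges_and_empty_nodes(tmp_path):
    content = CONLLU.replace("1\ta", "1-2\tab\t_\t_\t_\t_\t_\t_\t_\t_\n1\ta")
    content = content.replace("3\tc\tc\tNN\t_\t_\t2\tdobj\t_\t_\n",
                              "3\tc\tc\tNN\t_\t_\t2\tdobj\t_\t_\n"
                              "3.1\tx\tx\tX\t_\t_\t_\t_\t_\t_\n")
    path = tmp_path / "mw.conllu"
    path.write_text(content)
    tokens = read_conllu(path)["s1"]
    assert [t.surface for t in tokens] == ["a", "b", "c"]
    # parsed token count equals the number of plain-integer-id rows
    plain_rows = [l for l in content.splitlines()
                  if l and not l.startswith("#")
                  and l.split("\t")[0].isdigit()]
    assert len(tokens) == len(plain_rows)


def test_read_conllu_cycle_is_hard_error(tmp_path):
    bad = CONLLU.replace("2\tb\tb\tNN\t_\t_\t0\troot", "2\tb\tb\tNN\t_\t_\t3\tdep")
    path = tmp_path / "cyc.conllu"
    path.write_text(bad)
    with pytest.raises(CorpusError):
        read_conllu(path)


def test_missing_parse_for_sentence_is_hard_error(tmp_path):
    path = tmp_path / "one.xml"
    path.write_text(XML_ONE)
    sents = parse_corpus_xml(path)
    with pytest.raises(CorpusError, match="d1.s0"):
        build_instances(sents, parses={})


# ---------------------------------------------------------------------------
# Offset alignment
# ---------------------------------------------------------------------------

def _tokens_for(text):
    toks = []
    start = 0
    words = text.split(" ")
    for i, w in enumerate(words):
        toks.append(Token(index=i, surface=w, lemma=w, pos="NN",
                          head=None if i == 0 else 0, deprel="dep",
                          char_start=start, char_end=start + len(w)))
        start += len(w) + 1
    return toks


def test_align_single_and_multi_token_entities():
    text = "aspirin like drug"
    toks = _tokens_for(text)
    ents = [EntityMention(id="e0", type="drug", text="aspirin",
                          char_start=0, char_end=7),
            EntityMention(id="e1", type="drug", text="like drug",
                          char_start=8, char_end=17)]
    resolved = align_offsets(text, ents, toks)
    assert resolved[0].token_span == (0, 0)
    assert resolved[1].token_span == (1, 2)
    assert resolved[1].orig_words == ["like", "drug"]


def test_align_uncovered_entity_is_hard_error():
    toks = _tokens_for("a b")
    ents = [EntityMention(id="e0", type="drug", text="zz",
                          char_start=40, char_end=42)]
    with pytest.raises(CorpusError):
        align_offsets("a b", ents, toks, "sX")


def test_aligned_span_covers_entity_text(small_corpus):
    """On generated sentences the resolved span's characters contain the mention."""
    from ddipath.corpus_io import align_offsets
    for sent in small_corpus.sentences:
        tokens = small_corpus.parses[sent.sentence_id]
        for ent in align_offsets(sent.text, sent.entities, tokens):
            a = tokens[ent.token_span[0]].char_start
            b = tokens[ent.token_span[1]].char_end
            assert ent.text in sent.text[a:b]


# ---------------------------------------------------------------------------
# Anonymization
# ---------------------------------------------------------------------------

def _pair(tokens, span0, span1, others=()):
    def ent(i, span):
        return EntityMention(id=f"e{i}", type="drug",
                             text=" ".join(t.surface for t in tokens[span[0]:span[1] + 1]),
                             token_span=span,
                             orig_words=[t.surface for t in tokens[span[0]:span[1] + 1]])
    return PairInstance(sentence_id="s", pair_id="p", tokens=tokens,
                        e0=ent(0, span0), e1=ent(1, span1), label="Effect")


def _is_tree(tokens):
    roots = [t for t in tokens if t.head is None]
    if len(roots) != 1:
        return False
    for t in tokens:
        seen, cur = set(), t
        while cur.head is not None:
            if cur.index in seen:
                return False
            seen.add(cur.index)
            cur = tokens[cur.head]
    return True


def test_anonymize_single_token_entities_keeps_length():
    toks = _tokens_for("aspirin reduces warfarin levels")
    inst = anonymize(_pair(toks, (0, 0), (2, 2)))
    assert len(inst.tokens) == 4
    assert inst.tokens[0].surface == "drug0"
    assert inst.tokens[2].surface == "drug1"
    assert inst.tokens[1].surface == "reduces"
    assert _is_tree(inst.tokens)


def test_anonymize_collapses_multi_token_span_and_remaps_heads():
    # e0 spans 3 tokens; heads inside the span must be redirected
    toks = [Token(0, "acetyl", "acetyl", "JJ", 2, "amod"),
            Token(1, "salicylic", "salicylic", "JJ", 2, "amod"),
            Token(2, "acid", "acid", "NN", 3, "nsubj"),
            Token(3, "reduces", "reduces", "VB", None, "root"),
            Token(4, "warfarin", "warfarin", "NN", 3, "dobj"),
            Token(5, "levels", "levels", "NN", 4, "nmod")]
    inst = anonymize(_pair(toks, (0, 2), (4, 4)))
    assert len(inst.tokens) == 4  # dropped 2 tokens
    assert [t.surface for t in inst.tokens] == ["drug0", "reduces", "drug1", "levels"]
    assert _is_tree(inst.tokens)
    assert inst.e0.token_span == (0, 0)
    assert inst.e1.token_span == (2, 2)
    assert inst.e0.orig_words == ["acetyl", "salicylic", "acid"]
    for t in inst.tokens:
        assert t.head is None or 0 <= t.head < len(inst.tokens)


def test_anonymize_blinds_other_drug_mentions():
    toks = _tokens_for("aspirin reduces warfarin and heparin")
    other = EntityMention(id="e2", type="drug", text="heparin",
                          token_span=(4, 4), orig_words=["heparin"])
    inst = anonymize(_pair(toks, (0, 0), (2, 2)), other_entities=[other])
    assert inst.tokens[4].surface == "drugn"
    without = anonymize(_pair(toks, (0, 0), (2, 2)), other_entities=[other],
                        anonymize_others=False)
    assert without.tokens[4].surface == "heparin"


def test_anonymized_parse_is_tree_on_every_synthetic_instance(small_instances):
    for inst in small_instances:
        assert _is_tree(inst.tokens)
        assert inst.tokens[inst.e0.token_span[0]].surface == "drug0"
        assert inst.tokens[inst.e1.token_span[0]].surface == "drug1"


def test_instance_count_equals_pair_count(small_corpus, small_instances):
    n_pairs = sum(len(s.pairs) for s in small_corpus.sentences)
    assert len(small_instances) == n_pairs


def test_instances_jsonl_round_trip(tmp_path, small_instances):
    path = tmp_path / "inst.jsonl"
    write_instances_jsonl(small_instances, path)
    back = read_instances_jsonl(path)
    assert len(back) == len(small_instances)
    for a, b in zip(small_instances, back):
        assert a.pair_id == b.pair_id
        assert a.label == b.label
        assert a.sdp == b.sdp
        assert [t.surface for t in a.tokens] == [t.surface for t in b.tokens]
        assert [t.head for t in a.tokens] == [t.head for t in b.tokens]
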