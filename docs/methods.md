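# Methods

## Task and data model

A candidate instance is one ordered pair of drug mentions inside one
sentence, labelled `Negative`, `Advice`, `Effect`, `Mechanism` or `Int`.
Inputs are (a) an annotated corpus in the DDIExtraction-2013 XML dialect
(sentences with inclusive character-offset entity mentions and labelled
pair elements) and (b) per-sentence dependency parses in CoNLL-U, produced
by any parser whose tokenization is consistent with the sentence text.
The reader converts inclusive offsets to 0-based half-open spans, aligns
each entity to the minimal covering token range, and fails loudly on
malformed structure (unknown entity references, cyclic heads, missing
parses). Discontinuous mentions (`"a-b;c-d"` offsets) keep their first span
with a warning — they are rare and the data model requires contiguous spans.

## Preprocessing decisions

**Entity blinding.** The targeted mentions become single `drug0`/`drug1`
tokens; other drug mentions become `drugn` (configurable off). Blinding
prevents the classifier from memorizing drug names. A multi-token mention
collapses onto its span token closest to the root; every head pointing into
the span is redirected to the surviving token. Choosing the minimal-depth
token guarantees the contraction cannot create a cycle (no ancestor of that
token's head lies inside the span), so the parse remains a tree — asserted
on every synthetic instance in the tests.

**Shortest dependency path.** Path finding runs on the undirected view of
the dependency tree by breadth-first search from the `drug0` token to the
`drug1` token. On a tree the shortest path is unique, so tie-breaking is
immaterial (asserted by reversing adjacency order); per-edge walk direction
and relation labels are retained. The SDP input sequence consists of the
on-path tokens only: the token representation has word/POS/position
channels, none of which exist for relation labels. An experimental flag
(`sdp_include_relations`) interleaves relation labels as pseudo-tokens that
draw a word-vocabulary embedding and pad POS/position ids; it is off by
default and not used in any reported number.

## Encoding

Token vectors concatenate four channels: word (200-d), POS (10-d), and two
position embeddings (10-d each) indexed by the signed token distance to
each targeted entity, clipped to ±30 (the clip is a package choice; 30
covers all but the longest sentences, and a dedicated pad row handles
padding). Word and POS tables initialize from a seeded normal scaled by
0.1 unless pretrained word2vec-text vectors are supplied; position vectors
draw from a standard normal. All tables are trainable.

An entity is represented by the mean of its original (pre-blinding) word
vectors, the noun POS row (entity POS is fixed to noun by convention), the
zero-distance row and the signed distance to the other entity.

**Entity attention.** θ_i^k softmax-normalizes dot(w_i^word, e_k^word)
over the sequence; the token's full 230-d vector is scaled by
(θ_i^0 + θ_i^1)/2. Only the word channel enters the dot product; the
scalar multiplies all channels. Numerical stabilization subtracts the
maximum logit (softmax is shift-invariant, asserted as a property test).
Two domain decisions:

- the sentence and the SDP are normalized independently, each over its own
  length — the attention definition sums over the input sequence, and the
  SDP is its own input sequence;
- entity placeholder tokens participate in the sentence softmax like any
  token (they are sentence tokens after blinding), while the mean-of-words
  entity vector is used for the dedicated e0/e1 slots.

The averaged weight scales vectors by roughly 1/m on an m-token sequence;
we keep this literal form (an `attention_rescale` alternative was
considered and rejected as an unstated deviation).

## Architecture and training

Bottom bidirectional encoders (LSTM by default; GRU/simple variants are
config options) reduce each of the three subsequences (one shared encoder)
and the SDP (a separate encoder, since path token sequences are
distributionally unlike running text) to the concatenated final
forward/backward states (2×100-d). Empty subsequences encode to the zero
vector. The 230-d entity vectors are linearly projected to the same width
so the top encoder sees a homogeneous six-step sequence
`[sub0, e0, sub1, e1, sub2, SDP]`; its final states (2×100-d) feed the
softmax head. Max-pooling over bottom states is available
(`bottom_pooling: max`) but final-state reduction is the default — the top
encoder, not pooling, integrates the parts.

Training: cross-entropy, RMSProp (lr 0.001, ρ 0.9, ε 1e-7), batch 64,
dropout 0.7 after the embedding level and 0.5 on the top representation,
train-time only. 30 epochs by default; the dev micro-F is logged per epoch
and the best-dev parameters are kept. All randomness (initialization,
shuffling, dropout) derives from explicit seeds; two runs with the same
seeds produce bitwise-identical loss sequences on CPU.

The model runs on a package-local reverse-mode autodiff engine over NumPy
(float32 working precision; float64 in the numerical gradient checks).
Variable-length segments are packed: only real tokens enter the input
projection, and the recurrence advances a length-sorted prefix of rows at
each time step, which is exactly equivalent to masked padded computation
(asserted against the padded path in the tests).

## Evaluation

Per-class precision/recall/F for the four positive classes and a
micro-average pooling tp/fp/fn across them, excluding `Negative` — the
shared-task convention, under which predicting everything `Negative` scores
zero recall. A positive prediction is a true positive only when the type
matches exactly. Zero-denominator precision or recall is reported as 0 so
F is always defined. F is the harmonic mean 2PR/(P+R).

## Synthetic corpus

The generator emulates the corpus shape at desk scale: each sentence has
two drug-name tokens joined by a random dependency tree, Negative-dominant
class priors (0.8/0.05/0.05/0.05/0.05, mirroring the heavy class imbalance
of real DDI corpora), and a planted class signal: each positive class has a
distinct trigger lemma placed on the entity-to-entity dependency path (with
probability `p_trigger_on_sdp`, default 1.0; otherwise attached off-path as
a leaf). Negative sentences contain no trigger. Trees are built by
constructing the entity–(interior)–entity chain explicitly and attaching
all remaining tokens as uniformly random dependents, which guarantees the
on/off-path placement by construction. Defaults: 2000 sentences, filler
vocabulary 120, sentence length 6–25, seed 7. A 15% chance of a third,
non-targeted drug mention exercises the `drugn` blinding path.

Toy pretrained vectors give the four trigger lemmas exactly orthogonal
dense sign patterns (tiled Hadamard rows, entries ±0.125, so pairwise dot
products cancel exactly in floating point) — dense directions keep the
signal visible under the heavy embedding dropout — and seeded random
vectors for everything else.

What the generator does not emulate: grammar, lexical ambiguity, multi-pair
sentences, annotation noise, discontinuous or nested mentions, and
realistic parse error. Passing the recovery suite therefore demonstrates
that the pipeline wiring, attention, encoders and evaluator are correct —
not that corpus-level performance on real text is reproduced, which would
require the external corpus and pretrained biomedical embeddings.

## End-to-end study protocol

The acceptance experiments use the default 2000-sentence corpus split
1600/200/200 (train/dev/test) by position — sentences are generated
i.i.d., so slicing is a random split. Three runs at the published
hyperparameters, 30 epochs each:

1. **Recovery** — held-out micro-F on the default corpus (expected ≥ 0.9;
   the planted signal is fully separable).
2. **Chance control** — training and dev labels randomly permuted; held-out
   micro-F stays at chance (< 0.35).
3. **SDP-ablation contrast** — trigger surfaces are confined to the
   dependency-path branch (`trigger_only_on_sdp_surface`): they are removed
   from the three subsequences and blinded to the unknown id in the
   sentence-level attention channel (otherwise the trigger identity leaks
   through the shared softmax denominator), while the SDP sequence keeps
   them. The full model recovers the signal; the variant trained with the
   SDP slot zeroed scores strictly lower, showing the path branch carries
   the information.

The corpus seed is part of the study conditions (seed 7); the command-line
`--seed` of `scripts/acceptance.py` sets training initialization and the
oracle RNG draws.

## Numerical and degenerate-input choices

- Softmax stabilized by max subtraction; attention sums checked to 1e-6.
- Empty segments (entity-initial sentences, adjacent entities) encode to
  zero vectors without special-casing downstream.
- One-token entity means reduce to the word vector itself; entities whose
  original words are unrecorded fall back to the unknown embedding.
- Non-finite training loss raises immediately, naming the batch.
- LSTM forget-gate bias initialized to 1; other gates Glorot-uniform.

## Known limitations

- The recurrent engine is CPU-only and unbatched across experiments; it is
  sized for desk-scale corpora (thousands of sentences), not the full
  literature.
- `bottom_pooling: max` falls back to the padded (slower) execution path.
- The reader assumes one parse per sentence id; enhanced dependency graphs
  and nested entities are out of scope.
- Hyperparameters are taken as given; no search is implemented.
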