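"""End-to-end synthetic recovery experiments.

A single protocol shared by the test suite and the acceptance script:
generate a synthetic corpus, run the full preprocessing pipeline (XML +
CoNLL-U -> anonymized pair instances with SDPs), build vocabularies and toy
pretrained vectors, train the hierarchical extractor, and score held-out
micro-F over the positive classes.

The default corpus of 2000 sentences is split 1600/200/200 into
train/dev/test by position (sentences are generated i.i.d., so slicing is a
random split).  Variants cover the chance-level control (permuted training
labels) and the SDP-ablation contrast (trigger surfaces excluded from the
linear subsequences so the class signal reaches the model only through the
dependency-path branch, then the SDP slot zeroed).
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np

from .corpus_io import build_instances
from .encoding import EmbeddingConfig, build_vocab, index_instance, load_word_vectors
from .evaluation import EvalReport, score
from .hrnn_model import (HierarchicalExtractor, ModelConfig, TrainConfig,
                         fit, predict)
from .synthetic_data import SyntheticSpec, generate, make_toy_vectors


@dataclass
class ExperimentResult:
    micro_f: float
    report: EvalReport
    log: list[dict]
    n_train: int
    n_test: int


@dataclass
class SyntheticDatasets:
    train: list
    dev: list
    test: list
    word_init: np.ndarray
    emb_cfg: EmbeddingConfig
    word_vocab: object
    pos_vocab: object
    test_gold: dict[str, str]


def prepare_synthetic_datasets(spec: SyntheticSpec | None = None,
                               emb_cfg: EmbeddingConfig | None = None,
                               trigger_only_on_sdp_surface: bool = False,
                               split: tuple[float, float] = (0.8, 0.1)) -> SyntheticDatasets:
    """Generate, preprocess and index the synthetic corpus."""
    spec = spec or SyntheticSpec()
    emb_cfg = emb_cfg or EmbeddingConfig(seed=spec.seed)
    gen = generate(spec)
    instances = build_instances(gen.sentences, gen.parses)
    n = len(instances)
    n_train = int(n * split[0])
    n_dev = int(n * split[1])
    train = instances[:n_train]
    dev = instances[n_train:n_train + n_dev]
    test = instances[n_train + n_dev:]

    word_vocab, pos_vocab = build_vocab(train, min_count=emb_cfg.min_count,
                                        noun_tag=emb_cfg.noun_tag)
    triggers = list(spec.trigger_map.values())
    with tempfile.TemporaryDirectory() as tmp:
        vec_path = make_toy_vectors(word_vocab.itos[2:], emb_cfg.d_word,
                                    seed=spec.seed, trigger_lemmas=triggers,
                                    path=f"{tmp}/vectors.txt")
        word_init, _ = load_word_vectors(vec_path, word_vocab, emb_cfg.d_word,
                                         seed=emb_cfg.seed)

    exclude = frozenset(triggers) if trigger_only_on_sdp_surface else frozenset()
    idx = [
        [index_instance(i, word_vocab, pos_vocab, emb_cfg, exclude_surfaces=exclude)
         for i in part]
        for part in (train, dev, test)
    ]
    test_gold = {i.pair_id: i.label for i in test}
    return SyntheticDatasets(train=idx[0], dev=idx[1], test=idx[2],
                             word_init=word_init, emb_cfg=emb_cfg,
                             word_vocab=word_vocab, pos_vocab=pos_vocab,
                             test_gold=test_gold)


def train_and_score(data: SyntheticDatasets, train_seed: int = 1,
                    epochs: int = 30, model_cfg: ModelConfig | None = None,
                    permute_labels: bool = False,
                    train_cfg: TrainConfig | None = None) -> ExperimentResult:
    """Train on the prepared datasets and score held-out micro-F."""
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig(epochs=epochs, seed=train_seed)

    train_set, dev_set = data.train, data.dev
    if permute_labels:
        rng = np.random.default_rng(train_seed)
        train_set = _with_permuted_labels(train_set, rng)
        dev_set = _with_permuted_labels(dev_set, rng)

    model = HierarchicalExtractor(model_cfg, data.emb_cfg, data.word_vocab,
                                  data.pos_vocab, seed=train_seed,
                                  word_init=data.word_init)
    log = fit(model, train_set, dev_set, train_cfg)
    labels, _ = predict(model, data.test, train_cfg.batch_size)
    preds = {x.pair_id: lab for x, lab in zip(data.test, labels)}
    report = score(preds, data.test_gold)
    return ExperimentResult(micro_f=report.micro["f"], report=report, log=log,
                            n_train=len(train_set), n_test=len(data.test))


def _with_permuted_labels(instances: list, rng: np.random.Generator) -> list:
    from dataclasses import replace
    perm = rng.permutation(len(instances))
    return [replace(inst, label_id=instances[j].label_id)
            for inst, j in zip(instances, perm)]
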