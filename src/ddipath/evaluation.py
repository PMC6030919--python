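"""Scoring: per-class and micro-averaged precision/recall/F over DDI types.

Micro averaging follows the DDIExtraction-2013 shared-task convention:
true/false positives and false negatives are pooled over the four positive
relation classes (Advice, Effect, Mechanism, Int); Negative is excluded from
the pooling, so predicting everything Negative scores recall 0.  A positive
prediction counts as a true positive only when the predicted type equals the
gold type.  Zero-denominator precision or recall is reported as 0 so the
F-score is always defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import LABELS, POSITIVE_LABELS


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    per_class: dict[str, dict[str, float]]
    micro: dict[str, float]
    confusion: np.ndarray = field(repr=False)  # confusion[gold, pred], label order

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "micro": self.micro,
                "labels": list(LABELS), "confusion": self.confusion.tolist()}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True),
                              encoding="utf-8")


def score(predictions: dict[str, str], gold: dict[str, str]) -> EvalReport:
    """Score predicted labels against gold labels keyed by pair id."""
    if set(predictions) != set(gold):
        missing = set(gold) - set(predictions)
        extra = set(predictions) - set(gold)
        raise ValueError(f"prediction/gold key mismatch: missing={sorted(missing)[:5]} "
                         f"extra={sorted(extra)[:5]}")
    idx = {lab: i for i, lab in enumerate(LABELS)}
    confusion = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    for pid in gold:
        confusion[idx[gold[pid]], idx[predictions[pid]]] += 1

    per_class: dict[str, dict[str, float]] = {}
    micro_tp = micro_fp = micro_fn = 0
    for lab in POSITIVE_LABELS:
        i = idx[lab]
        tp = int(confusion[i, i])
        fp = int(confusion[:, i].sum() - tp)
        fn = int(confusion[i, :].sum() - tp)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        per_class[lab] = {"tp": tp, "fp": fp, "fn": fn,
                          "precision": p, "recall": r, "f": f_score(p, r)}
        micro_tp += tp
        micro_fp += fp
        micro_fn += fn
    micro_p = micro_tp / (micro_tp + micro_fp) if micro_tp + micro_fp else 0.0
    micro_r = micro_tp / (micro_tp + micro_fn) if micro_tp + micro_fn else 0.0
    micro = {"precision": micro_p, "recall": micro_r, "f": f_score(micro_p, micro_r),
             "tp": micro_tp, "fp": micro_fp, "fn": micro_fn}
    return EvalReport(per_class=per_class, micro=micro, confusion=confusion)
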