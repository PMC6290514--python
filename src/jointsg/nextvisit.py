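"""Next-visit diagnosis prediction and its top-k recall evaluation.

Consecutive visits of each patient form labeled examples: the earlier
visit supplies a feature vector, the later visit's code set is the label.
A softmax layer over the grouped code vocabulary is trained with
categorical cross-entropy (the multi-code label becomes a uniform target
distribution over its codes) and scored by top-k recall,
|top-k predictions ∩ true codes| / |true codes|, averaged over examples
with its standard error.

Feature schemes:
  codes_avg     mean V row of the visit's codes (length T)
  words_avg     mean V row of the visit's word occurrences (length T)
  concat_avg    the two means concatenated (length 2T)
  concat_onehot binary indicators over words then codes (length |W|+|C|)
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from jointsg.core import EmbeddingModel
from jointsg.corpus import IndexedVisit

logger = logging.getLogger(__name__)

SCHEMES = ("codes_avg", "words_avg", "concat_avg", "concat_onehot")


@dataclass
class LabeledExample:
    """Feature vector of a visit and the code ids of the patient's next visit.

    ``label_ids`` are local code indices in ``[0, |C|)`` (vocabulary id
    minus ``|W|``); the label set is never empty.
    """

    features: np.ndarray
    label_ids: np.ndarray


@dataclass
class NextVisitModel:
    """Softmax weights Z of shape ``(|C|, n_features)`` plus training meta."""

    Z: np.ndarray
    epochs: int
    seed: int


def visit_features(model: EmbeddingModel, visit: IndexedVisit, scheme: str) -> np.ndarray:
    """Feature vector of one visit under a scheme (see module docstring).

    An averaging scheme over an empty token set yields a zero block, with
    a debug log; one-hot marks each distinct in-vocabulary token once.
    """
    vocab = model.vocab
    T = model.dim
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")

    def _avg(ids: np.ndarray) -> np.ndarray:
        if ids.size == 0:
            logger.debug(
                "visit %s: empty token set for averaging; zero block", visit.visit_id
            )
            return np.zeros(T)
        return model.V[ids].mean(axis=0)

    if scheme == "codes_avg":
        return _avg(visit.code_ids)
    if scheme == "words_avg":
        return _avg(visit.word_ids)
    if scheme == "concat_avg":
        return np.concatenate([_avg(visit.code_ids), _avg(visit.word_ids)])
    x = np.zeros(len(vocab))
    x[np.unique(visit.word_ids)] = 1.0
    x[visit.code_ids] = 1.0
    return x


def make_labeled_pairs(
    visits: Iterable[IndexedVisit],
) -> list[tuple[IndexedVisit, IndexedVisit]]:
    """Consecutive (earlier, later) visit pairs per patient.

    Visits are grouped by patient and sorted by admission time (ties break
    deterministically by visit id, with a warning); a patient with v
    visits yields v - 1 pairs, so single-visit patients yield none.  Pairs
    whose later visit has no in-vocabulary codes are skipped: they cannot
    form a label set.
    """
    by_patient: dict[str, list[IndexedVisit]] = defaultdict(list)
    for v in visits:
        by_patient[v.patient_id].append(v)
    pairs: list[tuple[IndexedVisit, IndexedVisit]] = []
    for pid in sorted(by_patient):
        pvisits = by_patient[pid]
        times = [v.admit_time for v in pvisits]
        if len(set(times)) != len(times):
            logger.warning(
                "patient %s has duplicate admit times; breaking ties by visit_id", pid
            )
        pvisits.sort(key=lambda v: (v.admit_time, v.visit_id))
        for earlier, later in zip(pvisits, pvisits[1:]):
            if later.code_ids.size == 0:
                logger.warning(
                    "skipping pair (%s -> %s): next visit has no codes",
                    earlier.visit_id, later.visit_id,
                )
                continue
            pairs.append((earlier, later))
    return pairs


def build_examples(
    model: EmbeddingModel,
    pairs: Sequence[tuple[IndexedVisit, IndexedVisit]],
    scheme: str,
) -> list[LabeledExample]:
    """Feature/label examples from consecutive-visit pairs."""
    n_words = model.vocab.n_words
    out = []
    for earlier, later in pairs:
        out.append(
            LabeledExample(
                features=visit_features(model, earlier, scheme),
                label_ids=later.code_ids - n_words,
            )
        )
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def train_softmax(
    examples: Sequence[LabeledExample],
    n_codes: int,
    epochs: int = 100,
    lr: float = 0.5,
    seed: int = 0,
) -> NextVisitModel:
    """Fit the softmax predictor by per-example SGD.

    Minimizes categorical cross-entropy against a uniform target over each
    example's true next-visit codes; example order is reshuffled each
    epoch with the seed.  Z starts at zero (uniform predictions).
    """
    if not examples:
        raise ValueError("no labeled examples")
    n_feat = examples[0].features.shape[0]
    X = np.stack([ex.features for ex in examples])
    targets = np.zeros((len(examples), n_codes))
    for i, ex in enumerate(examples):
        if ex.label_ids.size == 0:
            raise ValueError("label set must be nonempty")
        targets[i, ex.label_ids] = 1.0 / ex.label_ids.size
    Z = np.zeros((n_codes, n_feat))
    rng = np.random.default_rng(seed)
    for _epoch in range(epochs):
        for i in rng.permutation(len(examples)):
            p = _softmax(Z @ X[i])
            Z -= lr * np.outer(p - targets[i], X[i])
        if not np.all(np.isfinite(Z)):
            raise FloatingPointError(
                f"softmax training diverged at epoch {_epoch}; try a smaller lr"
            )
    return NextVisitModel(Z=Z, epochs=epochs, seed=seed)


def cross_entropy(model: NextVisitModel, examples: Sequence[LabeledExample]) -> float:
    """Mean categorical cross-entropy of the fitted predictor."""
    total = 0.0
    for ex in examples:
        logits = model.Z @ ex.features
        logp = logits - logits.max()
        logp = logp - np.log(np.exp(logp).sum())
        total -= float(logp[ex.label_ids].mean())
    return total / len(examples)


def predict_probs(model: NextVisitModel, x: np.ndarray) -> np.ndarray:
    """Softmax probabilities over the code vocabulary for one feature vector."""
    return _softmax(model.Z @ x)


def predict_topk(model: NextVisitModel, x: np.ndarray, k: int) -> np.ndarray:
    """The k most probable local code ids, ties broken by smaller id."""
    p = predict_probs(model, x)
    k = min(k, p.shape[0])
    # stable sort on -p keeps id order among ties
    order = np.argsort(-p, kind="stable")
    return order[:k]


def topk_recall(predicted: Sequence[int], true_set: Iterable[int]) -> float:
    """|predicted ∩ true| / |true|."""
    true = set(true_set)
    if not true:
        raise ValueError("true code set must be nonempty")
    return len(true.intersection(predicted)) / len(true)


def evaluate(
    model: NextVisitModel,
    examples: Sequence[LabeledExample],
    ks: Sequence[int] = (20, 30, 40),
) -> dict[int, tuple[float, float]]:
    """Mean top-k recall with standard error, per k.

    Macro average over examples; the standard error is the sample standard
    deviation divided by sqrt(n).
    """
    if not examples:
        raise ValueError("no examples to evaluate")
    out: dict[int, tuple[float, float]] = {}
    kmax = max(ks)
    ranked = [predict_topk(model, ex.features, kmax) for ex in examples]
    for k in ks:
        recalls = np.array(
            [topk_recall(r[:k], ex.label_ids) for r, ex in zip(ranked, examples)]
        )
        se = float(recalls.std(ddof=1) / np.sqrt(len(recalls))) if len(recalls) > 1 else 0.0
        out[k] = (float(recalls.mean()), se)
    return out


def read_feature_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an externally computed feature matrix (TSV: id then floats).

    Lets feature sets produced by other decompositions (SVD, LDA, ...) be
    scored by the same softmax harness.
    """
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: need id + >=1 feature")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    M = np.array(rows)
    if M.ndim != 2:
        raise ValueError(f"{path}: rows have inconsistent feature counts")
    return ids, M
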