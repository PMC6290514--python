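"""Skip-gram with negative sampling over the joint code + word space.

The model keeps two matrices, ``V`` (input/target representations) and
``U`` (context representations), each of shape ``(|W| + |C|) x T`` so that
word rows and code rows live in one space.  Per visit, every code predicts
every other code of the visit and every note-word occurrence; every word
predicts its note-window neighbours and every code of the visit.  Each
observed (target, context) pair is scored as

    log sigma(V_t . U_c)  +  sum_{n in negatives} log(1 - sigma(V_t . U_n))

with the K negatives drawn from the unigram distribution of the context's
namespace (words for a word context, codes for a code context), optionally
raised to a power.  Training maximizes this objective by stochastic
gradient ascent, one pair at a time.

Two restricted modes recover the classical baselines: ``words_only`` is
plain skip-gram over the notes, ``codes_only`` is skip-gram over co-visit
code pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from jointsg.corpus import IndexedVisit, Vocabulary

logger = logging.getLogger(__name__)

MODES = ("joint", "words_only", "codes_only")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the embedding trainer.

    Defaults follow the reference setting: 200-dimensional vectors, 40
    passes over the visits, a +/-5 word window, 5 negative samples per
    observed pair, and a words-only pretraining pass over ~10% of visits
    before joint training.  ``noise_power`` = 0.75 is the usual SGNS
    smoothing of the unigram distribution; set 1.0 for the raw marginal.
    """

    dim: int = 200
    epochs: int = 40
    window: int = 5
    negatives: int = 5
    initial_lr: float = 0.025
    lr_schedule: str = "linear-decay"  # or "constant"
    noise_power: float = 0.75
    mode: str = "joint"
    seed: int = 0
    pretrain_fraction: float = 0.10
    pretrain_epochs: int = 5

    def __post_init__(self) -> None:
        if self.dim < 1 or self.epochs < 1 or self.window < 1 or self.negatives < 0:
            raise ValueError("dim, epochs, window must be >= 1 and negatives >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.lr_schedule not in ("linear-decay", "constant"):
            raise ValueError("lr_schedule must be 'linear-decay' or 'constant'")
        if not 0.0 < self.noise_power <= 1.0:
            raise ValueError("noise_power must be in (0, 1]")
        if not 0.0 <= self.pretrain_fraction <= 1.0:
            raise ValueError("pretrain_fraction must be in [0, 1]")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")


@dataclass
class EmbeddingModel:
    """Joint embedding: V and U of shape ``(|W|+|C|) x T`` plus the vocabulary."""

    V: np.ndarray
    U: np.ndarray
    vocab: Vocabulary
    config: TrainingConfig | None = None

    @property
    def dim(self) -> int:
        return self.V.shape[1]


class NoiseDistribution:
    """Normalized negative-sampling weights over one namespace's token ids."""

    def __init__(self, tokens: np.ndarray, probs: np.ndarray):
        tokens = np.asarray(tokens, dtype=np.int64)
        probs = np.asarray(probs, dtype=np.float64)
        if tokens.size == 0:
            raise ValueError("noise distribution needs a nonempty support")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        self.tokens = tokens
        self.probs = probs
        self._cdf = np.cumsum(probs)
        self._cdf[-1] = 1.0

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        """Draw token ids; inverse-CDF on uniforms so draws are reproducible."""
        return self.sample_from_uniforms(rng.random(size))

    def sample_from_uniforms(self, u: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._cdf, u, side="right")
        return self.tokens[np.minimum(idx, self.tokens.size - 1)]


def build_noise_distribution(counts: Mapping[int, float], power: float = 0.75) -> NoiseDistribution:
    """Unigram noise distribution: p_i proportional to count_i ** power."""
    if not counts:
        raise ValueError("empty counts")
    ids = np.array(sorted(counts), dtype=np.int64)
    w = np.array([float(counts[i]) for i in ids], dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("all counts must be positive")
    w = w ** power
    return NoiseDistribution(ids, w / w.sum())


def namespace_noise(vocab: Vocabulary, namespace: str, power: float = 0.75) -> NoiseDistribution:
    """Noise distribution over one namespace, from corpus counts."""
    counts = vocab.id_counts()
    if namespace == "words":
        ids = range(vocab.n_words)
    elif namespace == "codes":
        ids = range(vocab.n_words, len(vocab))
    else:
        raise ValueError("namespace must be 'words' or 'codes'")
    return build_noise_distribution({i: int(counts[i]) for i in ids}, power)


# ---------------------------------------------------------------------------
# Context enumeration


def code_target_contexts(
    visit: IndexedVisit, include_words: bool = True
) -> list[tuple[int, int]]:
    """(target code, context) pairs for every code of a visit.

    Each code's context is every *other* code of the visit plus — in joint
    mode — every word occurrence of its notes (multiplicity preserved).
    Emission order is deterministic: codes in id order, each paired first
    with the other codes in id order, then with words in sequence order.
    """
    pairs: list[tuple[int, int]] = []
    codes = [int(c) for c in visit.code_ids]
    words = [int(w) for w in visit.word_ids] if include_words else []
    for ci in codes:
        for cj in codes:
            if cj != ci:
                pairs.append((ci, cj))
        for w in words:
            pairs.append((ci, w))
    return pairs


def word_target_contexts(
    visit: IndexedVisit, q: int, include_codes: bool = True
) -> list[tuple[int, int]]:
    """(target word, context) pairs for every word occurrence of a visit.

    Each word's context is the words within ``q`` positions on either side
    — windows never cross a note boundary — plus, in joint mode, every
    code of the visit.
    """
    pairs: list[tuple[int, int]] = []
    codes = [int(c) for c in visit.code_ids] if include_codes else []
    for note in visit.note_ids:
        m = len(note)
        for i in range(m):
            wi = int(note[i])
            for j in range(max(0, i - q), min(m, i + q + 1)):
                if j != i:
                    pairs.append((wi, int(note[j])))
            for c in codes:
                pairs.append((wi, c))
    return pairs


def visit_pairs(visit: IndexedVisit, q: int, mode: str) -> list[tuple[int, int]]:
    """Full (target, context) stream for one visit under a training mode."""
    pairs: list[tuple[int, int]] = []
    if mode in ("joint", "codes_only"):
        pairs.extend(code_target_contexts(visit, include_words=(mode == "joint")))
    if mode in ("joint", "words_only"):
        pairs.extend(word_target_contexts(visit, q, include_codes=(mode == "joint")))
    return pairs


# ---------------------------------------------------------------------------
# Objective and updates


def _log_sigmoid(x: float) -> float:
    # log sigma(x) = -log(1 + e^{-x}), stable on both tails
    return -np.logaddexp(0.0, -x)


def pair_objective(
    model: EmbeddingModel, target: int, context: int, negatives: Sequence[int]
) -> float:
    """Negative-sampling score of one observed pair against its negatives.

    ``log sigma(V_t . U_c) + sum_n log(1 - sigma(V_t . U_n))``; finite for
    dot products far beyond float overflow of the naive formula.
    """
    v = model.V[target]
    total = _log_sigmoid(float(np.dot(v, model.U[context])))
    for nid in negatives:
        # log(1 - sigma(x)) = log sigma(-x)
        total += _log_sigmoid(-float(np.dot(v, model.U[nid])))
    return float(total)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def sgd_pair_update(
    model: EmbeddingModel,
    target: int,
    context: int,
    negatives: Sequence[int],
    lr: float,
) -> None:
    """One in-place gradient-ascent step on ``pair_objective``.

    The target's V row accumulates its gradient over the positive context
    and all negatives before being applied, while each context/negative U
    row is updated immediately — the word2vec update order.
    """
    if lr < 0:
        raise ValueError("lr must be >= 0")
    V, U = model.V, model.U
    v = V[target]
    acc = np.zeros_like(v)
    for row, label in [(context, 1.0)] + [(n, 0.0) for n in negatives]:
        f = _sigmoid(float(np.dot(v, U[row])))
        g = lr * (label - f)
        acc += g * U[row]
        U[row] += g * v
    v += acc
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(U[context]))):
        raise FloatingPointError(
            f"non-finite update for pair ({target}, {context}); "
            "reduce the learning rate"
        )


@njit(cache=False)
def _sgns_kernel(V, U, tgt, ctx, neg, lrs):  # pragma: no cover - jitted
    n = tgt.shape[0]
    K = neg.shape[1]
    T = V.shape[1]
    acc = np.empty(T)
    for i in range(n):
        t = tgt[i]
        lr = lrs[i]
        for d in range(T):
            acc[d] = 0.0
        for j in range(K + 1):
            if j == 0:
                row = ctx[i]
                label = 1.0
            else:
                row = neg[i, j - 1]
                label = 0.0
            x = 0.0
            for d in range(T):
                x += V[t, d] * U[row, d]
            if x >= 0.0:
                sig = 1.0 / (1.0 + math.exp(-x))
            else:
                z = math.exp(x)
                sig = z / (1.0 + z)
            g = lr * (label - sig)
            for d in range(T):
                acc[d] += g * U[row, d]
                U[row, d] += g * V[t, d]
        for d in range(T):
            V[t, d] += acc[d]


# ---------------------------------------------------------------------------
# Training loop


def _build_streams(
    visits: Sequence[IndexedVisit], q: int, mode: str
) -> list[np.ndarray]:
    """Per-visit (n_pairs, 2) arrays of the (target, context) stream."""
    streams = []
    for v in visits:
        pairs = visit_pairs(v, q, mode)
        streams.append(
            np.array(pairs, dtype=np.int64).reshape(-1, 2)
            if pairs
            else np.empty((0, 2), dtype=np.int64)
        )
    return streams


def _run_sgd(
    V: np.ndarray,
    U: np.ndarray,
    streams: list[np.ndarray],
    vocab: Vocabulary,
    cfg: TrainingConfig,
    epochs: int,
    rng: np.random.Generator,
    word_noise: NoiseDistribution | None,
    code_noise: NoiseDistribution | None,
    epoch_callback=None,
) -> None:
    """Seeded epoch loop: shuffle visits, draw negatives, run the kernel."""
    pairs_per_epoch = sum(s.shape[0] for s in streams)
    if pairs_per_epoch == 0:
        return
    total = pairs_per_epoch * epochs
    done = 0
    n_words = vocab.n_words
    K = cfg.negatives
    for _epoch in range(epochs):
        order = rng.permutation(len(streams))
        stream = np.concatenate([streams[i] for i in order], axis=0)
        tgt, ctx = stream[:, 0], np.ascontiguousarray(stream[:, 1])
        n = tgt.shape[0]
        neg = np.empty((n, K), dtype=np.int64)
        if K > 0:
            u = rng.random((n, K))
            is_code_ctx = ctx >= n_words
            if is_code_ctx.any():
                if code_noise is None:
                    raise ValueError("code contexts present but no code vocabulary")
                neg[is_code_ctx] = code_noise.sample_from_uniforms(u[is_code_ctx])
            if (~is_code_ctx).any():
                if word_noise is None:
                    raise ValueError("word contexts present but no word vocabulary")
                neg[~is_code_ctx] = word_noise.sample_from_uniforms(u[~is_code_ctx])
        if cfg.lr_schedule == "linear-decay":
            frac = 1.0 - (done + np.arange(n, dtype=np.float64)) / total
            lrs = cfg.initial_lr * np.maximum(frac, 0.01)
        else:
            lrs = np.full(n, cfg.initial_lr)
        _sgns_kernel(V, U, tgt, ctx, neg, lrs)
        done += n
        if epoch_callback is not None:
            epoch_callback(_epoch)
        if not (np.all(np.isfinite(V)) and np.all(np.isfinite(U))):
            raise FloatingPointError(
                "non-finite embedding entries after epoch "
                f"{_epoch}; reduce initial_lr (currently {cfg.initial_lr})"
            )


def _init_model(vocab: Vocabulary, cfg: TrainingConfig, rng: np.random.Generator) -> EmbeddingModel:
    # word2vec convention: V uniform in [-0.5/T, 0.5/T], U zero
    n = len(vocab)
    V = (rng.random((n, cfg.dim)) - 0.5) / cfg.dim
    U = np.zeros((n, cfg.dim))
    return EmbeddingModel(V=V, U=U, vocab=vocab, config=cfg)


def _pretrain_sample(n_visits: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    k = math.ceil(fraction * n_visits)
    return np.sort(rng.choice(n_visits, size=k, replace=False))


def pretrain_words(
    visits: Sequence[IndexedVisit],
    vocab: Vocabulary,
    cfg: TrainingConfig,
    model: EmbeddingModel | None = None,
    rng: np.random.Generator | None = None,
) -> EmbeddingModel:
    """Words-only pretraining on a seeded sample of visits.

    Trains word vectors with plain skip-gram over ``ceil(fraction * n)``
    sampled visits for ``cfg.pretrain_epochs``; code rows stay at their
    initialization.  Used to warm-start joint training.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = _init_model(vocab, cfg, rng)
    if cfg.pretrain_fraction == 0.0:
        return model
    idx = _pretrain_sample(len(visits), cfg.pretrain_fraction, rng)
    sample = [visits[i] for i in idx]
    streams = _build_streams(sample, cfg.window, "words_only")
    word_noise = namespace_noise(vocab, "words", cfg.noise_power) if vocab.n_words else None
    _run_sgd(
        model.V, model.U, streams, vocab, cfg, cfg.pretrain_epochs, rng,
        word_noise, None,
    )
    return model


def train(
    visits: Sequence[IndexedVisit],
    vocab: Vocabulary,
    cfg: TrainingConfig,
    epoch_callback=None,
) -> EmbeddingModel:
    """Train the embedding by SGD over per-visit (target, context) pairs.

    Visit order is reshuffled each epoch with the configured seed; every
    pair draws ``cfg.negatives`` negatives from the noise distribution of
    its context's namespace.  In ``joint`` mode a words-only pretraining
    phase (``pretrain_fraction`` > 0) precedes the joint epochs.  The
    learning rate decays linearly to 1% of its initial value over each
    phase's scheduled updates.
    """
    if not visits:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(cfg.seed)
    model = _init_model(vocab, cfg, rng)
    word_noise = namespace_noise(vocab, "words", cfg.noise_power) if vocab.n_words else None
    code_noise = namespace_noise(vocab, "codes", cfg.noise_power) if vocab.n_codes else None
    if cfg.mode == "joint" and cfg.pretrain_fraction > 0.0:
        pretrain_words(visits, vocab, cfg, model=model, rng=rng)
    streams = _build_streams(visits, cfg.window, cfg.mode)
    _run_sgd(model.V, model.U, streams, vocab, cfg, cfg.epochs, rng,
             word_noise, code_noise, epoch_callback)
    return model
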