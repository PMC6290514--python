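"""Similarity queries over the joint space, and model persistence.

Phenotype discovery is a nearest-neighbour query: given a diagnosis code,
rank all note words by cosine similarity of their input (V) vectors and
return the top k as a textual description of the condition.  Only V is
queried; U is persisted so training can resume but plays no role in
retrieval.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from jointsg.core import EmbeddingModel, TrainingConfig
from jointsg.corpus import CODE_PREFIX, Vocabulary


@dataclass
class RankedNeighbors:
    """Query token with its neighbours, best first."""

    query: str
    neighbors: list[tuple[str, float]]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonzero vectors, in [-1, 1]."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _resolve_token(model: EmbeddingModel, token: str) -> int:
    vocab = model.vocab
    if token in vocab._word_id:
        return vocab._word_id[token]
    prefixed = token if token.startswith(CODE_PREFIX) else CODE_PREFIX + token
    if prefixed in vocab._code_id:
        return vocab._code_id[prefixed]
    bare = [c.removeprefix(CODE_PREFIX) for c in vocab.codes]
    close = difflib.get_close_matches(token.removeprefix(CODE_PREFIX), bare + vocab.words, n=5)
    raise KeyError(f"unknown token {token!r}; closest known tokens: {close}")


def nearest_neighbors(
    model: EmbeddingModel, token: str, k: int = 15, namespace: str = "both"
) -> RankedNeighbors:
    """Top-k tokens by cosine of V rows, restricted to a namespace.

    ``namespace`` is ``words``, ``codes`` or ``both``.  The query token is
    never its own neighbour; ties in similarity break lexicographically.
    A k beyond the namespace size returns every candidate.
    """
    if namespace not in ("words", "codes", "both"):
        raise ValueError("namespace must be 'words', 'codes' or 'both'")
    qid = _resolve_token(model, token)
    vocab = model.vocab
    lo = 0 if namespace in ("words", "both") else vocab.n_words
    hi = len(vocab) if namespace in ("codes", "both") else vocab.n_words
    V = model.V
    q = V[qid]
    qn = float(np.linalg.norm(q))
    if qn == 0.0:
        raise ValueError(f"query {token!r} has a zero vector")
    block = V[lo:hi]
    norms = np.linalg.norm(block, axis=1)
    norms[norms == 0.0] = np.inf  # zero vectors can never rank
    sims = block @ q / (norms * qn)
    cand = [
        (float(sims[i - lo]), vocab.id_to_token(i))
        for i in range(lo, hi)
        if i != qid
    ]
    cand.sort(key=lambda sc: (-sc[0], sc[1]))
    top = cand[: min(k, len(cand))]
    return RankedNeighbors(query=token, neighbors=[(t, s) for s, t in top])


def nearest_words_to_code(model: EmbeddingModel, code: str, k: int = 15) -> RankedNeighbors:
    """The phenotype-discovery query: nearest k words to a diagnosis code."""
    return nearest_neighbors(model, code, k=k, namespace="words")


# ---------------------------------------------------------------------------
# Persistence: word2vec text format, one file per matrix


def _write_w2v(path: Path, tokens: list[str], M: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{M.shape[0]} {M.shape[1]}\n")
        for tok, row in zip(tokens, M):
            fh.write(tok + " " + " ".join(repr(float(x)) for x in row) + "\n")


def _read_w2v(path: Path) -> tuple[list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        M = np.empty((n, dim))
        for i in range(n):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated file: expected {n} rows, got {i}")
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: row {i} has {len(parts) - 1} values, expected {dim}")
            tokens.append(parts[0])
            M[i] = [float(x) for x in parts[1:]]
    return tokens, M


def save_model(model: EmbeddingModel, directory: str | Path) -> None:
    """Write V, U, vocabulary and a config snapshot to a directory.

    Matrices go to ``vectors_v.txt`` / ``vectors_u.txt`` in word2vec text
    format with namespaced tokens; the vocabulary to ``vocab.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tokens = [model.vocab.id_to_raw_token(i) for i in range(len(model.vocab))]
    _write_w2v(directory / "vectors_v.txt", tokens, model.V)
    _write_w2v(directory / "vectors_u.txt", tokens, model.U)
    model.vocab.save_tsv(directory / "vocab.tsv")
    cfg = model.config.__dict__ if model.config is not None else None
    (directory / "config.json").write_text(json.dumps(cfg, indent=2), "utf-8")


def load_model(directory: str | Path) -> EmbeddingModel:
    """Load a model saved by :func:`save_model`; validates shapes and tokens."""
    directory = Path(directory)
    vocab = Vocabulary.load_tsv(directory / "vocab.tsv")
    tokens_v, V = _read_w2v(directory / "vectors_v.txt")
    tokens_u, U = _read_w2v(directory / "vectors_u.txt")
    expected = [vocab.id_to_raw_token(i) for i in range(len(vocab))]
    if tokens_v != expected or tokens_u != expected:
        raise ValueError(f"{directory}: vector tokens do not match the vocabulary")
    if V.shape != U.shape:
        raise ValueError(f"{directory}: V shape {V.shape} != U shape {U.shape}")
    cfg_path = directory / "config.json"
    config = None
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text("utf-8"))
        if raw is not None:
            config = TrainingConfig(**raw)
    return EmbeddingModel(V=V, U=U, vocab=vocab, config=config)
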