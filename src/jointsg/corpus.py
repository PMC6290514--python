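"""Reading, tokenizing, filtering and indexing of visit data.

A *visit* is one hospital admission: an unordered set of ICD-9 diagnosis
codes plus the words of its clinical notes.  Preprocessing follows the
standard EHR-embedding recipe: lowercase, strip digit-bearing tokens and
stopwords, optionally keep only dictionary words, group ICD-9 codes by
their first three characters, and drop tokens under a frequency threshold
(words occurring fewer than 50 times, codes fewer than 5 times, by
default).
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Namespace prefix attached to every code token so that no code string can
#: collide with a note word ("570" the code vs "570" a stray token).
CODE_PREFIX = "ICD9:"

_TOKEN_SPLIT = re.compile(r"[^a-zA-Z0-9]+")
_HAS_DIGIT = re.compile(r"\d")


def default_stopwords() -> frozenset[str]:
    """The English stopword list shipped with the package."""
    text = resources.files("jointsg.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


@dataclass(frozen=True)
class PreprocessConfig:
    """Corpus-cleaning knobs.

    ``min_word_count`` / ``min_code_count`` are inclusive-keep thresholds:
    a token is kept iff its corpus frequency is >= the threshold (i.e.
    tokens whose frequency is *less than* the threshold are removed).
    ``dictionary_words`` switches between the two vocabulary regimes: when
    given, tokens absent from the word list are dropped (typo filtering for
    phenotype retrieval); when ``None`` every surviving token is kept,
    which is the regime used for treatment discovery.
    """

    min_word_count: int = 50
    min_code_count: int = 5
    group_codes: bool = True
    dictionary_words: frozenset[str] | None = None
    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    lowercase: bool = True

    def __post_init__(self) -> None:
        if self.min_word_count < 1 or self.min_code_count < 1:
            raise ValueError("frequency thresholds must be >= 1")


@dataclass
class Visit:
    """One admission: code set ``D`` plus ordered note word sequences ``N``.

    ``notes`` is a list of per-note token sequences; keeping notes separate
    lets context windows stop at note boundaries.  Before tokenization the
    entries are raw strings.
    """

    patient_id: str
    visit_id: str
    admit_time: str
    codes: set[str]
    notes: list

    @property
    def words(self) -> list[str]:
        """All note tokens in chronological order, note boundaries dropped."""
        out: list[str] = []
        for note in self.notes:
            out.extend(note)
        return out


@dataclass
class IndexedVisit:
    """A visit after vocabulary lookup: integer token ids only."""

    patient_id: str
    visit_id: str
    admit_time: str
    code_ids: np.ndarray      # sorted unique ids in the code id range
    note_ids: list[np.ndarray]  # one int array per note, order preserved

    @property
    def word_ids(self) -> np.ndarray:
        if not self.note_ids:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(self.note_ids)


class Vocabulary:
    """Two namespaced token inventories sharing one id space.

    Words get ids ``[0, |W|)`` and codes ids ``[|W|, |W|+|C|)``; within
    each namespace ids are assigned by descending corpus count with
    lexicographic tie-breaking, so indexing is a pure function of the
    corpus and configuration.
    """

    def __init__(self, word_counts: Mapping[str, int], code_counts: Mapping[str, int]):
        self.word_counts: dict[str, int] = dict(word_counts)
        self.code_counts: dict[str, int] = dict(code_counts)
        self.words: list[str] = sorted(self.word_counts, key=lambda w: (-self.word_counts[w], w))
        self.codes: list[str] = sorted(self.code_counts, key=lambda c: (-self.code_counts[c], c))
        self._word_id = {w: i for i, w in enumerate(self.words)}
        off = len(self.words)
        self._code_id = {c: off + i for i, c in enumerate(self.codes)}

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    def __len__(self) -> int:
        return self.n_words + self.n_codes

    def word_id(self, token: str) -> int:
        return self._word_id[token]

    def code_id(self, token: str) -> int:
        """Id of a code token; accepts the token with or without prefix."""
        if not token.startswith(CODE_PREFIX):
            token = CODE_PREFIX + token
        return self._code_id[token]

    def __contains__(self, token: str) -> bool:
        return token in self._word_id or token in self._code_id or (
            CODE_PREFIX + token in self._code_id
        )

    def is_code_id(self, token_id: int) -> bool:
        return token_id >= self.n_words

    def id_to_token(self, token_id: int) -> str:
        """Token string for an id; the code namespace prefix is stripped."""
        if token_id < self.n_words:
            return self.words[token_id]
        return self.codes[token_id - self.n_words].removeprefix(CODE_PREFIX)

    def id_to_raw_token(self, token_id: int) -> str:
        if token_id < self.n_words:
            return self.words[token_id]
        return self.codes[token_id - self.n_words]

    def id_counts(self) -> np.ndarray:
        """Corpus count per token id, words then codes."""
        out = np.empty(len(self), dtype=np.int64)
        for w, i in self._word_id.items():
            out[i] = self.word_counts[w]
        for c, i in self._code_id.items():
            out[i] = self.code_counts[c]
        return out

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i in range(len(self)):
                tok = self.id_to_raw_token(i)
                cnt = self.word_counts[tok] if i < self.n_words else self.code_counts[tok]
                fh.write(f"{tok}\t{i}\t{cnt}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Vocabulary":
        word_counts: dict[str, int] = {}
        code_counts: dict[str, int] = {}
        rows: list[tuple[str, int, int]] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}: malformed vocabulary row at line {lineno}")
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        for tok, _i, cnt in rows:
            (code_counts if tok.startswith(CODE_PREFIX) else word_counts)[tok] = cnt
        vocab = cls(word_counts, code_counts)
        for tok, i, _cnt in rows:
            got = vocab.code_id(tok) if tok.startswith(CODE_PREFIX) else vocab.word_id(tok)
            if got != i:
                raise ValueError(
                    f"{path}: id mismatch for {tok!r}: stored {i}, rebuilt {got}"
                )
        return vocab


def read_visits(path: str | Path) -> list[Visit]:
    """Read visits from a JSON-lines file, one record per line.

    Each record carries ``patient_id``, ``visit_id``, ``admit_time``,
    ``codes`` (list of raw code strings) and ``notes``.  A note entry may
    be a raw string (to be tokenized later) or a list of tokens
    (pre-tokenized input); strings and token lists may be mixed.
    """
    required = ("patient_id", "visit_id", "admit_time", "codes", "notes")
    visits: list[Visit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON at line {lineno}: {exc}") from exc
            missing = [k for k in required if k not in rec]
            if missing:
                raise KeyError(
                    f"{path}: line {lineno} missing field(s) {', '.join(missing)}"
                )
            visits.append(
                Visit(
                    patient_id=str(rec["patient_id"]),
                    visit_id=str(rec["visit_id"]),
                    admit_time=str(rec["admit_time"]),
                    codes=set(map(str, rec["codes"])),
                    notes=list(rec["notes"]),
                )
            )
    return visits


def visits_from_records(records: Iterable[Mapping]) -> list[Visit]:
    """Build raw visits from in-memory records (same schema as the JSONL)."""
    return [
        Visit(
            patient_id=str(r["patient_id"]),
            visit_id=str(r["visit_id"]),
            admit_time=str(r["admit_time"]),
            codes=set(map(str, r["codes"])),
            notes=list(r["notes"]),
        )
        for r in records
    ]


def tokenize_note(raw_text: str, cfg: PreprocessConfig) -> list[str]:
    """Clean one note into a word-token sequence.

    Splits on any non-alphanumeric character, lowercases, drops every token
    containing a digit, drops stopwords, and — when a dictionary word list
    is configured — drops tokens absent from it.
    """
    text = raw_text.lower() if cfg.lowercase else raw_text
    out = []
    for tok in _TOKEN_SPLIT.split(text):
        if not tok or _HAS_DIGIT.search(tok):
            continue
        if tok in cfg.stopword_list:
            continue
        if cfg.dictionary_words is not None and tok not in cfg.dictionary_words:
            continue
        out.append(tok)
    return out


def group_icd9(code: str) -> str:
    """Group a raw ICD-9 code by its first three characters.

    ``"2901"`` (presenile dementia) and its siblings all map to ``"290"``
    (dementias); V- and E-codes are grouped by the same uniform rule.  The
    returned token carries the code namespace prefix.  Codes shorter than
    three characters after cleaning are returned whole with a warning.
    """
    cleaned = code.strip().replace(".", "").replace(" ", "")
    if not cleaned:
        raise ValueError("empty ICD-9 code")
    if len(cleaned) < 3:
        logger.warning("ICD-9 code %r shorter than 3 characters; kept whole", code)
        return CODE_PREFIX + cleaned
    return CODE_PREFIX + cleaned[:3]


def preprocess_visits(visits: Iterable[Visit], cfg: PreprocessConfig) -> list[Visit]:
    """Tokenize raw notes and group/namespace codes, visit by visit.

    Code sets are deduplicated after grouping; notes already supplied as
    token lists pass through tokenization untouched apart from filtering
    rules not applying (they are trusted as preprocessed).
    """
    out: list[Visit] = []
    for v in visits:
        notes = [
            list(n) if isinstance(n, (list, tuple)) else tokenize_note(n, cfg)
            for n in v.notes
        ]
        if cfg.group_codes:
            codes = {group_icd9(c) for c in v.codes}
        else:
            codes = {c if c.startswith(CODE_PREFIX) else CODE_PREFIX + c for c in v.codes}
        out.append(Visit(v.patient_id, v.visit_id, v.admit_time, codes, notes))
    return out


def build_vocabulary(visits: Sequence[Visit], cfg: PreprocessConfig) -> Vocabulary:
    """Count tokens over the whole corpus and apply frequency thresholds.

    Words are counted with multiplicity over all notes; codes once per
    visit (a visit's code set has no duplicates).  Tokens with count below
    the threshold are excluded; keeping is inclusive (count >= threshold).
    """
    word_counts: Counter[str] = Counter()
    code_counts: Counter[str] = Counter()
    for v in visits:
        for note in v.notes:
            word_counts.update(note)
        code_counts.update(v.codes)
    kept_words = {w: c for w, c in word_counts.items() if c >= cfg.min_word_count}
    kept_codes = {c: n for c, n in code_counts.items() if n >= cfg.min_code_count}
    if not kept_words and not kept_codes:
        raise ValueError(
            "no token survives the frequency thresholds "
            f"(min_word_count={cfg.min_word_count}, min_code_count={cfg.min_code_count})"
        )
    return Vocabulary(kept_words, kept_codes)


def prepare_corpus(
    visits: Sequence[Visit], cfg: PreprocessConfig
) -> tuple[list[IndexedVisit], Vocabulary]:
    """Full preprocessing pipeline: tokenize, group, count, filter, index."""
    processed = preprocess_visits(visits, cfg)
    vocab = build_vocabulary(processed, cfg)
    return index_visits(processed, vocab), vocab


def index_visits(visits: Iterable[Visit], vocab: Vocabulary) -> list[IndexedVisit]:
    """Map tokens to ids, dropping out-of-vocabulary tokens.

    Word order within each note is preserved; visits left with neither
    codes nor words are dropped (they carry no training signal).
    """
    out: list[IndexedVisit] = []
    for v in visits:
        code_ids = sorted(
            vocab.code_id(c) for c in v.codes if CODE_PREFIX + c.removeprefix(CODE_PREFIX) in vocab._code_id
        )
        note_ids = []
        for note in v.notes:
            ids = np.array(
                [vocab.word_id(w) for w in note if w in vocab._word_id], dtype=np.int64
            )
            if ids.size:
                note_ids.append(ids)
        if not code_ids and not note_ids:
            continue
        out.append(
            IndexedVisit(
                patient_id=v.patient_id,
                visit_id=v.visit_id,
                admit_time=v.admit_time,
                code_ids=np.array(code_ids, dtype=np.int64),
                note_ids=note_ids,
            )
        )
    return out
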