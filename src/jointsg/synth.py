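"""Synthetic EHR corpora with known latent structure.

Real visit data pairing diagnosis codes with clinical notes is access
restricted, so testing and demonstration run on generated cohorts with a
planted topic structure: each latent "condition" (topic) owns a pool of
diagnosis codes and a pool of note words; a patient's visits follow a
sticky Markov chain over topics, and each visit draws its code set from
the topic's code pool and a note mixing topic words with shared noise
words.  The generator is a pure function of its config (seed included),
and its ground truth (token -> topic) makes retrieval and prediction
quality measurable without experts.

It makes no attempt to mimic real clinical language, note lengths, or the
heavy-tailed ICD-9 frequency distribution.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from jointsg.core import EmbeddingModel
from jointsg.query import nearest_words_to_code


def _letters(i: int, width: int = 2) -> str:
    out = []
    for _ in range(width):
        out.append(chr(97 + i % 26))
        i //= 26
    return "".join(reversed(out))


@dataclass(frozen=True)
class SynthConfig:
    """Cohort shape and topic structure of the generator.

    Defaults give a 500-patient cohort over 5 conditions with 8 codes and
    40 words per condition, 40 shared noise words, ~30-word notes of which
    20% are noise, and a 0.8 probability that the next visit keeps the
    current condition.
    """

    n_patients: int = 500
    visits_min: int = 2
    visits_max: int = 4
    n_topics: int = 5
    codes_per_topic: int = 8
    words_per_topic: int = 40
    n_noise_words: int = 40
    codes_per_visit: int = 4
    note_length: int = 30
    noise_word_fraction: float = 0.2
    topic_transition_stickiness: float = 0.8
    seed: int = 0
    long_codes: bool = False  # emit 4-5 character raw codes to exercise grouping

    def __post_init__(self) -> None:
        if min(self.n_patients, self.visits_min, self.n_topics, self.codes_per_topic,
               self.words_per_topic, self.codes_per_visit, self.note_length) < 1:
            raise ValueError("all counts must be >= 1")
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max must be >= visits_min")
        if self.codes_per_visit > self.codes_per_topic:
            raise ValueError("codes_per_visit cannot exceed codes_per_topic")
        if not 0.0 <= self.noise_word_fraction < 1.0:
            raise ValueError("noise_word_fraction must be in [0, 1)")
        if not 0.0 <= self.topic_transition_stickiness <= 1.0:
            raise ValueError("stickiness must be in [0, 1]")
        if self.n_topics * self.codes_per_topic > 900:
            raise ValueError("too many codes for 3-digit code strings")


@dataclass
class GroundTruth:
    """Planted structure: token -> topic, and each patient's topic path."""

    word_topic: dict[str, int]
    code_topic: dict[str, int]
    patient_topics: dict[str, list[int]]
    noise_words: set[str] = field(default_factory=set)


def topic_codes(cfg: SynthConfig, topic: int) -> list[str]:
    """Grouped (3-digit) code strings owned by a topic."""
    base = 100 + topic * cfg.codes_per_topic
    return [str(base + j) for j in range(cfg.codes_per_topic)]


def topic_words(cfg: SynthConfig, topic: int) -> list[str]:
    return [f"w{_letters(topic, 1)}{_letters(j)}" for j in range(cfg.words_per_topic)]


def noise_words(cfg: SynthConfig) -> list[str]:
    return [f"zz{_letters(j)}" for j in range(cfg.n_noise_words)]


def generate_corpus(cfg: SynthConfig) -> tuple[list[dict], GroundTruth]:
    """Generate JSON-ready visit records plus their ground truth.

    Each patient's first-visit topic is uniform; later visits keep the
    topic with probability ``topic_transition_stickiness`` and otherwise
    redraw uniformly.  Admission times are strictly increasing per
    patient.  Records match the visit-reader schema: ``patient_id``,
    ``visit_id``, ``admit_time``, ``codes``, ``notes``.
    """
    rng = np.random.default_rng(cfg.seed)
    words_by_topic = [topic_words(cfg, t) for t in range(cfg.n_topics)]
    codes_by_topic = [topic_codes(cfg, t) for t in range(cfg.n_topics)]
    noise_pool = noise_words(cfg)
    truth = GroundTruth(
        word_topic={w: t for t in range(cfg.n_topics) for w in words_by_topic[t]},
        code_topic={c: t for t in range(cfg.n_topics) for c in codes_by_topic[t]},
        patient_topics={},
        noise_words=set(noise_pool),
    )
    t0 = datetime.datetime(2020, 1, 1)
    records: list[dict] = []
    for p in range(cfg.n_patients):
        pid = f"p{p:05d}"
        n_visits = int(rng.integers(cfg.visits_min, cfg.visits_max + 1))
        topics: list[int] = []
        topic = int(rng.integers(cfg.n_topics))
        for v in range(n_visits):
            if v > 0 and rng.random() >= cfg.topic_transition_stickiness:
                topic = int(rng.integers(cfg.n_topics))
            topics.append(topic)
            codes = list(rng.choice(codes_by_topic[topic], size=cfg.codes_per_visit,
                                    replace=False))
            if cfg.long_codes:
                codes = [c + "".join(map(str, rng.integers(0, 10, size=int(rng.integers(1, 3)))))
                         for c in codes]
            note_tokens = []
            for _ in range(cfg.note_length):
                if rng.random() < cfg.noise_word_fraction:
                    note_tokens.append(noise_pool[int(rng.integers(cfg.n_noise_words))])
                else:
                    note_tokens.append(
                        words_by_topic[topic][int(rng.integers(cfg.words_per_topic))]
                    )
            admit = (t0 + datetime.timedelta(days=int(v))).isoformat()
            records.append(
                {
                    "patient_id": pid,
                    "visit_id": f"{pid}v{v}",
                    "admit_time": admit,
                    "codes": codes,
                    "notes": [" ".join(note_tokens)],
                }
            )
        truth.patient_topics[pid] = topics
    return records, truth


def write_jsonl(records: Sequence[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "word_topic": truth.word_topic,
        "code_topic": truth.code_topic,
        "patient_topics": truth.patient_topics,
        "noise_words": sorted(truth.noise_words),
    }
    Path(path).write_text(json.dumps(payload, indent=1), "utf-8")


def load_truth(path: str | Path) -> GroundTruth:
    raw = json.loads(Path(path).read_text("utf-8"))
    return GroundTruth(
        word_topic={k: int(v) for k, v in raw["word_topic"].items()},
        code_topic={k: int(v) for k, v in raw["code_topic"].items()},
        patient_topics={k: list(map(int, v)) for k, v in raw["patient_topics"].items()},
        noise_words=set(raw.get("noise_words", [])),
    )


def retrieval_precision(model: EmbeddingModel, truth: GroundTruth, k: int = 15) -> float:
    """Topic purity of phenotype retrieval, macro-averaged over codes.

    For each code in the model's vocabulary with a known topic, the
    fraction of its k nearest words that belong to the same topic (noise
    words and other topics' words count as misses); averaged over codes.
    """
    precisions = []
    for raw_code in model.vocab.codes:
        code = raw_code.split(":", 1)[-1]
        topic = truth.code_topic.get(code)
        if topic is None:
            continue
        hits = nearest_words_to_code(model, code, k=k)
        same = sum(1 for w, _s in hits.neighbors if truth.word_topic.get(w) == topic)
        precisions.append(same / max(len(hits.neighbors), 1))
    if not precisions:
        raise ValueError("no model code has a known topic in the ground truth")
    return float(np.mean(precisions))
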