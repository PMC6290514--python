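import numpy as np
import pytest

from jointsg import (
    PreprocessConfig,
    SynthConfig,
    TrainingConfig,
    generate_corpus,
    train,
)
from jointsg.corpus import prepare_corpus, visits_from_records

#: Preprocessing thresholds sized for small test corpora.
SMALL_PCFG = PreprocessConfig(min_word_count=2, min_code_count=1)


@pytest.fixture(scope="session")
def tiny_corpus():
    """A 40-patient, 2-topic corpus small enough for fast training."""
    cfg = SynthConfig(
        n_patients=40, n_topics=2, codes_per_topic=4, words_per_topic=10,
        n_noise_words=6, codes_per_visit=2, note_length=12, seed=11,
    )
    records, truth = generate_corpus(cfg)
    indexed, vocab = prepare_corpus(visits_from_records(records), SMALL_PCFG)
    return {"cfg": cfg, "records": records, "truth": truth,
            "visits": indexed, "vocab": vocab}


@pytest.fixture(scope="session")
def tiny_model(tiny_corpus):
    """Joint model trained on the tiny corpus (dim 16, 10 epochs)."""
    tcfg = TrainingConfig(dim=16, epochs=10, window=3, seed=11,
                          pretrain_fraction=0.1, pretrain_epochs=2)
    model = train(tiny_corpus["visits"], tiny_corpus["vocab"], tcfg)
    return model


@pytest.fixture(scope="session")
def cohort():
    """The full-size synthetic cohort used by the end-to-end checks.

    500 patients, 5 latent conditions with 8 codes and 40 words each, 20%
    noise words, sticky (0.8) visit-to-visit condition transitions — and a
    joint model trained for 30 epochs at dim 50.
    """
    scfg = SynthConfig(seed=20260)
    records, truth = generate_corpus(scfg)
    indexed, vocab = prepare_corpus(visits_from_records(records), PreprocessConfig())
    tcfg = TrainingConfig(dim=50, epochs=30, seed=20260)
    model = train(indexed, vocab, tcfg)
    return {"scfg": scfg, "truth": truth, "visits": indexed,
            "vocab": vocab, "model": model, "tcfg": tcfg}


@pytest.fixture
def rng():
    return np.random.default_rng(123)
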