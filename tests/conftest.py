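"""Shared fixtures: small synthetic corpora and trained models.

Everything is generated programmatically at test time; the expensive
trained-predictor fixture is session-scoped so the end-to-end checks
share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from espred import predictors, spectra_topics, synthetic_data


SMALL_FAMILIES = {"C5H12O": 5, "C6H14O": 5, "C5H13N": 5, "C6H14O2": 5}


@pytest.fixture(scope="session")
def small_config() -> synthetic_data.SyntheticConfig:
    return synthetic_data.SyntheticConfig(
        families=dict(SMALL_FAMILIES), energies=(10.0, 40.0), sigma=0.0,
        seed=7, fp_bits=512)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return synthetic_data.generate_corpus(small_config)


@pytest.fixture(scope="session")
def study_corpus():
    """The noise-free study corpus: 30 formula families of 10 isomers each."""
    cfg = synthetic_data.SyntheticConfig(sigma=0.0, seed=0, fp_bits=1024)
    return cfg, synthetic_data.generate_corpus(cfg)


@pytest.fixture(scope="session")
def trained_predictors(study_corpus):
    """Both predictors trained on the study corpus, plus the topic model."""
    cfg, corpus = study_corpus
    Y = np.array([s.intensities for _, s in corpus.pairs_in_split("train")])
    topics = spectra_topics.fit_lda(Y, n_topics=10, seed=0, max_iter=15)
    mlp = predictors.train_predictor(corpus, topics, predictors.PredictorConfig(
        encoder="fingerprint", fp_bits=1024, n_topics=10,
        epochs=30, eval_every=10, seed=0))
    gnn = predictors.train_predictor(corpus, topics, predictors.PredictorConfig(
        encoder="graph", latent_dim=128, enc_hidden=64, n_topics=10,
        epochs=40, eval_every=10, lr=2e-3, seed=0))
    return {"corpus": corpus, "topics": topics, "mlp": mlp, "gnn": gnn}


class TablePredictor:
    """Duck-typed predictor returning preassigned spectra per molecule id."""

    def __init__(self, table: dict[str, np.ndarray]):
        self.table = table

    def predict_spectra(self, records, settings, precursor_mzs):
        return np.array([self.table[r.id] for r in records])


@pytest.fixture(scope="session")
def table_predictor_cls():
    return TablePredictor
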