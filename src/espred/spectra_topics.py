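"""Spectral similarity, spectral loss, and the LDA topic model.

A binned spectrum is treated as a document whose words are m/z bins and
whose word counts are (rescaled, rounded) bin intensities; latent
Dirichlet allocation over the spectrum corpus then yields "spectral
motifs" — topics that group co-occurring peaks. The per-spectrum topic
distribution is used as a fixed auxiliary target during multi-task
predictor training: reproducing it regularizes the molecular latent
space toward peak co-occurrence structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EPS = 1e-8
#: intensity -> pseudo-count scale: max bin of each spectrum maps to this count
DEFAULT_COUNT_SCALE = 100
DEFAULT_N_TOPICS = 30


def cosine_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Spectral loss: negative cosine similarity, in [-1, 0] for non-negative data.

    A zero-norm prediction is defined to return 0.0 (the worst possible
    value against a non-negative target). The true spectrum ``y`` must
    have positive norm.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    ny = np.linalg.norm(y)
    if ny == 0:
        raise ValueError("target spectrum has zero norm")
    nh = np.linalg.norm(y_hat)
    if nh == 0:
        return 0.0
    return float(-(y_hat @ y) / (nh * ny))


def cosine_similarity(y_hat: np.ndarray, y: np.ndarray) -> float:
    """cos(y_hat, y); zero-norm prediction scores 0."""
    return -cosine_loss(y_hat, y)


def spectra_to_counts(spectra: np.ndarray, scale: int = DEFAULT_COUNT_SCALE) -> np.ndarray:
    """Convert normalized intensity vectors to count-like data for LDA.

    Each spectrum is rescaled so its maximum bin equals ``scale``, then
    rounded to integers; bins that round to zero are dropped. The map is
    scale-invariant, so L2-normalized and raw spectra give the same counts.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    maxes = spectra.max(axis=1, keepdims=True)
    if (maxes <= 0).any():
        raise ValueError("every spectrum must have a positive maximum intensity")
    return np.rint(spectra / maxes * scale).astype(np.int64)


@dataclass
class TopicModel:
    """A fitted LDA over the binned-spectrum corpus.

    ``topic_word`` is T x P, each row a probability distribution over the
    P m/z-bin vocabulary (rows sum to 1).
    """

    n_topics: int
    topic_word: np.ndarray
    count_scale: int
    seed: int
    n_fit_spectra: int
    _lda: object | None = None   # fitted sklearn model, needed for inference

    def __post_init__(self):
        if self.n_topics < 2:
            raise ValueError("need at least 2 topics")
        rowsums = self.topic_word.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise ValueError("topic-word rows must sum to 1")

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "topic_word.npy", self.topic_word)
        np.save(out / "components.npy", np.asarray(self._lda.components_))
        (out / "topics_config.json").write_text(json.dumps({
            "n_topics": self.n_topics, "count_scale": self.count_scale,
            "seed": self.seed, "n_fit_spectra": self.n_fit_spectra,
        }, indent=2))

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "TopicModel":
        from sklearn.decomposition import LatentDirichletAllocation

        bundle = Path(bundle_dir)
        cfg = json.loads((bundle / "topics_config.json").read_text())
        topic_word = np.load(bundle / "topic_word.npy")
        components = np.load(bundle / "components.npy")
        lda = LatentDirichletAllocation(n_components=cfg["n_topics"],
                                        random_state=cfg["seed"])
        lda.components_ = components
        lda.exp_dirichlet_component_ = np.exp(
            _dirichlet_expectation(components))
        lda.n_features_in_ = components.shape[1]
        lda.doc_topic_prior_ = 1.0 / cfg["n_topics"]
        return cls(n_topics=cfg["n_topics"], topic_word=topic_word,
                   count_scale=cfg["count_scale"], seed=cfg["seed"],
                   n_fit_spectra=cfg["n_fit_spectra"], _lda=lda)


def _dirichlet_expectation(alpha: np.ndarray) -> np.ndarray:
    from scipy.special import psi

    return psi(alpha) - psi(alpha.sum(axis=1))[:, None]


def fit_lda(spectra: np.ndarray, n_topics: int = DEFAULT_N_TOPICS, seed: int = 0,
            count_scale: int = DEFAULT_COUNT_SCALE, max_iter: int = 30) -> TopicModel:
    """Fit LDA on a matrix of binned spectra (rows = spectra, columns = bins).

    Fitting is restricted by the caller to the training split so topic
    targets never leak held-out information into predictor training.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if n_topics < 2:
        raise ValueError("need at least 2 topics")
    if spectra.shape[0] < n_topics:
        raise ValueError(f"need at least {n_topics} spectra to fit {n_topics} topics")
    counts = spectra_to_counts(spectra, scale=count_scale)
    lda = LatentDirichletAllocation(n_components=n_topics, random_state=seed,
                                    max_iter=max_iter, learning_method="batch")
    lda.fit(counts)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(n_topics=n_topics, topic_word=topic_word,
                      count_scale=count_scale, seed=seed,
                      n_fit_spectra=spectra.shape[0], _lda=lda)


def topic_distribution(model: TopicModel, y: np.ndarray) -> np.ndarray:
    """Posterior topic mixture for one spectrum (or a matrix of spectra).

    Returns a length-T simplex vector (rows sum to 1 for matrix input).
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    counts = spectra_to_counts(np.atleast_2d(y), scale=model.count_scale)
    dist = model._lda.transform(counts)
    dist = dist / dist.sum(axis=1, keepdims=True)
    return dist[0] if single else dist


def aux_topic_loss(r_hat: np.ndarray, r: np.ndarray) -> float:
    """Cross-entropy of the predicted topic distribution against the target.

    -sum_t r_t log(r_hat_t), with r_hat clamped at EPS. Always at least
    the entropy of r (Gibbs inequality), with equality at r_hat = r.
    """
    r_hat = np.asarray(r_hat, dtype=float)
    r = np.asarray(r, dtype=float)
    if r_hat.shape != r.shape:
        raise ValueError(f"length mismatch: {r_hat.shape} vs {r.shape}")
    return float(-(r * np.log(np.clip(r_hat, EPS, None))).sum())


def entropy(r: np.ndarray) -> float:
    """Shannon entropy of a topic distribution (nats)."""
    r = np.asarray(r, dtype=float)
    nz = r[r > 0]
    return float(-(nz * np.log(nz)).sum())
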