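"""Phase-2 ensemble: rank labels, SMAPE weights, classifier, combined inference.

For every training query spectrum, both base predictors rank the target
within its formula stratum. The better-ranking model defines a binary
label (MLP wins ties), and the symmetric mean absolute percentage error
of the two ranks, gamma = |R_gnn - R_mlp| / (R_gnn + R_mlp), weights the
example: queries where one model decisively outranks the other matter
most, and exact ties (gamma = 0) drop out of the loss entirely.

A small classifier f_ENS maps the raw binned query spectrum to the
probability that the fingerprint (MLP) predictor is the better ranker.
At annotation time that probability softly blends the two predicted
spectra per candidate, y = p * y_mlp + (1 - p) * y_gnn, and ranking
proceeds by cosine as usual.

Two ablations are exposed as configuration switches: labels/weights
derived from spectral losses instead of ranks (ESP-SL), and uniform
example weights (ESP-RU).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor
from .chemdata import PairedCorpus, Spectrum, stratify_by_formula
from .ranking import CandidateSet, RankResult, score_candidates

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleLabel:
    """Which base model ranked a query better, and how decisively."""

    d_mlp: int
    gamma: float
    rank_mlp: int
    rank_gnn: int

    @property
    def d_gnn(self) -> int:
        return 1 - self.d_mlp


def make_labels(rank_mlp: int, rank_gnn: int) -> EnsembleLabel:
    """Binary winner label (MLP wins ties) and SMAPE importance weight."""
    if rank_mlp < 1 or rank_gnn < 1:
        raise ValueError("ranks must be positive integers")
    d_mlp = 1 if rank_mlp <= rank_gnn else 0
    gamma = abs(rank_gnn - rank_mlp) / (rank_gnn + rank_mlp)
    return EnsembleLabel(d_mlp=d_mlp, gamma=gamma,
                         rank_mlp=rank_mlp, rank_gnn=rank_gnn)


@dataclass
class TrainingRow:
    """One labeled ensemble-training example."""

    spectrum: Spectrum
    label: EnsembleLabel
    loss_mlp: float      # target's own spectral loss under each model
    loss_gnn: float


def build_training_table(corpus: PairedCorpus, mlp, gnn,
                         split: str = "train") -> list[TrainingRow]:
    """One labeled row per query spectrum in formula strata of size >= 2.

    Both base models rank each query's target within its stratum; strata
    of size 1 have empty candidate sets and are skipped (logged).
    """
    strata = stratify_by_formula(corpus, split=split)
    usable = {f: mids for f, mids in strata.items() if len(mids) >= 2}
    skipped = len(strata) - len(usable)
    if skipped:
        logger.info("build_training_table: skipped %d singleton strata", skipped)
    if not usable:
        raise ValueError("no formula stratum of size >= 2: ensemble untrainable")

    formula_of = {mid: corpus.molecules[mid].formula for mid in corpus.molecules}
    rows: list[TrainingRow] = []
    for mid, spec in corpus.pairs_in_split(split):
        mids = usable.get(formula_of[mid])
        if mids is None:
            continue
        members = [corpus.molecules[m] for m in mids]
        cset = CandidateSet(query=spec, target_id=mid, candidates=members)
        res_mlp = score_candidates(cset, mlp, predictor="mlp")
        res_gnn = score_candidates(cset, gnn, predictor="gnn")
        rows.append(TrainingRow(
            spectrum=spec,
            label=make_labels(res_mlp.target_rank, res_gnn.target_rank),
            loss_mlp=-res_mlp.scores[mid],
            loss_gnn=-res_gnn.scores[mid],
        ))
    return rows


@dataclass
class EnsembleConfig:
    n_bins: int = 1000
    hidden: tuple[int, int] = (128, 32)
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 256
    seed: int = 0
    val_fraction: float = 0.1
    label_source: str = "rank"       # "rank" | "spectral_loss"  (ESP-SL ablation)
    weighting: str = "smape"         # "smape" | "uniform"       (ESP-RU ablation)


def table_to_arrays(rows: list[TrainingRow], config: EnsembleConfig
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve the configured label source and weighting into (X, d, gamma)."""
    X = np.array([r.spectrum.intensities for r in rows])
    if config.label_source == "rank":
        d = np.array([r.label.d_mlp for r in rows], dtype=float)
        gamma = np.array([r.label.gamma for r in rows])
    elif config.label_source == "spectral_loss":
        d = np.array([1.0 if r.loss_mlp <= r.loss_gnn else 0.0 for r in rows])
        gamma = np.array([abs(r.loss_gnn - r.loss_mlp) /
                          (abs(r.loss_gnn) + abs(r.loss_mlp) + 1e-12) for r in rows])
    else:
        raise ValueError(f"unknown label source {config.label_source!r}")
    if config.weighting == "uniform":
        gamma = np.ones(len(rows))
    elif config.weighting != "smape":
        raise ValueError(f"unknown weighting {config.weighting!r}")
    return X, d, gamma


class EnsembleModel:
    """f_ENS: binned query spectrum -> probability the MLP predictor wins."""

    def __init__(self, config: EnsembleConfig, params: dict[str, Tensor] | None = None):
        self.config = config
        if params is None:
            rng = np.random.default_rng(config.seed)
            h1, h2 = config.hidden
            shapes = {"W1": (config.n_bins, h1), "W2": (h1, h2), "W3": (h2, 1)}
            params = {}
            for name, (a, b) in shapes.items():
                s = np.sqrt(6.0 / (a + b))
                params[name] = Tensor(rng.uniform(-s, s, size=(a, b)), requires_grad=True)
                params[name.replace("W", "b")] = Tensor(np.zeros(b), requires_grad=True)
        self.params = params
        self.training_log: list[dict] = []

    def _forward(self, X: np.ndarray) -> Tensor:
        p = self.params
        h = (Tensor(X) @ p["W1"] + p["b1"]).relu()
        h = (h @ p["W2"] + p["b2"]).relu()
        return (h @ p["W3"] + p["b3"]).sigmoid()

    def predict_proba(self, spectrum: np.ndarray | Spectrum) -> float:
        """d_hat_mlp for a single query spectrum; d_hat_gnn = 1 - this."""
        y = spectrum.intensities if isinstance(spectrum, Spectrum) else np.asarray(spectrum)
        return float(self._forward(y[None, :]).data[0, 0])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "ens_params.npz", **{k: t.data for k, t in self.params.items()})
        cfg = asdict(self.config)
        cfg["hidden"] = list(cfg["hidden"])
        (out / "ens_config.json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "EnsembleModel":
        bundle = Path(bundle_dir)
        cfg = json.loads((bundle / "ens_config.json").read_text())
        cfg["hidden"] = tuple(cfg["hidden"])
        with np.load(bundle / "ens_params.npz") as npz:
            params = {k: Tensor(npz[k].copy(), requires_grad=True) for k in npz.files}
        return cls(EnsembleConfig(**cfg), params=params)


def train_ensemble(rows: list[TrainingRow], config: EnsembleConfig) -> EnsembleModel:
    """Train f_ENS under gamma-weighted binary cross-entropy.

    Rows with gamma = 0 (exact rank ties) contribute zero loss; if every
    gamma is zero the ensemble is untrainable and an error is raised.
    Checkpoint selection uses a held-out fraction of the table.
    """
    if not rows:
        raise ValueError("empty ensemble training table")
    X, d, gamma = table_to_arrays(rows, config)
    if not (gamma > 0).any():
        raise ValueError("all importance weights are zero: ensemble untrainable")

    rng = np.random.default_rng(config.seed)
    n = len(rows)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * config.val_fraction))) if n >= 10 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = order, np.array([], dtype=int)

    model = EnsembleModel(config)
    opt = Adam(list(model.params.values()), lr=config.lr)
    best_loss, best_params = np.inf, None

    def weighted_bce(idx: np.ndarray) -> Tensor:
        p = model._forward(X[idx]).reshape(-1)
        eps = 1e-7
        d_i, g_i = Tensor(d[idx]), Tensor(gamma[idx])
        ll = d_i * (p.clip_min(eps)).log() + (1.0 - d_i) * ((1.0 - p).clip_min(eps)).log()
        return -(g_i * ll).sum() * (1.0 / max(1, len(idx)))

    for epoch in range(config.epochs):
        perm = rng.permutation(len(tr_idx))
        ep = 0.0
        nb = 0
        for start in range(0, len(tr_idx), config.batch_size):
            idx = tr_idx[perm[start:start + config.batch_size]]
            loss = weighted_bce(idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep += float(loss.data)
            nb += 1
        entry = {"epoch": epoch, "train_loss": ep / nb}
        if len(val_idx):
            vloss = float(weighted_bce(val_idx).data)
            entry["val_loss"] = vloss
            if vloss < best_loss:
                best_loss = vloss
                best_params = {k: t.data.copy() for k, t in model.params.items()}
        model.training_log.append(entry)

    if best_params is not None:
        for k, t in model.params.items():
            t.data = best_params[k]
    return model


class _CombinedPredictor:
    """Duck-typed predictor blending two base models with a fixed probability."""

    def __init__(self, mlp, gnn, p_mlp: float):
        self.mlp, self.gnn, self.p_mlp = mlp, gnn, p_mlp

    def predict_spectra(self, records, settings, precursor_mzs) -> np.ndarray:
        y_mlp = self.mlp.predict_spectra(records, settings, precursor_mzs)
        y_gnn = self.gnn.predict_spectra(records, settings, precursor_mzs)
        return self.p_mlp * y_mlp + (1.0 - self.p_mlp) * y_gnn


def ensemble_predict(cset: CandidateSet, mlp, gnn, ens: EnsembleModel) -> RankResult:
    """Rank candidates under the soft ensemble combination.

    The classifier is evaluated once on the query spectrum; its
    probability weights the two base predictions for every candidate,
    and ranking proceeds by cosine to the query.
    """
    p_mlp = ens.predict_proba(cset.query)
    combined = _CombinedPredictor(mlp, gnn, p_mlp)
    res = score_candidates(cset, combined, predictor="esp")
    return res
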