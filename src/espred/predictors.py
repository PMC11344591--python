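"""The two spectral predictors: fingerprint (MLP) and molecular-graph (GINE).

Both predictors map a molecule plus its instrument setting to a latent
code z, then decode z into a binned spectrum through a shared head
design:

* a two-layer MLP emitting a forward intensity vector (indexed by
  fragment mass), a reverse vector (indexed by neutral-loss mass, so it
  is re-indexed against the precursor bin), and a per-bin sigmoid gate
  that blends the two — the "bidirectional" mode that helps predict
  large fragments arising from small neutral losses;
* a label-mixing stack of low-rank symmetric PSD matrices Q_l = D_l D_l^T
  that redistributes predicted intensity between co-occurring peaks,
  blended with the raw prediction by a fixed weight theta;
* an auxiliary two-layer head predicting the spectrum's LDA topic
  distribution, trained jointly (multi-task) to regularize the latent
  space toward peak co-occurrence structure.

The fingerprint encoder is z = NN(CONCAT(NN(x_fp), NN(x_is))). The graph
encoder initializes node states the same way from atom features and the
instrument setting, runs K rounds of message passing where each node
aggregates its own state, neighbor states, and incident bond-type
embeddings (ReLU of a per-layer affine map), and mean-pools node states
into z.

Training minimizes  L = -cos(y_hat, y) + lambda_aux * CE(r_hat, r)
with Adam; model selection is by validation average rank within formula
strata (falling back to validation cosine when strata are degenerate).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor, concat
from .chemdata import (InstrumentSetting, MolecularGraph, MoleculeRecord,
                       PairedCorpus, ATOM_TYPES, BOND_TYPES)
from .spectra_topics import TopicModel, topic_distribution

logger = logging.getLogger(__name__)


@dataclass
class PredictorConfig:
    encoder: str = "fingerprint"          # "fingerprint" | "graph"
    n_bins: int = 1000
    fp_bits: int = 4096
    n_precursor_types: int = 1
    enc_hidden: int = 256                 # width of the NN(x_fp) / NN(x_atom) projection
    is_hidden: int = 16                   # width of the NN(x_is) projection
    latent_dim: int = 256                 # z width (graph encoder: node-state width)
    gnn_layers: int = 3                   # K message-passing rounds
    head_hidden: int = 256
    aux_hidden: int = 64
    n_topics: int = 0                     # 0 disables the auxiliary head
    # label mixing
    n_mixing: int = 4                     # L
    mixing_rank: int = 64                 # M < P
    theta: float = 0.5
    # training
    lambda_aux: float = 0.1
    lr: float = 1e-3
    epochs: int = 150
    batch_size: int = 128
    eval_every: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.encoder not in ("fingerprint", "graph"):
            raise ValueError(f"unknown encoder kind {self.encoder!r}")
        if self.mixing_rank >= self.n_bins:
            raise ValueError("mixing rank M must be < number of bins P")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")


@dataclass(frozen=True)
class LatentCode:
    """A molecular latent representation z produced by either encoder."""

    vector: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("latent code has non-finite entries")


@dataclass
class MixingStack:
    """Low-rank peak co-occurrence mixing: Q_l = D_l D_l^T, weights on a simplex."""

    factors: list[np.ndarray]     # L matrices of shape (P, M)
    weights: np.ndarray           # simplex over L
    theta: float

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-6):
            raise ValueError("mixing weights must sum to 1")
        P = self.factors[0].shape[0]
        for D in self.factors:
            if D.shape[1] >= P:
                raise ValueError("mixing rank M must be < P")

    @property
    def n_matrices(self) -> int:
        return len(self.factors)

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]


def apply_label_mixing(y_hat: np.ndarray, mix: MixingStack) -> np.ndarray:
    """Blend a prediction with its co-occurrence mixing, in factored form.

    y_co = sum_l (y_hat D_l) D_l^T tau_l, computed without ever forming
    the P x P matrices Q_l; the result is theta*y_hat + (1-theta)*y_co,
    clamped at zero from below.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y_co = np.zeros_like(y_hat)
    for D, tau in zip(mix.factors, mix.weights):
        y_co += (y_hat @ D) @ D.T * tau
    out = mix.theta * y_hat + (1.0 - mix.theta) * y_co
    return np.maximum(out, 0.0)


# ----------------------------------------------------------------------
# parameter initialization
# ----------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def _init_params(cfg: PredictorConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    P, M, L = cfg.n_bins, cfg.mixing_rank, cfg.n_mixing
    n_is = cfg.n_precursor_types + 1
    p: dict[str, np.ndarray] = {}

    if cfg.encoder == "fingerprint":
        p["fp_W"] = _glorot(rng, cfg.fp_bits, cfg.enc_hidden)
        p["fp_b"] = np.zeros(cfg.enc_hidden)
        p["is_W"] = _glorot(rng, n_is, cfg.is_hidden)
        p["is_b"] = np.zeros(cfg.is_hidden)
        p["z_W"] = _glorot(rng, cfg.enc_hidden + cfg.is_hidden, cfg.latent_dim)
        p["z_b"] = np.zeros(cfg.latent_dim)
    else:
        n_atom = len(ATOM_TYPES) + 1
        H = cfg.latent_dim
        p["atom_W"] = _glorot(rng, n_atom, cfg.enc_hidden)
        p["atom_b"] = np.zeros(cfg.enc_hidden)
        p["is_W"] = _glorot(rng, n_is, cfg.is_hidden)
        p["is_b"] = np.zeros(cfg.is_hidden)
        p["node_W"] = _glorot(rng, cfg.enc_hidden + cfg.is_hidden, H)
        p["node_b"] = np.zeros(H)
        for k in range(cfg.gnn_layers):
            p[f"edge_W{k}"] = _glorot(rng, len(BOND_TYPES), H)
            p[f"edge_b{k}"] = np.zeros(H)
            p[f"gnn_W{k}"] = _glorot(rng, H, H)
            p[f"gnn_b{k}"] = np.zeros(H)

    p["head_W1"] = _glorot(rng, cfg.latent_dim, cfg.head_hidden)
    p["head_b1"] = np.zeros(cfg.head_hidden)
    p["head_W2"] = _glorot(rng, cfg.head_hidden, 3 * P)
    p["head_b2"] = np.zeros(3 * P)

    for l in range(L):
        p[f"mix_D{l}"] = rng.normal(0.0, 1.0 / np.sqrt(P), size=(P, M))
    p["mix_tau"] = np.zeros(L)            # softmax logits -> uniform simplex

    if cfg.n_topics >= 2:
        p["aux_W1"] = _glorot(rng, cfg.latent_dim, cfg.aux_hidden)
        p["aux_b1"] = np.zeros(cfg.aux_hidden)
        p["aux_W2"] = _glorot(rng, cfg.aux_hidden, cfg.n_topics)
        p["aux_b2"] = np.zeros(cfg.n_topics)

    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


# ----------------------------------------------------------------------
# batches
# ----------------------------------------------------------------------

@dataclass
class _FPBatch:
    x_fp: np.ndarray       # (B, fp_bits)
    x_is: np.ndarray       # (B, n_is)
    prec_bins: np.ndarray  # (B,)


@dataclass
class _GraphBatch:
    node_feats: np.ndarray   # (N, |A|+1)
    node_is: np.ndarray      # (N, n_is)
    src: np.ndarray          # (E,)
    dst: np.ndarray          # (E,)
    edge_onehot: np.ndarray  # (E, |B|)
    graph_index: np.ndarray  # (N,)
    n_graphs: int
    prec_bins: np.ndarray    # (B,)


def _make_fp_batch(records: list[MoleculeRecord], settings: list[InstrumentSetting],
                   precursor_mzs: list[float], n_bins: int) -> _FPBatch:
    x_fp = np.array([r.fingerprint for r in records], dtype=float)
    x_is = np.array([s.features() for s in settings], dtype=float)
    prec = np.clip(np.floor(np.asarray(precursor_mzs)).astype(np.intp), 0, n_bins - 1)
    return _FPBatch(x_fp, x_is, prec)


def _make_graph_batch(records: list[MoleculeRecord], settings: list[InstrumentSetting],
                      precursor_mzs: list[float], n_bins: int) -> _GraphBatch:
    feats, node_is, srcs, dsts, etypes, gidx = [], [], [], [], [], []
    offset = 0
    for i, (rec, st) in enumerate(zip(records, settings)):
        g: MolecularGraph = rec.graph
        nf = g.node_features()
        feats.append(nf)
        node_is.append(np.tile(st.features(), (g.n_nodes, 1)))
        if g.n_edges:
            srcs.append(g.edge_index[:, 0] + offset)
            dsts.append(g.edge_index[:, 1] + offset)
            eo = np.zeros((g.n_edges, len(BOND_TYPES)))
            eo[np.arange(g.n_edges), g.edge_types] = 1.0
            etypes.append(eo)
        gidx.append(np.full(g.n_nodes, i, dtype=np.intp))
        offset += g.n_nodes
    prec = np.clip(np.floor(np.asarray(precursor_mzs)).astype(np.intp), 0, n_bins - 1)
    return _GraphBatch(
        node_feats=np.concatenate(feats),
        node_is=np.concatenate(node_is),
        src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
        dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
        edge_onehot=np.concatenate(etypes) if etypes else np.zeros((0, len(BOND_TYPES))),
        graph_index=np.concatenate(gidx),
        n_graphs=len(records),
        prec_bins=prec,
    )


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------

class PredictorModel:
    """A trained (or initialized) spectral predictor with one encoder kind."""

    def __init__(self, config: PredictorConfig, params: dict[str, Tensor] | None = None):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params = params if params is not None else _init_params(config, rng)
        self.training_log: list[dict] = []

    # -- encoding ------------------------------------------------------
    def _encode_fp(self, batch: _FPBatch) -> Tensor:
        p = self.params
        h_fp = (Tensor(batch.x_fp) @ p["fp_W"] + p["fp_b"]).relu()
        h_is = (Tensor(batch.x_is) @ p["is_W"] + p["is_b"]).relu()
        return (concat([h_fp, h_is], axis=1) @ p["z_W"] + p["z_b"]).relu()

    def _encode_graph(self, batch: _GraphBatch) -> Tensor:
        p = self.params
        h_a = (Tensor(batch.node_feats) @ p["atom_W"] + p["atom_b"]).relu()
        h_i = (Tensor(batch.node_is) @ p["is_W"] + p["is_b"]).relu()
        h = (concat([h_a, h_i], axis=1) @ p["node_W"] + p["node_b"]).relu()
        n_nodes = batch.node_feats.shape[0]
        for k in range(self.config.gnn_layers):
            e = Tensor(batch.edge_onehot) @ p[f"edge_W{k}"] + p[f"edge_b{k}"]
            if len(batch.src):
                msg = h + (h.gather_rows(batch.src) + e).segment_sum(batch.dst, n_nodes)
            else:
                msg = h       # no bonds: message reduces to the node's own state
            h = (msg @ p[f"gnn_W{k}"] + p[f"gnn_b{k}"]).relu()
        pooled = h.segment_sum(batch.graph_index, batch.n_graphs)
        counts = np.bincount(batch.graph_index, minlength=batch.n_graphs).astype(float)
        return pooled * (1.0 / counts)[:, None]

    def encode(self, batch) -> Tensor:
        if self.config.encoder == "fingerprint":
            return self._encode_fp(batch)
        return self._encode_graph(batch)

    # -- heads -----------------------------------------------------------
    def _head(self, z: Tensor, prec_bins: np.ndarray) -> Tensor:
        """Bidirectional prediction head: gated forward/neutral-loss blend."""
        p = self.params
        P = self.config.n_bins
        h = (z @ p["head_W1"] + p["head_b1"]).relu()
        out = h @ p["head_W2"] + p["head_b2"]
        fwd = out.slice_cols(0, P).relu()
        rev = out.slice_cols(P, 2 * P).relu()
        gate = out.slice_cols(2 * P, 3 * P).sigmoid()
        # reverse branch indexed by neutral-loss mass j -> fragment bin prec - j
        bins = np.arange(P)[None, :]
        idx = prec_bins[:, None] - bins
        mask = (idx >= 0).astype(float)      # also the <=precursor-bin mask
        rev_aligned = rev.gather2d(np.clip(idx, 0, P - 1)) * mask
        y0 = gate * fwd + (1.0 - gate) * rev_aligned
        return y0 * mask

    def _mix(self, y0: Tensor, prec_bins: np.ndarray) -> Tensor:
        p = self.params
        cfg = self.config
        tau = p["mix_tau"].softmax(axis=0)
        y_co = None
        for l in range(cfg.n_mixing):
            D = p[f"mix_D{l}"]
            term = ((y0 @ D) @ D.T) * tau.gather_rows(np.array([l]))
            y_co = term if y_co is None else y_co + term
        y = y0 * cfg.theta + y_co * (1.0 - cfg.theta)
        y = y.clip_min(0.0)
        P = cfg.n_bins
        mask = (prec_bins[:, None] - np.arange(P)[None, :] >= 0).astype(float)
        return y * mask

    def _aux(self, z: Tensor) -> Tensor:
        p = self.params
        h = (z @ p["aux_W1"] + p["aux_b1"]).relu()
        return (h @ p["aux_W2"] + p["aux_b2"]).softmax(axis=1)

    def forward(self, batch, with_aux: bool = False):
        """Full forward pass: returns (y_hat Tensor (B,P), aux Tensor or None)."""
        z = self.encode(batch)
        y0 = self._head(z, batch.prec_bins)
        y = self._mix(y0, batch.prec_bins)
        r_hat = self._aux(z) if (with_aux and self.config.n_topics >= 2) else None
        return y, r_hat

    # -- public prediction API -------------------------------------------
    def make_batch(self, records: list[MoleculeRecord], settings: list[InstrumentSetting],
                   precursor_mzs: list[float]):
        if self.config.encoder == "fingerprint":
            return _make_fp_batch(records, settings, precursor_mzs, self.config.n_bins)
        return _make_graph_batch(records, settings, precursor_mzs, self.config.n_bins)

    def predict_spectra(self, records: list[MoleculeRecord],
                        settings: list[InstrumentSetting],
                        precursor_mzs: list[float]) -> np.ndarray:
        """Predict binned spectra for a list of molecules, (B, P) ndarray."""
        batch = self.make_batch(records, settings, precursor_mzs)
        y, _ = self.forward(batch)
        return y.data.copy()

    def encode_one(self, record: MoleculeRecord, setting: InstrumentSetting) -> LatentCode:
        batch = self.make_batch([record], [setting], [0.0])
        return LatentCode(self.encode(batch).data[0].copy())

    def predict_from_latent(self, z: LatentCode, precursor_mz: float) -> np.ndarray:
        """Decode a latent code into a spectrum (head + mixing + mask)."""
        P = self.config.n_bins
        pb = int(np.floor(precursor_mz))
        if not (0 <= pb < P):
            raise ValueError(f"precursor bin {pb} outside [0, {P})")
        prec = np.array([pb], dtype=np.intp)
        zt = Tensor(z.vector[None, :])
        y = self._mix(self._head(zt, prec), prec)
        return y.data[0].copy()

    def mixing_stack(self) -> MixingStack:
        cfg = self.config
        factors = [self.params[f"mix_D{l}"].data.copy() for l in range(cfg.n_mixing)]
        logits = self.params["mix_tau"].data
        w = np.exp(logits - logits.max())
        return MixingStack(factors=factors, weights=w / w.sum(), theta=cfg.theta)

    # -- persistence -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "params.npz", **{k: t.data for k, t in self.params.items()})
        (out / "predictor_config.json").write_text(json.dumps(asdict(self.config), indent=2))
        (out / "training_log.json").write_text(json.dumps(self.training_log, indent=2))

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "PredictorModel":
        bundle = Path(bundle_dir)
        cfg = PredictorConfig(**json.loads((bundle / "predictor_config.json").read_text()))
        with np.load(bundle / "params.npz") as npz:
            params = {k: Tensor(npz[k].copy(), requires_grad=True) for k in npz.files}
        model = cls(cfg, params=params)
        log_path = bundle / "training_log.json"
        if log_path.exists():
            model.training_log = json.loads(log_path.read_text())
        return model


# convenience wrappers matching the operation-level API ------------------

def encode_fingerprint(record: MoleculeRecord, setting: InstrumentSetting,
                       model: PredictorModel) -> LatentCode:
    if model.config.encoder != "fingerprint":
        raise ValueError("model does not use the fingerprint encoder")
    if len(record.fingerprint) != model.config.fp_bits:
        raise ValueError(
            f"fingerprint width {len(record.fingerprint)} != model {model.config.fp_bits}")
    return model.encode_one(record, setting)


def encode_graph(record: MoleculeRecord, setting: InstrumentSetting,
                 model: PredictorModel) -> LatentCode:
    if model.config.encoder != "graph":
        raise ValueError("model does not use the graph encoder")
    if record.graph.n_nodes == 0:
        raise ValueError("empty molecular graph")
    return model.encode_one(record, setting)


def predict_spectrum(z: LatentCode, precursor_mz: float,
                     model: PredictorModel) -> np.ndarray:
    return model.predict_from_latent(z, precursor_mz)


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def _batch_cosine(y_hat: Tensor, y: np.ndarray) -> Tensor:
    """Mean cosine similarity of predictions against L2-normalized targets."""
    dot = (y_hat * Tensor(y)).sum(axis=1)
    norm = ((y_hat * y_hat).sum(axis=1) + 1e-12).sqrt()
    return (dot / norm).mean()


def _aux_ce(r_hat: Tensor, r: np.ndarray) -> Tensor:
    """Mean cross-entropy of predicted topic distributions against targets."""
    return -((r_hat.clip_min(1e-8)).log() * Tensor(r)).sum(axis=1).mean()


def evaluate_on_split(model: PredictorModel, corpus: PairedCorpus, split: str,
                      max_stratum: int | None = None) -> dict:
    """Mean cosine and within-stratum average rank of a predictor on a split."""
    from . import ranking
    from .chemdata import stratify_by_formula
    from .spectra_topics import cosine_similarity

    pairs = corpus.pairs_in_split(split)
    if not pairs:
        raise ValueError(f"split {split!r} is empty")
    records = [corpus.molecules[mid] for mid, _ in pairs]
    settings = [s.setting for _, s in pairs]
    pmzs = [s.precursor_mz for _, s in pairs]
    preds = model.predict_spectra(records, settings, pmzs)
    cosines = [cosine_similarity(preds[i], s.intensities)
               for i, (_, s) in enumerate(pairs)]

    strata = stratify_by_formula(corpus, split=split)
    ranks = []
    for formula, mids in strata.items():
        if len(mids) < 2 or (max_stratum and len(mids) > max_stratum):
            continue
        members = [corpus.molecules[m] for m in mids]
        for mid, spec in pairs:
            if corpus.molecules[mid].formula != formula:
                continue
            cset = ranking.CandidateSet(query=spec, target_id=mid,
                                        candidates=members, provenance="stratum")
            ranks.append(ranking.score_candidates(cset, model).target_rank)
    return {
        "mean_cosine": float(np.mean(cosines)),
        "avg_rank": float(np.mean(ranks)) if ranks else None,
        "n_rank_queries": len(ranks),
    }


def train_predictor(corpus: PairedCorpus, topics: TopicModel | None,
                    config: PredictorConfig) -> PredictorModel:
    """Phase-1 training of one spectral predictor on the corpus train split.

    Minimizes -cos + lambda_aux * topic cross-entropy with Adam; keeps the
    checkpoint with the best validation average rank (ties and degenerate
    strata resolved by validation cosine). Fully seeded and deterministic.
    """
    config.validate()
    train_pairs = corpus.pairs_in_split("train")
    if not train_pairs:
        raise ValueError("empty training split")
    use_aux = (topics is not None and config.lambda_aux > 0 and config.n_topics >= 2)
    if use_aux and topics.n_topics != config.n_topics:
        raise ValueError("config.n_topics must match the fitted topic model")

    model = PredictorModel(config)
    rng = np.random.default_rng(config.seed + 1)

    records = [corpus.molecules[mid] for mid, _ in train_pairs]
    settings = [s.setting for _, s in train_pairs]
    pmzs = [s.precursor_mz for _, s in train_pairs]
    Y = np.array([s.intensities for _, s in train_pairs])
    R = topic_distribution(topics, Y) if use_aux else None

    n = len(train_pairs)
    opt = Adam(list(model.params.values()), lr=config.lr)
    has_val = bool(corpus.pairs_in_split("val"))

    best = {"score": None, "params": None, "epoch": -1}

    def val_score():
        stats = evaluate_on_split(model, corpus, "val")
        # lower is better; average rank first, cosine breaks ties / fallback
        rank = stats["avg_rank"] if stats["avg_rank"] is not None else float("inf")
        return (rank, -stats["mean_cosine"]), stats

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_cos = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = model.make_batch([records[i] for i in idx],
                                     [settings[i] for i in idx],
                                     [pmzs[i] for i in idx])
            y_hat, r_hat = model.forward(batch, with_aux=use_aux)
            cos = _batch_cosine(y_hat, Y[idx])
            loss = -cos
            if use_aux:
                loss = loss + _aux_ce(r_hat, R[idx]) * config.lambda_aux
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            ep_cos += float(cos.data)
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": ep_loss / n_batches,
                 "train_cosine": ep_cos / n_batches}
        if has_val and ((epoch + 1) % config.eval_every == 0 or epoch == config.epochs - 1):
            score, stats = val_score()
            entry.update(val_cosine=stats["mean_cosine"], val_avg_rank=stats["avg_rank"])
            if best["score"] is None or score < best["score"]:
                best = {"score": score,
                        "params": {k: t.data.copy() for k, t in model.params.items()},
                        "epoch": epoch}
        model.training_log.append(entry)

    if best["params"] is not None:
        for k, t in model.params.items():
            t.data = best["params"][k]
        model.training_log.append({"selected_epoch": best["epoch"]})
    return model
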