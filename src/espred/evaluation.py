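"""End-to-end evaluation harness and run configuration.

Computes the annotation metrics — average rank, rank@k, mean cosine —
for any mix of base predictors and ensemble triples, across configured
candidate-set sizes and similarity modes, on a chosen corpus split.
A size of 0 means "the full formula stratum".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ranking
from .chemdata import PairedCorpus, stratify_by_formula
from .ensemble import EnsembleModel, ensemble_predict
from .spectra_topics import cosine_similarity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; YAML-loadable, snapshot-embedded."""

    seed: int = 0
    out_dir: str = "esp_run"
    corpus_dir: str = ""
    candidate_sizes: tuple[int, ...] = (10, 50, 0)      # 0 = full stratum
    modes: tuple[str, ...] = ("random",)
    k_list: tuple[int, ...] = (1, 3, 10, 20)
    split: str = "test"
    # ablation flags
    esp_sl: bool = False       # labels/weights from spectral loss
    esp_ru: bool = False       # uniform example weights
    # predictor hyperparameters forwarded to PredictorConfig
    predictor: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("candidate_sizes", "modes", "k_list"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def snapshot(self) -> dict:
        return asdict(self)


@dataclass
class EnsembleTriple:
    """An ensemble entry for evaluation: two frozen predictors + classifier."""

    mlp: object
    gnn: object
    ens: EnsembleModel


def _eval_queries(corpus: PairedCorpus, split: str) -> list[tuple]:
    """(molecule_id, spectrum, same-formula pool) for strata of size >= 2."""
    strata = stratify_by_formula(corpus, split=split)
    out = []
    for mid, spec in corpus.pairs_in_split(split):
        mids = strata[corpus.molecules[mid].formula]
        if len(mids) < 2:
            continue
        pool = [corpus.molecules[m] for m in mids if m != mid]
        out.append((mid, spec, pool))
    return out


def _rank_query(model, cset: ranking.CandidateSet) -> ranking.RankResult:
    if isinstance(model, EnsembleTriple):
        return ensemble_predict(cset, model.mlp, model.gnn, model.ens)
    return ranking.score_candidates(cset, model)


def _mean_cosine(model, corpus: PairedCorpus, split: str) -> float:
    pairs = corpus.pairs_in_split(split)
    records = [corpus.molecules[mid] for mid, _ in pairs]
    settings = [s.setting for _, s in pairs]
    pmzs = [s.precursor_mz for _, s in pairs]
    if isinstance(model, EnsembleTriple):
        y_mlp = model.mlp.predict_spectra(records, settings, pmzs)
        y_gnn = model.gnn.predict_spectra(records, settings, pmzs)
        probs = np.array([model.ens.predict_proba(s) for _, s in pairs])
        preds = probs[:, None] * y_mlp + (1 - probs[:, None]) * y_gnn
    else:
        preds = model.predict_spectra(records, settings, pmzs)
    return float(np.mean([cosine_similarity(preds[i], s.intensities)
                          for i, (_, s) in enumerate(pairs)]))


def run_evaluation(corpus: PairedCorpus, models: dict[str, object],
                   config: RunConfig) -> pd.DataFrame:
    """Rank every eligible query under every model/mode/size combination.

    Returns a tidy DataFrame with one row per (model, mode, size):
    average rank, rank@k for each configured k, mean cosine on the split,
    the number of queries, and the evaluation seed.
    """
    queries = _eval_queries(corpus, config.split)
    if not queries:
        raise ValueError(f"no rankable queries in split {config.split!r}")
    rows = []
    cosines = {name: _mean_cosine(m, corpus, config.split) for name, m in models.items()}
    for name, model in models.items():
        for mode in config.modes:
            for size in config.candidate_sizes:
                results = []
                for qi, (mid, spec, pool) in enumerate(queries):
                    if size == 0 or size >= len(pool) + 1:
                        cset = ranking.CandidateSet(
                            query=spec, target_id=mid,
                            candidates=pool + [corpus.molecules[mid]],
                            provenance="stratum")
                    else:
                        cset = ranking.build_eval_candidates(
                            corpus.molecules[mid], pool, spec, mode=mode,
                            n=size, seed=config.seed * 100003 + qi)
                    results.append(_rank_query(model, cset))
                row = {
                    "model": name, "mode": mode,
                    "size": size if size else "full",
                    "n_queries": len(results),
                    "avg_rank": ranking.average_rank(results),
                    "mean_cosine": cosines[name],
                    "seed": config.seed,
                }
                for k in config.k_list:
                    row[f"rank_at_{k}"] = ranking.rank_at_k(results, k)
                rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, config: RunConfig, out_dir: str | Path) -> None:
    """Emit the TSV + JSON report with the full config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "evaluation.tsv", sep="\t", index=False)
    (out / "evaluation.json").write_text(json.dumps({
        "config": config.snapshot(),
        "results": df.to_dict(orient="records"),
    }, indent=2))
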