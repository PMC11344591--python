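"""Candidate scoring against a query spectrum and ranking metrics.

Annotation works molecule-to-spectrum: a predictor generates a spectrum
for every candidate molecule (under the query's instrument setting,
since the candidate's own setting is unknowable at annotation time), and
candidates are ranked by cosine similarity of their predicted spectrum
to the measured query. The target's rank uses competition ranking with
worst-case tie handling: a target tied with non-targets is placed after
all of them, so reported ranks are conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chemdata import MoleculeRecord, Spectrum
from .spectra_topics import cosine_similarity

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """A query spectrum plus the molecules it must be ranked against.

    The target molecule is assumed to be a member of the candidate set.
    """

    query: Spectrum
    target_id: str
    candidates: list[MoleculeRecord]
    provenance: str = "stratum"

    def __post_init__(self):
        ids = [c.id for c in self.candidates]
        if len(set(ids)) != len(ids):
            raise ValueError("candidate ids must be unique")
        if self.target_id not in ids:
            raise ValueError(f"target {self.target_id!r} not in candidate set")


@dataclass
class RankResult:
    """Per-candidate scores and the target's (worst-case-tie) rank."""

    target_rank: int
    n_candidates: int
    scores: dict[str, float]
    predictor: str = ""

    def __post_init__(self):
        if not (1 <= self.target_rank <= self.n_candidates):
            raise ValueError("target rank out of range")


def _rank_of_target(scores: dict[str, float], target_id: str) -> int:
    """Competition rank of the target, ties resolved against it."""
    t = scores[target_id]
    return 1 + sum(1 for cid, s in scores.items() if cid != target_id and s >= t)


def score_candidates(cset: CandidateSet, model, predictor: str = "") -> RankResult:
    """Score every candidate by cosine of its predicted spectrum to the query.

    ``model`` is anything exposing ``predict_spectra(records, settings,
    precursor_mzs) -> (n, P) array``. Candidates that fail prediction are
    dropped with a log entry unless the target itself fails, which is an
    error.
    """
    records = list(cset.candidates)
    settings = [cset.query.setting] * len(records)
    pmzs = [cset.query.precursor_mz] * len(records)
    try:
        preds = model.predict_spectra(records, settings, pmzs)
    except Exception:
        # retry one-by-one so a single bad candidate cannot sink the set
        preds_list, kept = [], []
        for rec in records:
            try:
                preds_list.append(model.predict_spectra(
                    [rec], [cset.query.setting], [cset.query.precursor_mz])[0])
                kept.append(rec)
            except Exception:
                if rec.id == cset.target_id:
                    raise
                logger.warning("dropping unfeaturizable candidate %s", rec.id)
        records = kept
        preds = np.array(preds_list)
    scores = {rec.id: cosine_similarity(preds[i], cset.query.intensities)
              for i, rec in enumerate(records)}
    return RankResult(target_rank=_rank_of_target(scores, cset.target_id),
                      n_candidates=len(records), scores=scores,
                      predictor=predictor)


def average_rank(results: list[RankResult]) -> float:
    """Arithmetic mean of the target ranks."""
    if not results:
        raise ValueError("no rank results")
    return float(np.mean([r.target_rank for r in results]))


def rank_at_k(results: list[RankResult], k: int) -> float:
    """Fraction of queries whose target lands within the top k candidates."""
    if not results:
        raise ValueError("no rank results")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.mean([r.target_rank <= k for r in results]))


def maccs_tanimoto(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Tanimoto similarity of MACCS keys (the candidate-quality measure)."""
    inter = int(np.sum(a.maccs & b.maccs))
    union = int(np.sum(a.maccs | b.maccs))
    return inter / union if union else 0.0


def build_eval_candidates(target: MoleculeRecord, pool: list[MoleculeRecord],
                          query: Spectrum, mode: str = "random", n: int = 100,
                          seed: int = 0) -> CandidateSet:
    """Assemble an evaluation candidate set of size n around the target.

    ``pool`` holds same-formula non-target molecules. Modes: ``random``
    (seeded sample), ``most_similar`` / ``least_similar`` (by MACCS
    Tanimoto to the target, ties broken by molecule id). If the pool is
    smaller than n-1 the full pool is used with a warning.
    """
    if n < 1:
        raise ValueError("candidate set size must be >= 1")
    pool = [p for p in pool if p.id != target.id]
    for p in pool:
        if p.formula != target.formula:
            raise ValueError(f"pool molecule {p.id} formula {p.formula} != target {target.formula}")
    want = n - 1
    if len(pool) < want:
        logger.warning("candidate pool (%d) smaller than requested %d; using all",
                       len(pool), want)
        chosen = list(pool)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=want, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    elif mode in ("most_similar", "least_similar"):
        sims = sorted(((maccs_tanimoto(target, p), p.id, p) for p in pool),
                      reverse=(mode == "most_similar"))
        # reverse=True sorts ids descending too; re-sort equal-sim runs by id
        keyed = sorted(sims, key=lambda t: (-t[0] if mode == "most_similar" else t[0], t[1]))
        chosen = [p for _, _, p in keyed[:want]]
    else:
        raise ValueError(f"unknown candidate mode {mode!r}")
    return CandidateSet(query=query, target_id=target.id,
                        candidates=chosen + [target],
                        provenance=f"{mode}-{n}")
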