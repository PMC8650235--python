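"""Module-level mRNA ranking and preranked gene set enrichment analysis.

mRNAs are scored per module by their mean mutual rank with the module's
lncRNAs, computed under the orientation that places the module's own
correlated mRNAs at high MR: for a positive-network module the Spearman
coefficients are ranked ascending (so strongly positively correlated
mRNAs get the highest mutual ranks), for a negative-network module
descending.  The descending score list then feeds a weighted
Kolmogorov-Smirnov-style running-sum enrichment, with a random-gene-set
permutation null shared across sets of the same size (the only valid null
for an externally ranked list).  NES and the nominal p-value are taken
against same-sign permutation scores; the FDR q compares each observed
NES to the pooled permutation NES distribution, positive and negative
sides separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import MutualRankMatrix
from .errors import ConfigurationError, InputError
from .io import GeneSetCollection
from .network import Module

logger = logging.getLogger(__name__)

_FLIP = {"positive": "negative", "negative": "positive"}


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)
    size: int = 0


def module_rank(
    mr: MutualRankMatrix, module: Module, aggregate: str = "mean"
) -> pd.Series:
    """Descending per-mRNA mean (or min) mutual rank over the module's lncRNAs.

    ``mr`` must be the mutual-rank matrix of the orientation *opposite* to
    the module's network: a PLAN (positive) module is ranked on
    ascending-SCC mutual ranks (``mutual_rank(corr, 'negative')``) so its
    positively correlated mRNAs score highest, and vice versa.
    """
    if not module.members:
        raise InputError("empty module cannot be ranked")
    if mr.orientation != _FLIP[module.orientation]:
        raise ConfigurationError(
            f"module of orientation {module.orientation!r} must be ranked on the "
            f"{_FLIP[module.orientation]!r}-orientation mutual ranks"
        )
    if aggregate not in ("mean", "min"):
        raise ConfigurationError("aggregate must be 'mean' or 'min'")
    members = sorted(module.members)
    missing = [m for m in members if m not in mr.mr.index]
    if missing:
        raise InputError(f"module lncRNAs absent from MR matrix: {missing}")
    rows = mr.mr.loc[members]
    scores = rows.mean(axis=0) if aggregate == "mean" else rows.min(axis=0)
    scores.name = "score"
    return scores.sort_values(ascending=False, kind="mergesort")


def _running_es(
    n: int, hit_pos: np.ndarray, weights: np.ndarray
) -> tuple[float, int]:
    """Signed extremum of the weighted KS running sum and its position."""
    m = len(hit_pos)
    incr = np.full(n, -1.0 / (n - m))
    incr[hit_pos] = weights / weights.sum()
    running = np.cumsum(incr)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def _perm_es(
    n: int, m: int, abs_scores: np.ndarray, weight_p: float, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized running-sum ES for n_perm random size-m sets."""
    w_all = abs_scores**weight_p
    incr = np.full((n_perm, n), -1.0 / (n - m))
    rows = np.repeat(np.arange(n_perm), m)
    cols = np.empty((n_perm, m), dtype=np.int64)
    for i in range(n_perm):
        cols[i] = rng.choice(n, size=m, replace=False)
    w = w_all[cols]
    incr[rows, cols.ravel()] = (w / w.sum(axis=1, keepdims=True)).ravel()
    running = np.cumsum(incr, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked GSEA of ``ranked`` (descending score Series) against ``sets``.

    Hit increments are proportional to |score|^weight_p (normalized to 1
    over the set), miss decrements 1/(N - set size); ES is the signed
    extremum of the running sum.  The permutation null draws ``n_perm``
    random same-size sets from the ranked list, shared across query sets
    of equal size.  Sets outside [min_size, max_size] members-in-list, or
    covering the whole list, are skipped with a log entry.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-values and FDR will be coarse", n_perm)
    ranked = ranked.sort_values(ascending=False, kind="mergesort")
    genes = ranked.index.to_numpy()
    if len(genes) != len(set(genes)):
        raise InputError("ranked list contains duplicate gene ids")
    scores = ranked.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise InputError("ranked scores must be finite")
    n = len(genes)
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    abs_scores = np.abs(scores)

    analysed: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        hit = np.array(sorted(pos_of[g] for g in members if g in pos_of), dtype=np.int64)
        if len(hit) < min_size or len(hit) > max_size or len(hit) >= n:
            logger.info("set %s skipped (%d members in list)", name, len(hit))
            continue
        analysed.append((name, hit))
    if not analysed:
        return []

    null_by_size: dict[int, np.ndarray] = {}
    for _, hit in analysed:
        m = len(hit)
        if m not in null_by_size:
            null_by_size[m] = _perm_es(n, m, abs_scores, weight_p, n_perm, rng)

    # normalize permutation scores per size by same-sign means, then pool
    norm_null: list[np.ndarray] = []
    means: dict[int, tuple[float, float]] = {}
    for m, es_perm in null_by_size.items():
        pos_mean = es_perm[es_perm >= 0].mean() if (es_perm >= 0).any() else np.nan
        neg_mean = np.abs(es_perm[es_perm < 0]).mean() if (es_perm < 0).any() else np.nan
        means[m] = (pos_mean, neg_mean)
        nes_perm = np.where(
            es_perm >= 0,
            es_perm / pos_mean if np.isfinite(pos_mean) else np.nan,
            es_perm / neg_mean if np.isfinite(neg_mean) else np.nan,
        )
        norm_null.append(nes_perm[np.isfinite(nes_perm)])
    pooled = np.concatenate(norm_null)
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]

    results: list[EnrichmentResult] = []
    obs_nes: list[float] = []
    for name, hit in analysed:
        m = len(hit)
        w = abs_scores[hit] ** weight_p
        es, peak = _running_es(n, hit, w)
        es_perm = null_by_size[m]
        pos_mean, neg_mean = means[m]
        if es >= 0:
            same = es_perm[es_perm >= 0]
            p = float((same >= es).sum() / len(same)) if len(same) else float("nan")
            nes = es / pos_mean if np.isfinite(pos_mean) else float("nan")
            edge = [genes[i] for i in hit if i <= peak]
        else:
            same = es_perm[es_perm < 0]
            p = float((same <= es).sum() / len(same)) if len(same) else float("nan")
            nes = es / neg_mean if np.isfinite(neg_mean) else float("nan")
            edge = [genes[i] for i in hit if i >= peak]
        results.append(EnrichmentResult(name, es, float(nes), p, float("nan"), edge, m))
        obs_nes.append(float(nes))

    obs = np.array(obs_nes)
    for res in results:
        nes = res.nes
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = (pooled_pos >= nes).sum() / max(len(pooled_pos), 1)
            obs_frac = (obs[obs >= 0] >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            null_frac = (pooled_neg <= nes).sum() / max(len(pooled_neg), 1)
            obs_frac = (obs[obs < 0] <= nes).sum() / max((obs < 0).sum(), 1)
        res.fdr_q = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else 1.0
    return results


def top_results(
    results: list[EnrichmentResult], n_top: int = 10, fdr_max: float = 0.001
) -> list[EnrichmentResult]:
    """Top-NES results passing the FDR threshold (report-style selection)."""
    ok = [r for r in results if r.fdr_q < fdr_max]
    return sorted(ok, key=lambda r: -abs(r.nes))[:n_top]


def write_enrichment_table(results: list[EnrichmentResult], path) -> None:
    rows = [
        {
            "set_name": r.set_name,
            "size": r.size,
            "es": r.es,
            "nes": r.nes,
            "nominal_p": r.nominal_p,
            "fdr_q": r.fdr_q,
            "leading_edge": ",".join(r.leading_edge),
        }
        for r in sorted(results, key=lambda r: -r.nes if np.isfinite(r.nes) else 0.0)
    ]
    pd.DataFrame(
        rows,
        columns=["set_name", "size", "es", "nes", "nominal_p", "fdr_q", "leading_edge"],
    ).to_csv(path, sep="\t", index=False)
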