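"""lncRNA-mRNA Spearman correlation, mutual rank and correlated-set selection.

The mutual rank (MR) of a lncRNA-mRNA pair is the geometric mean of the
pair's rank within the lncRNA's row of correlations (over all mRNAs) and
within the mRNA's column (over all lncRNAs).  Under the *positive*
orientation rank 1 is the largest Spearman coefficient, so mutually
top-ranked positively correlated pairs get MR near 1; the *negative*
orientation ranks ascending so the strongest negative pairs get MR near 1.
Pairs with MR at or below ``sqrt(n_lnc * n_mrna) * fraction`` form each
lncRNA's positively / negatively correlated mRNA set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, InsufficientDataError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

ORIENTATIONS = ("positive", "negative")


@dataclass
class CorrelationMatrix:
    """Spearman coefficients, lncRNAs as rows and mRNAs as columns."""

    scc: pd.DataFrame

    @property
    def lnc_ids(self) -> pd.Index:
        return self.scc.index

    @property
    def mrna_ids(self) -> pd.Index:
        return self.scc.columns


@dataclass
class MutualRankMatrix:
    """Mutual ranks (>= 1) under one ranking orientation."""

    mr: pd.DataFrame
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(f"orientation must be one of {ORIENTATIONS}")


@dataclass
class CorrelatedSets:
    """Per-lncRNA positively / negatively correlated mRNA id sets."""

    pos_sets: dict[str, frozenset]
    neg_sets: dict[str, frozenset]
    cutoff: float

    def sets_for(self, orientation: str) -> dict[str, frozenset]:
        if orientation == "positive":
            return self.pos_sets
        if orientation == "negative":
            return self.neg_sets
        raise ConfigurationError(f"orientation must be one of {ORIENTATIONS}")


def spearman_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """All lncRNA x mRNA Spearman correlations across samples.

    Computed as Pearson on average ranks (the tie-robust definition, which
    reduces to the classical 1 - 6*sum(d^2)/(n(n^2-1)) form when no ties).
    Genes with zero rank variance (constant expression) get coefficient 0
    with a logged warning rather than NaN, so downstream ranks stay defined.
    """
    lnc_ids, mrna_ids = expr.lnc_ids, expr.mrna_ids
    if len(lnc_ids) == 0 or len(mrna_ids) == 0:
        raise InsufficientDataError("need both lncRNA and mRNA rows")
    n = expr.values.shape[1]
    if n < 3:
        raise InsufficientDataError("need >= 3 samples for Spearman correlation")

    ranks = rankdata(expr.values.to_numpy(), axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        bad = expr.gene_ids[constant].tolist()
        logger.warning("constant expression, SCC set to 0 for: %s", bad[:10])
    norms[constant] = 1.0
    ranks /= norms[:, None]

    is_lnc = expr.gene_types.to_numpy() == "lncRNA"
    scc = ranks[is_lnc] @ ranks[~is_lnc].T
    np.clip(scc, -1.0, 1.0, out=scc)
    scc[constant[is_lnc], :] = 0.0
    scc[:, constant[~is_lnc]] = 0.0
    return CorrelationMatrix(pd.DataFrame(scc, index=lnc_ids, columns=mrna_ids))


def mutual_rank(corr: CorrelationMatrix, orientation: str) -> MutualRankMatrix:
    """Geometric mean of the within-row and within-column SCC ranks.

    ``positive``: rank 1 = largest SCC in its row/column (descending);
    ``negative``: rank 1 = smallest (ascending).  Ties take average ranks.
    """
    if orientation not in ORIENTATIONS:
        raise ConfigurationError(f"orientation must be one of {ORIENTATIONS}")
    scc = corr.scc.to_numpy()
    signed = -scc if orientation == "positive" else scc
    rank_row = rankdata(signed, axis=1)  # lncRNA -> over mRNAs
    rank_col = rankdata(signed, axis=0)  # mRNA -> over lncRNAs
    mr = np.sqrt(rank_row * rank_col)
    return MutualRankMatrix(
        pd.DataFrame(mr, index=corr.lnc_ids, columns=corr.mrna_ids), orientation
    )


def mr_cutoff(n_lnc: int, n_mrna: int, fraction: float = 0.001) -> float:
    """MR selection threshold: ``sqrt(n_lnc * n_mrna) * fraction``.

    With 4342 lncRNAs, 16619 mRNAs and fraction 0.001 this is ~8.49.
    """
    if n_lnc < 1 or n_mrna < 1:
        raise ConfigurationError("gene counts must be >= 1")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must lie strictly in (0, 1)")
    return float(np.sqrt(n_lnc * n_mrna) * fraction)


def select_correlated_sets(
    mr_pos: MutualRankMatrix, mr_neg: MutualRankMatrix, cutoff: float
) -> CorrelatedSets:
    """mRNAs with MR <= cutoff (inclusive) per lncRNA and orientation."""
    if not mr_pos.mr.index.equals(mr_neg.mr.index) or not mr_pos.mr.columns.equals(
        mr_neg.mr.columns
    ):
        raise ConfigurationError("MR matrices must share the same gene index")
    mrna = mr_pos.mr.columns.to_numpy()

    def _sets(mat: pd.DataFrame) -> dict[str, frozenset]:
        mask = mat.to_numpy() <= cutoff
        return {
            lnc: frozenset(mrna[mask[i]]) for i, lnc in enumerate(mat.index)
        }

    return CorrelatedSets(_sets(mr_pos.mr), _sets(mr_neg.mr), float(cutoff))


def correlated_sets_from_expression(
    expr: ExpressionMatrix, fraction: float = 0.001
) -> tuple[CorrelationMatrix, MutualRankMatrix, MutualRankMatrix, CorrelatedSets]:
    """Convenience: SCC -> MR (both orientations) -> thresholded sets."""
    corr = spearman_matrix(expr)
    mr_pos = mutual_rank(corr, "positive")
    mr_neg = mutual_rank(corr, "negative")
    cutoff = mr_cutoff(len(corr.lnc_ids), len(corr.mrna_ids), fraction)
    return corr, mr_pos, mr_neg, select_correlated_sets(mr_pos, mr_neg, cutoff)


def write_pair_table(
    corr: CorrelationMatrix,
    mr_pos: MutualRankMatrix,
    mr_neg: MutualRankMatrix,
    path,
) -> None:
    """Long-format dump: lnc_id, mrna_id, scc, mr_pos, mr_neg."""
    long = pd.DataFrame(
        {
            "lnc_id": np.repeat(corr.lnc_ids, len(corr.mrna_ids)),
            "mrna_id": np.tile(corr.mrna_ids, len(corr.lnc_ids)),
            "scc": corr.scc.to_numpy().ravel(),
            "mr_pos": mr_pos.mr.to_numpy().ravel(),
            "mr_neg": mr_neg.mr.to_numpy().ravel(),
        }
    )
    long.to_csv(path, sep="\t", index=False)
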