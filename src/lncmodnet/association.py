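"""Set-overlap association index between lncRNAs and thresholded edge lists.

Two lncRNAs are compared through their correlated-mRNA sets N(X), N(Y)
inside a universe of n mRNAs.  The association index is

    pcc(X, Y) = (|N(X) ∩ N(Y)| * n - |N(X)| |N(Y)|)
                / sqrt(|N(X)| |N(Y)| (n - |N(X)|) (n - |N(Y)|))

which is exactly the Pearson correlation of the two 0/1 membership
indicator vectors over the universe.  It is undefined when either set is
empty or covers the whole universe (zero indicator variance).  Pairs above
a strict threshold (0.7 by default downstream) become network edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import ORIENTATIONS, CorrelatedSets
from .errors import ConfigurationError, UndefinedAssociationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationEdge:
    """Undirected lncRNA pair with its association index."""

    lnc_a: str
    lnc_b: str
    pcc: float
    orientation: str

    def __post_init__(self) -> None:
        if self.lnc_a == self.lnc_b:
            raise ConfigurationError("self-pair is not a valid association edge")
        if self.lnc_a > self.lnc_b:  # canonical order
            a, b = self.lnc_a, self.lnc_b
            object.__setattr__(self, "lnc_a", b)
            object.__setattr__(self, "lnc_b", a)


def association_pcc(set_x, set_y, n_universe: int) -> float:
    """Eq-of-indicators Pearson between two mRNA sets over ``n_universe`` genes."""
    a, b = len(set_x), len(set_y)
    if a == 0 or b == 0 or a >= n_universe or b >= n_universe:
        raise UndefinedAssociationError(
            f"set sizes {a}, {b} must lie strictly inside (0, {n_universe})"
        )
    k = len(set(set_x) & set(set_y))
    num = k * n_universe - a * b
    den = math.sqrt(a * b * (n_universe - a) * (n_universe - b))
    return num / den


def association_jaccard(set_x, set_y) -> float:
    """Alternative overlap index: |X ∩ Y| / |X ∪ Y|."""
    if len(set_x) == 0 and len(set_y) == 0:
        raise UndefinedAssociationError("both sets empty")
    x, y = set(set_x), set(set_y)
    return len(x & y) / len(x | y)


def _valid_lncs(sets: dict[str, frozenset], n_universe: int) -> list[str]:
    valid = []
    for lnc, s in sets.items():
        if 0 < len(s) < n_universe:
            valid.append(lnc)
        else:
            logger.warning(
                "lncRNA %s skipped: correlated set size %d undefined in universe %d",
                lnc,
                len(s),
                n_universe,
            )
    return sorted(valid)


def association_matrix(
    sets: CorrelatedSets, orientation: str, n_universe: int, index: str = "pcc"
) -> pd.DataFrame:
    """All-pairs association index among lncRNAs with defined sets.

    Symmetric square DataFrame with 1.0 on the diagonal; lncRNAs whose set
    is empty or universe-sized are excluded (logged).  ``index`` selects the
    indicator-Pearson form ("pcc", default) or "jaccard" for comparison.
    """
    if orientation not in ORIENTATIONS:
        raise ConfigurationError(f"orientation must be one of {ORIENTATIONS}")
    if index not in ("pcc", "jaccard"):
        raise ConfigurationError("index must be 'pcc' or 'jaccard'")
    oriented = sets.sets_for(orientation)
    lncs = _valid_lncs(oriented, n_universe)
    universe = sorted(set().union(*(oriented[l] for l in lncs)) if lncs else set())
    col = {m: j for j, m in enumerate(universe)}
    member = np.zeros((len(lncs), len(universe)), dtype=np.float64)
    for i, lnc in enumerate(lncs):
        for m in oriented[lnc]:
            member[i, col[m]] = 1.0
    sizes = member.sum(axis=1)
    overlap = member @ member.T
    if index == "jaccard":
        union = sizes[:, None] + sizes[None, :] - overlap
        vals = overlap / union
    else:
        num = overlap * n_universe - np.outer(sizes, sizes)
        den = np.sqrt(
            np.outer(sizes * (n_universe - sizes), sizes * (n_universe - sizes))
        )
        vals = num / den
    np.fill_diagonal(vals, 1.0)
    return pd.DataFrame(vals, index=lncs, columns=lncs)


def build_edge_list(
    sets: CorrelatedSets,
    orientation: str,
    threshold: float = 0.7,
    n_universe: int | None = None,
    index: str = "pcc",
) -> list[AssociationEdge]:
    """Unordered lncRNA pairs with association index strictly above threshold.

    ``n_universe`` is the total preprocessed mRNA count; pairs involving an
    undefined set are skipped (with a warning), never treated as zero.
    """
    if not -1.0 < threshold < 1.0:
        raise ConfigurationError("threshold must lie in (-1, 1)")
    if n_universe is None:
        raise ConfigurationError("n_universe (total mRNA count) is required")
    pcc = association_matrix(sets, orientation, n_universe, index)
    lncs = pcc.index.to_numpy()
    mat = pcc.to_numpy()
    ii, jj = np.triu_indices(len(lncs), k=1)
    keep = mat[ii, jj] > threshold
    return [
        AssociationEdge(lncs[i], lncs[j], float(mat[i, j]), orientation)
        for i, j in zip(ii[keep], jj[keep])
    ]


def write_edge_list(edges: list[AssociationEdge], path) -> None:
    df = pd.DataFrame(
        [(e.lnc_a, e.lnc_b, e.pcc, e.orientation) for e in edges],
        columns=["lnc_a", "lnc_b", "pcc", "orientation"],
    )
    df.to_csv(path, sep="\t", index=False)
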