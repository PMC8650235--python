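"""Association network construction, module extraction and topology checks.

Modules are the connected components of the thresholded association graph
with at least ``min_size`` members (12 by default), labelled P1, P2, ... /
N1, N2, ... in decreasing size order.  Scale-free structure is checked by
ordinary least squares of log10 degree density on log10 degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationEdge
from .correlation import ORIENTATIONS
from .errors import ConfigurationError, InputError, InsufficientDataError

DEFAULT_MIN_MODULE_SIZE = 12


@dataclass
class Module:
    """One connected cluster of highly associated lncRNAs."""

    module_id: str
    members: frozenset
    orientation: str


@dataclass
class TopologyFit:
    """log-log OLS fit of the degree density: pk ~ k^slope."""

    k: np.ndarray
    pk: np.ndarray
    slope: float
    intercept: float
    p_value: float
    r_squared: float


def build_network(edges: list[AssociationEdge]) -> nx.Graph:
    """Simple undirected graph over the edge endpoints (no isolated nodes)."""
    orientations = {e.orientation for e in edges}
    if len(orientations) > 1:
        raise InputError(f"edges mix orientations: {sorted(orientations)}")
    g = nx.Graph(orientation=orientations.pop() if orientations else None)
    for e in edges:
        if e.lnc_a == e.lnc_b:
            raise InputError(f"self-loop on {e.lnc_a}")
        g.add_edge(e.lnc_a, e.lnc_b, pcc=e.pcc)
    return g


def extract_modules(
    net: nx.Graph, min_size: int = DEFAULT_MIN_MODULE_SIZE, orientation: str | None = None
) -> list[Module]:
    """Connected components with >= min_size nodes, largest first.

    Labels are P1, P2, ... for the positive network and N1, N2, ... for the
    negative one; ties in size break on the lexicographically smallest
    member id.
    """
    orientation = orientation or net.graph.get("orientation")
    if orientation not in ORIENTATIONS:
        raise ConfigurationError(f"orientation must be one of {ORIENTATIONS}")
    prefix = "P" if orientation == "positive" else "N"
    comps = [c for c in nx.connected_components(net) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [
        Module(f"{prefix}{i}", frozenset(c), orientation)
        for i, c in enumerate(comps, start=1)
    ]


def degree_density(net: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Observed degrees k and their node fractions pk (sum(pk) = 1)."""
    if net.number_of_nodes() == 0:
        raise InsufficientDataError("empty network has no degree distribution")
    degrees = np.array([d for _, d in net.degree()])
    k, counts = np.unique(degrees, return_counts=True)
    return k, counts / counts.sum()


def power_law_fit(k: np.ndarray, pk: np.ndarray) -> TopologyFit:
    """OLS of log10(pk) on log10(k) over points with pk > 0."""
    k = np.asarray(k, dtype=float)
    pk = np.asarray(pk, dtype=float)
    mask = (pk > 0) & (k > 0)
    k, pk = k[mask], pk[mask]
    if len(np.unique(k)) < 3:
        raise InsufficientDataError("need >= 3 distinct degrees for the log-log fit")
    res = stats.linregress(np.log10(k), np.log10(pk))
    return TopologyFit(
        k=k,
        pk=pk,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
    )


def node_metrics(net: nx.Graph, modules: list[Module]) -> pd.DataFrame:
    """Per-node degree, local clustering, normalized betweenness, module id."""
    module_of = {m: mod.module_id for mod in modules for m in mod.members}
    clustering = nx.clustering(net)
    betweenness = nx.betweenness_centrality(net, normalized=True)
    rows = [
        {
            "node": v,
            "degree": net.degree(v),
            "clustering": clustering[v],
            "betweenness": betweenness[v],
            "module_id": module_of.get(v, ""),
        }
        for v in sorted(net.nodes)
    ]
    return pd.DataFrame(rows).set_index("node")


def intra_inter_comparison(
    pcc_table: pd.DataFrame, modules: list[Module]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Intra- vs inter-module association values and a rank-sum p-value.

    ``pcc_table`` is the symmetric all-pairs association matrix; only pairs
    of module members are considered.  The two-sided Wilcoxon rank-sum test
    compares the intra-module and inter-module value distributions.
    """
    if len(modules) < 2:
        raise InsufficientDataError("need >= 2 modules for inter-module pairs")
    module_of = {m: mod.module_id for mod in modules for m in mod.members}
    members = sorted(m for m in module_of if m in pcc_table.index)
    intra, inter = [], []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            val = pcc_table.loc[a, b]
            (intra if module_of[a] == module_of[b] else inter).append(val)
    intra_arr, inter_arr = np.asarray(intra), np.asarray(inter)
    if len(intra_arr) == 0 or len(inter_arr) == 0:
        raise InsufficientDataError("a comparison group is empty")
    _, p = stats.ranksums(intra_arr, inter_arr)
    return intra_arr, inter_arr, float(p)


# ---------------------------------------------------------------------------
# exports


def write_graphml(net: nx.Graph, path) -> None:
    g = net.copy()
    if g.graph.get("orientation") is None:
        g.graph.pop("orientation", None)
    nx.write_graphml(g, path)


def write_sif(net: nx.Graph, path, interaction: str = "assoc") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_module_table(modules: list[Module], path) -> None:
    rows = [
        (m, mod.module_id, mod.orientation)
        for mod in modules
        for m in sorted(mod.members)
    ]
    pd.DataFrame(rows, columns=["lnc_id", "module_id", "orientation"]).to_csv(
        path, sep="\t", index=False
    )
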