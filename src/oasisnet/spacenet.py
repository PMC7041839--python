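"""Space-sharing networks over tracked bats, plus co-roosting and metrics.

An edge joins two bats that were located at the same foraging site on the same
night (spatial co-occurrence as a proxy for association).  Edge weights are
the proportion of foraging sites the pair shares; held internally in [0, 1]
and rendered as percentages on output.  Binary adjacency drives density,
normalized degree and the (unweighted) clustering coefficient; weights enter
only through the weighted degree s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SharingNetwork",
    "NetworkSummary",
    "build_sharing_network",
    "filter_by_relatedness",
    "build_coroost_matrix",
    "network_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SharingNetwork:
    nodes: tuple[str, ...]
    #: symmetric weights in [0, 1], zero diagonal
    weights: np.ndarray
    #: number of shared sites behind each weight
    shared_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.diag(self.weights).any():
            raise ValueError("weight matrix diagonal must be zero")

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights > 0).astype(int)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > 0:
                    g.add_edge(self.nodes[i], self.nodes[j], weight=float(self.weights[i, j]))
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > 0:
                    rows.append(
                        (
                            self.nodes[i],
                            self.nodes[j],
                            100.0 * self.weights[i, j],
                            int(self.shared_counts[i, j]),
                        )
                    )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "weight_pct", "n_shared_sites"])

    def write(self, edges_csv: str | Path, graphml: str | Path | None = None) -> None:
        self.edge_list().to_csv(edges_csv, index=False)
        if graphml is not None:
            nx.write_graphml(self.to_graph(), graphml)


def build_sharing_network(
    visits: pd.DataFrame,
    nodes: list[str] | None = None,
    denominator: str = "union",
) -> SharingNetwork:
    """Build the weighted space-sharing network from a visit table.

    A site is shared by a pair iff both have a visit record at it on the same
    night.  The weight divides the shared-site count by the size of the pair's
    combined site repertoire: ``union`` (default, Jaccard-style) |S_i u S_j|,
    ``min`` min(|S_i|, |S_j|), or ``mean`` of the two repertoire sizes.
    Requested nodes without any visit record are dropped with a warning.
    """
    if denominator not in {"union", "min", "mean"}:
        raise ValueError("denominator must be one of union/min/mean")
    visits = visits.drop_duplicates(["bat_id", "night", "site_id"])
    present = list(pd.unique(visits["bat_id"].astype(str)))
    if nodes is None:
        nodes = sorted(present)
    else:
        missing = [b for b in nodes if str(b) not in present]
        if missing:
            logger.warning("nodes without visits excluded: %s", missing)
        nodes = [b for b in nodes if str(b) in present]
    idx = {str(b): i for i, b in enumerate(nodes)}
    n = len(nodes)
    sites_by_bat: dict[int, set] = {i: set() for i in range(n)}
    co_sites: dict[tuple[int, int], set] = {}
    for (_, site), grp in visits.groupby(["night", "site_id"]):
        bats = sorted({idx[str(b)] for b in grp["bat_id"] if str(b) in idx})
        for b in bats:
            sites_by_bat[b].add(site)
        for ai in range(len(bats)):
            for bi in range(ai + 1, len(bats)):
                co_sites.setdefault((bats[ai], bats[bi]), set()).add(site)
    W = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for (i, j), shared in co_sites.items():
        si, sj = sites_by_bat[i], sites_by_bat[j]
        if denominator == "union":
            denom = len(si | sj)
        elif denominator == "min":
            denom = min(len(si), len(sj))
        else:
            denom = 0.5 * (len(si) + len(sj))
        w = len(shared) / denom
        W[i, j] = W[j, i] = w
        counts[i, j] = counts[j, i] = len(shared)
    return SharingNetwork(nodes=tuple(str(b) for b in nodes), weights=W, shared_counts=counts)


def filter_by_relatedness(
    net: SharingNetwork, rel_matrix: pd.DataFrame, threshold: float = 0.25
) -> SharingNetwork:
    """Keep only edges between related pairs (r >= threshold); nodes retained.

    The default threshold 0.25 is the half-sib expectation; it is a
    configuration knob, not an empirical claim.
    """
    missing = set(net.nodes) - set(rel_matrix.index.astype(str))
    if missing:
        raise ValueError(f"relatedness matrix missing nodes: {sorted(missing)}")
    r = rel_matrix.loc[list(net.nodes), list(net.nodes)].to_numpy(dtype=float)
    keep = np.nan_to_num(r, nan=-1.0) >= threshold
    np.fill_diagonal(keep, False)
    return SharingNetwork(
        nodes=net.nodes,
        weights=np.where(keep, net.weights, 0.0),
        shared_counts=np.where(keep, net.shared_counts, 0),
    )


def build_coroost_matrix(records: pd.DataFrame, nodes: list[str] | None = None) -> pd.DataFrame:
    """Days-in-same-roost counts from (bat_id, day, roost_id) records.

    If a bat has several records on one day, the day's first is used.
    """
    rec = records.drop_duplicates(["bat_id", "day"], keep="first").copy()
    rec["bat_id"] = rec["bat_id"].astype(str)
    if nodes is None:
        nodes = sorted(rec["bat_id"].unique())
    idx = {b: i for i, b in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n), dtype=int)
    for (_, _), grp in rec.groupby(["day", "roost_id"]):
        bats = sorted({idx[b] for b in grp["bat_id"] if b in idx})
        for ai in range(len(bats)):
            for bi in range(ai + 1, len(bats)):
                M[bats[ai], bats[bi]] += 1
                M[bats[bi], bats[ai]] += 1
    return pd.DataFrame(M, index=nodes, columns=nodes)


@dataclass(frozen=True)
class NetworkSummary:
    density: float
    node_metrics: pd.DataFrame  # bat_id, degree_norm, clustering, strength
    mean_degree_norm: float
    mean_clustering: float
    mean_strength: float


def network_metrics(net: SharingNetwork) -> NetworkSummary:
    """Density, normalized degree, local clustering and weighted degree.

    Density is realized edges over n(n-1)/2; k_i = deg_i / (n-1); C_i is the
    unweighted local clustering coefficient (0 for degree < 2); s_i is the row
    sum of the weight matrix on the proportion scale.
    """
    n = len(net.nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    A = net.adjacency
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                g.add_edge(net.nodes[i], net.nodes[j])
    density = nx.density(g)
    k = {b: g.degree(b) / (n - 1) for b in net.nodes}
    clustering = nx.clustering(g)
    strength = {b: float(net.weights[i].sum()) for i, b in enumerate(net.nodes)}
    node_metrics = pd.DataFrame(
        {
            "bat_id": list(net.nodes),
            "degree_norm": [k[b] for b in net.nodes],
            "clustering": [clustering[b] for b in net.nodes],
            "strength": [strength[b] for b in net.nodes],
        }
    )
    return NetworkSummary(
        density=float(density),
        node_metrics=node_metrics,
        mean_degree_norm=float(node_metrics["degree_norm"].mean()),
        mean_clustering=float(node_metrics["clustering"].mean()),
        mean_strength=float(node_metrics["strength"].mean()),
    )
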