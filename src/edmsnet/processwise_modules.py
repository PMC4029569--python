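"""Process-wise modules: union of the transition subnetworks, complete-
linkage clustering of per-edge dC trajectories, and derived statistics
(components, mean trajectories, interfacing proteins, betweenness ranks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .edms_core import Subnetwork
from .network_io import Edge, Network
from .stage_correlation import EdgeProfile


@dataclass
class ClusterAssignment:
    """Edge -> cluster id (contiguous 1..k) over the union subnetwork."""

    assignment: dict[Edge, int]
    k: int
    dc_vectors: dict[Edge, np.ndarray] = field(default_factory=dict)

    def edges_of(self, cluster: int) -> set[Edge]:
        return {e for e, c in self.assignment.items() if c == cluster}

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.assignment.values()))


def union_subnetworks(
    subs: list[Subnetwork], profiles: dict[Edge, EdgeProfile]
) -> tuple[Network, dict[Edge, np.ndarray]]:
    """Edge union of the transition subnetworks, each edge carrying its
    full (K - 1)-vector of dC values."""
    if not subs:
        raise ValueError("need at least one subnetwork")
    edges: set[Edge] = set()
    for sub in subs:
        edges |= sub.edges
    missing = [e for e in edges if e not in profiles]
    if missing:
        raise ValueError(f"union edges without profiles: {missing[:5]}")
    vectors = {e: np.asarray(profiles[e].dC, dtype=float) for e in edges}
    return Network(edges), vectors


def cluster_edges(dc_vectors: dict[Edge, np.ndarray], k: int) -> ClusterAssignment:
    """Complete-linkage hierarchy on Euclidean distances between dC
    vectors, cut into (at most) k flat clusters.

    Edges are processed in canonical order, which makes the result
    invariant to the caller's edge ordering.  Duplicate vectors merge at
    distance zero and always co-cluster; if fewer than k distinct merge
    heights exist the cut can yield fewer clusters.  Ids are relabeled
    contiguously (1..k) by first appearance in canonical edge order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = sorted(dc_vectors)
    n = len(edges)
    if k > n:
        raise ValueError(f"k={k} exceeds edge count {n}")
    if n == 1 or k == 1:
        raw = [1] * n
    elif k == n:
        raw = list(range(1, n + 1))
    else:
        X = np.vstack([dc_vectors[e] for e in edges])
        Z = linkage(pdist(X, metric="euclidean"), method="complete")
        raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    assignment: dict[Edge, int] = {}
    for e, c in zip(edges, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        assignment[e] = relabel[c]
    return ClusterAssignment(
        assignment=assignment,
        k=len(relabel),
        dc_vectors={e: np.asarray(dc_vectors[e], float) for e in edges},
    )


@dataclass
class ClusterComponentStats:
    cluster: int
    n_nodes: int
    n_edges: int
    n_components_min_size: int
    largest_component: int


def cluster_components(
    assignment: ClusterAssignment, min_size: int = 5
) -> list[ClusterComponentStats]:
    """Connected-component statistics of each cluster's edge-induced graph."""
    stats: list[ClusterComponentStats] = []
    for c in assignment.clusters:
        edges = assignment.edges_of(c)
        g = nx.Graph()
        g.add_edges_from(sorted(edges))
        sizes = sorted((len(nodes) for nodes in nx.connected_components(g)), reverse=True)
        stats.append(
            ClusterComponentStats(
                cluster=c,
                n_nodes=g.number_of_nodes(),
                n_edges=g.number_of_edges(),
                n_components_min_size=sum(1 for s in sizes if s >= min_size),
                largest_component=sizes[0] if sizes else 0,
            )
        )
    return stats


def cluster_trajectory(
    assignment: ClusterAssignment,
    profiles: dict[Edge, EdgeProfile],
    value: str = "r",
) -> dict[int, np.ndarray]:
    """Per-cluster mean trajectory of members' per-stage values.

    ``value`` selects "r" (untransformed, default) or "R" (Fisher scale).
    """
    if value not in ("r", "R"):
        raise ValueError("value must be 'r' or 'R'")
    out: dict[int, np.ndarray] = {}
    for c in assignment.clusters:
        rows = [getattr(profiles[e], value) for e in sorted(assignment.edges_of(c))]
        out[c] = np.mean(np.vstack(rows), axis=0)
    return out


def interfacing_proteins(
    assignment: ClusterAssignment,
) -> dict[str, set[int]]:
    """Nodes whose incident edges span at least two clusters.

    The value is the node's cluster set; nodes touching every cluster can
    be detected by comparing against ``assignment.k``.
    """
    node_clusters: dict[str, set[int]] = {}
    for (a, b), c in assignment.assignment.items():
        node_clusters.setdefault(a, set()).add(c)
        node_clusters.setdefault(b, set()).add(c)
    return {n: cs for n, cs in sorted(node_clusters.items()) if len(cs) >= 2}


def all_cluster_interfacers(assignment: ClusterAssignment) -> list[str]:
    """Interfacing proteins touching every cluster."""
    k = len(assignment.clusters)
    return sorted(
        n for n, cs in interfacing_proteins(assignment).items() if len(cs) == k
    )


def betweenness_ranking(net: Network) -> list[tuple[str, float]]:
    """Exact unweighted betweenness centrality (raw counts), descending;
    ties broken lexicographically."""
    if not net.edges:
        raise ValueError("empty network")
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=False)
    return sorted(bc.items(), key=lambda t: (-t[1], t[0]))


def degree_ranking(net: Network) -> list[tuple[str, int]]:
    """Nodes by degree, descending; ties lexicographic."""
    g = net.to_networkx()
    return sorted(g.degree(), key=lambda t: (-t[1], t[0]))


def write_cluster_assignment(assignment: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        any_vec = next(iter(assignment.dc_vectors.values()), np.array([]))
        dc_cols = [f"dC_{i + 1}" for i in range(len(any_vec))]
        fh.write("\t".join(["node_a", "node_b", "cluster", *dc_cols]) + "\n")
        for e in sorted(assignment.assignment):
            vec = assignment.dc_vectors.get(e, np.array([]))
            vals = [f"{v:.6g}" for v in vec]
            fh.write("\t".join([e[0], e[1], str(assignment.assignment[e]), *vals]) + "\n")


def write_trajectories(trajectories: dict[int, np.ndarray], stages: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["cluster", *stages]) + "\n")
        for c in sorted(trajectories):
            vals = [f"{v:.6g}" for v in trajectories[c]]
            fh.write("\t".join([str(c), *vals]) + "\n")
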