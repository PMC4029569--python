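"""Edge-wise dense module search (eDMS).

Seed edges are split into connected components; each component grows
greedily by absorbing the adjacent network edge with the largest |dC|, as
long as the relative decrease of the module score (mean |dC| of member
edges) stays within a tolerance ``delta``.  The expanded modules are
combined by edge union, small components are filtered out, and ``delta``
is chosen by a grid scan maximizing the overall module score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .network_io import Edge, Network, canonical_edge


class EdmsError(RuntimeError):
    """Raised when a search yields no reportable subnetwork."""


def _default_grid() -> tuple[float, ...]:
    return tuple(round(0.01 * i, 2) for i in range(11))  # 0.00 .. 0.10


@dataclass
class ModuleSearchConfig:
    """Knobs of the eDMS search.

    ``delta`` is the score-decrease tolerance; when None it must be chosen
    via :func:`scan_delta` over ``delta_grid``.  ``max_iterations`` caps
    accepted absorptions per initial module; components with fewer than
    ``min_component_genes`` genes are dropped from the final subnetwork.
    """

    delta: float | None = None
    delta_grid: tuple[float, ...] = field(default_factory=_default_grid)
    max_iterations: int = 100
    min_component_genes: int = 5
    seed_fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be >= 0")
        if any(d < 0 for d in self.delta_grid):
            raise ValueError("delta_grid values must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_component_genes < 1:
            raise ValueError("min_component_genes must be >= 1")
        if not 0 < self.seed_fraction <= 1:
            raise ValueError("seed_fraction must be in (0, 1]")


@dataclass
class Subnetwork:
    """An edge subset of the reference network with per-edge |dC| scores."""

    edges: set[Edge]
    dc: dict[Edge, float]
    transition: int | None = None
    edge_attributes: dict[Edge, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("subnetwork edge set is empty")
        missing = self.edges - set(self.dc)
        if missing:
            raise ValueError(f"edges without dC score: {sorted(missing)[:5]}")

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(sorted(self.edges))
        return g

    def components(self) -> list[set[Edge]]:
        """Edge sets of connected components, in sorted-node order."""
        g = self.to_networkx()
        comps = []
        for nodes in nx.connected_components(g):
            comp_edges = {e for e in self.edges if e[0] in nodes}
            comps.append(comp_edges)
        comps.sort(key=lambda es: min(es))
        return comps

    def component_scores(self) -> list[float]:
        return [module_score(es, self.dc) for es in self.components()]


def module_score(edges: Iterable[Edge], dc_map: Mapping[Edge, float]) -> float:
    """Mean |dC| over the member edges."""
    edges = list(edges)
    if not edges:
        raise ValueError("module score of an empty edge set is undefined")
    return sum(abs(dc_map[e]) for e in edges) / len(edges)


def seed_components(seed_edges: Iterable[Edge], net: Network) -> list[set[Edge]]:
    """Connected components of the seed-edge graph; one initial module each."""
    seeds = {canonical_edge(*e) for e in seed_edges}
    outside = seeds - net.edges
    if outside:
        raise ValueError(f"seed edges not in network: {sorted(outside)[:5]}")
    g = nx.Graph()
    g.add_edges_from(seeds)
    comps = []
    for nodes in nx.connected_components(g):
        comps.append({e for e in seeds if e[0] in nodes})
    comps.sort(key=lambda es: min(es))
    return comps


def expand_module(
    module: Iterable[Edge],
    net: Network,
    dc_map: Mapping[Edge, float],
    config: ModuleSearchConfig,
) -> set[Edge]:
    """Greedy expansion of one module.

    Each step considers every network edge outside the module with at
    least one endpoint inside, takes the one with maximum |dC| (ties by
    canonical edge name), and accepts it iff the relative score decrease
    (S - S') / S does not exceed ``delta`` (increases always accepted).
    Stops at the first rejection or after ``max_iterations`` acceptances.
    """
    if config.delta is None:
        raise ValueError("config.delta must be set (run scan_delta first)")
    edges = {canonical_edge(*e) for e in module}
    if not edges:
        raise ValueError("cannot expand an empty module")
    nodes = {n for e in edges for n in e}
    adj = net.adjacency()
    total = sum(abs(dc_map[e]) for e in edges)
    score = total / len(edges)

    for _ in range(config.max_iterations):
        best: Edge | None = None
        best_dc = -1.0
        for node in nodes:
            for nb in adj.get(node, ()):
                e = canonical_edge(node, nb)
                if e in edges:
                    continue
                v = abs(dc_map[e])
                if v > best_dc or (v == best_dc and (best is None or e < best)):
                    best, best_dc = e, v
        if best is None:
            break
        new_score = (total + best_dc) / (len(edges) + 1)
        if new_score < score and (score - new_score) / score > config.delta:
            break
        edges.add(best)
        nodes.update(best)
        total += best_dc
        score = new_score
    return edges


def edms(
    net: Network,
    dc_map: Mapping[Edge, float],
    seed_edges: Iterable[Edge],
    config: ModuleSearchConfig,
    transition: int | None = None,
) -> Subnetwork:
    """Full search: expand every seed component, union, filter small components."""
    expanded: set[Edge] = set()
    for comp in seed_components(seed_edges, net):
        expanded |= expand_module(comp, net, dc_map, config)

    g = nx.Graph()
    g.add_edges_from(expanded)
    kept: set[Edge] = set()
    dropped = 0
    for nodes in nx.connected_components(g):
        if len(nodes) >= config.min_component_genes:
            kept |= {e for e in expanded if e[0] in nodes}
        else:
            dropped += 1
    if not kept:
        raise EdmsError(
            f"all {dropped} components fell below {config.min_component_genes} genes "
            f"(expanded edge count {len(expanded)}); consider a larger delta or more seeds"
        )
    return Subnetwork(
        edges=kept,
        dc={e: float(dc_map[e]) for e in kept},
        transition=transition,
    )


def overall_module_score(sub: Subnetwork) -> float:
    """Unweighted mean of the component module scores."""
    scores = sub.component_scores()
    return sum(scores) / len(scores)


def scan_delta(
    net: Network,
    dc_map: Mapping[Edge, float],
    seed_edges: Iterable[Edge],
    config: ModuleSearchConfig,
) -> tuple[float, list[dict]]:
    """Run eDMS per grid delta; return (best delta, per-delta report).

    Best = maximal overall module score, ties resolved toward the smallest
    delta.  Deltas whose search fails are reported with score None.
    """
    if not config.delta_grid:
        raise ValueError("delta_grid is empty")
    seed_edges = list(seed_edges)
    report: list[dict] = []
    best_delta: float | None = None
    best_score = float("-inf")
    for delta in config.delta_grid:
        cfg = ModuleSearchConfig(
            delta=delta,
            delta_grid=config.delta_grid,
            max_iterations=config.max_iterations,
            min_component_genes=config.min_component_genes,
            seed_fraction=config.seed_fraction,
        )
        row: dict = {"delta": delta}
        try:
            sub = edms(net, dc_map, seed_edges, cfg)
        except EdmsError as exc:
            row.update(score=None, n_edges=0, n_nodes=0, n_components=0, error=str(exc))
        else:
            score = overall_module_score(sub)
            row.update(
                score=score,
                n_edges=len(sub.edges),
                n_nodes=len(sub.nodes),
                n_components=len(sub.components()),
            )
            if score > best_score:
                best_delta, best_score = delta, score
        report.append(row)
    if best_delta is None:
        raise EdmsError("eDMS failed at every delta in the grid")
    return best_delta, report
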