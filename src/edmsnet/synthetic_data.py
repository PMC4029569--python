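"""Synthetic multi-stage datasets with planted differential co-expression.

The generator emits an interactome, an ordered stage design, and an
expression matrix in which planted edge groups follow prescribed per-stage
population correlations (shared-latent-factor construction), against a
background of independent noise.  Ground truth is serializable so recovery
can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn.metrics import rand_score

from .network_io import (
    Edge,
    ExpressionMatrix,
    Network,
    StageDesign,
    canonical_edge,
    write_gene_sets,
)

DEFAULT_STAGES = ("N", "C", "D", "E", "A")
DEFAULT_STAGE_SIZES = (10, 10, 17, 18, 17)
MAX_TARGET_R = 0.99


@dataclass
class PlantedGroup:
    """An edge group sharing one latent factor per stage.

    ``trajectory`` holds the per-stage target Pearson correlation for all
    gene pairs within the group (so in particular for its edges).
    """

    name: str
    edges: list[Edge]
    trajectory: list[float]

    def __post_init__(self) -> None:
        self.edges = [canonical_edge(*e) for e in self.edges]
        if any(abs(t) >= MAX_TARGET_R for t in self.trajectory):
            raise ValueError(f"group {self.name}: |target r| must be < {MAX_TARGET_R}")

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass
class PlantedTruth:
    groups: list[PlantedGroup]
    background_r: float = 0.0
    marked_sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[Edge] = set()
        for g in self.groups:
            overlap = seen & set(g.edges)
            if overlap:
                raise ValueError(f"groups share edges: {sorted(overlap)[:5]}")
            seen |= set(g.edges)

    @property
    def planted_edges(self) -> set[Edge]:
        return {e for g in self.groups for e in g.edges}

    def partition(self) -> dict[Edge, str]:
        return {e: g.name for g in self.groups for e in g.edges}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "background_r": self.background_r,
            "groups": [
                {
                    "name": g.name,
                    "edges": [list(e) for e in sorted(g.edges)],
                    "trajectory": list(g.trajectory),
                }
                for g in self.groups
            ],
            "marked_sets": {k: sorted(v) for k, v in self.marked_sets.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            groups=[
                PlantedGroup(g["name"], [tuple(e) for e in g["edges"]], g["trajectory"])
                for g in payload["groups"]
            ],
            background_r=payload.get("background_r", 0.0),
            marked_sets={k: set(v) for k, v in payload.get("marked_sets", {}).items()},
        )


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(
    n_nodes: int,
    model: str = "scale-free",
    seed: int | None = None,
    m: int = 3,
    p: float = 0.05,
) -> Network:
    """Connected simple graph with string node names.

    ``scale-free`` uses preferential attachment (heavy-tailed degrees, so
    hubs exist); ``erdos-renyi`` draws G(n, p) and deterministically
    bridges any disconnected components.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if model == "scale-free":
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "erdos-renyi":
        g = nx.gnp_random_graph(n_nodes, p, seed=seed)
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: c[0])
        for prev, cur in zip(comps[:-1], comps[1:]):
            g.add_edge(prev[0], cur[0])
    else:
        raise ValueError(f"unknown model {model!r}")
    return Network({canonical_edge(_node_name(a), _node_name(b)) for a, b in g.edges()})


def make_design(
    stage_sizes: tuple[int, ...] = DEFAULT_STAGE_SIZES,
    stages: tuple[str, ...] = DEFAULT_STAGES,
) -> StageDesign:
    """Ordered design with samples S00001... assigned stage by stage."""
    if len(stage_sizes) != len(stages):
        raise ValueError("stage_sizes and stages must have equal length")
    assignment: dict[str, str] = {}
    i = 0
    for stage, n in zip(stages, stage_sizes):
        for _ in range(n):
            i += 1
            assignment[f"S{i:05d}"] = stage
    return StageDesign(list(stages), assignment)


@dataclass
class GroupSpec:
    """Requested shape of one planted group (built by :func:`plant_groups`)."""

    name: str
    trajectory: list[float]
    n_nodes: int = 8
    n_edges: int = 12


def plant_groups(
    net: Network, specs: list[GroupSpec], rng: np.random.Generator
) -> PlantedTruth:
    """Create planted groups by wiring dense connected subgraphs into the
    network on previously group-free nodes (augmenting ``net`` in place).

    Each group is a random spanning tree plus extra edges among its nodes,
    so losing a few edges rarely disconnects it.
    """
    used: set[str] = set()
    pool = sorted(net.nodes)
    groups: list[PlantedGroup] = []
    for spec in specs:
        max_edges = spec.n_nodes * (spec.n_nodes - 1) // 2
        if spec.n_edges > max_edges:
            raise ValueError(f"group {spec.name}: {spec.n_edges} edges > C({spec.n_nodes},2)")
        candidates = [n for n in pool if n not in used]
        if len(candidates) < spec.n_nodes:
            raise ValueError("not enough free nodes to plant all groups")
        nodes = sorted(rng.choice(candidates, size=spec.n_nodes, replace=False).tolist())
        used |= set(nodes)
        edges: set[Edge] = set()
        order = rng.permutation(spec.n_nodes)
        for i in range(1, spec.n_nodes):  # random spanning tree
            j = int(rng.integers(0, i))
            edges.add(canonical_edge(nodes[order[i]], nodes[order[j]]))
        all_pairs = [
            canonical_edge(nodes[i], nodes[j])
            for i in range(spec.n_nodes)
            for j in range(i + 1, spec.n_nodes)
        ]
        extra = [e for e in all_pairs if e not in edges]
        n_extra = spec.n_edges - len(edges)
        if n_extra > 0:
            picked = rng.choice(len(extra), size=n_extra, replace=False)
            edges |= {extra[i] for i in picked}
        for e in edges:
            net.add_edge(*e)
        groups.append(PlantedGroup(spec.name, sorted(edges), list(spec.trajectory)))
    return PlantedTruth(groups=groups)


def _group_signs(group: PlantedGroup) -> dict[str, int]:
    """Two-coloring signs so that negative targets flip across each edge."""
    g = nx.Graph()
    g.add_edges_from(group.edges)
    try:
        color = nx.bipartite.color(g)
    except nx.NetworkXError as exc:
        raise ValueError(
            f"group {group.name}: negative targets need a bipartite edge group"
        ) from exc
    return {n: 1 if c == 0 else -1 for n, c in color.items()}


def generate_expression(
    net: Network,
    design: StageDesign,
    truth: PlantedTruth,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Expression matrix realizing the planted correlation structure.

    Within each stage, genes of a planted group follow
    ``x_g = w_g * z + sqrt(1 - w_g^2) * e_g`` with a shared latent ``z``
    and ``w_g = s_g * sqrt(|r|)``, which gives population pairwise
    correlation ``s_a * s_b * |r|``; signs are +1 for non-negative targets
    and alternate over a two-coloring for negative ones.  Background genes
    are independent noise.
    """
    missing = truth.planted_edges - net.edges
    if missing:
        raise ValueError(f"planted edges absent from network: {sorted(missing)[:5]}")
    for g in truth.groups:
        if len(g.trajectory) != design.K:
            raise ValueError(f"group {g.name}: trajectory length != K")
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    samples = [s for stage in design.stages for s in design.samples_of(stage)]
    values = rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    col_idx = {s: j for j, s in enumerate(samples)}

    for group in truth.groups:
        signs = (
            _group_signs(group)
            if any(t < 0 for t in group.trajectory)
            else {g: 1 for g in group.genes}
        )
        members = sorted(group.genes)
        rows = np.array([gene_idx[g] for g in members])
        sgn = np.array([signs[g] for g in members], dtype=float)
        for stage, target in zip(design.stages, group.trajectory):
            cols = np.array([col_idx[s] for s in design.samples_of(stage)])
            if abs(target) >= MAX_TARGET_R:
                raise ValueError(f"unattainable target r {target}")
            w = np.sqrt(abs(target))
            z = rng.normal(0.0, 1.0, size=len(cols))
            e = rng.normal(0.0, 1.0, size=(len(rows), len(cols)))
            x = (sgn[:, None] * w) * z[None, :] + np.sqrt(1 - w * w) * e
            values[np.ix_(rows, cols)] = noise_sd * x
    return ExpressionMatrix(genes, samples, values)


def mock_gene_sets(
    net: Network,
    truth: PlantedTruth,
    rng: np.random.Generator,
    background_rate: float = 0.05,
    enrichment_factor: float = 5.0,
    name: str = "MOCK_MARKED",
) -> dict[str, set[str]]:
    """A marked gene set enriched on planted genes by ``enrichment_factor``."""
    planted = {g for grp in truth.groups for g in grp.genes}
    marked: set[str] = set()
    p_planted = min(1.0, background_rate * enrichment_factor)
    for gene in sorted(net.nodes):
        p = p_planted if gene in planted else background_rate
        if rng.random() < p:
            marked.add(gene)
    if not marked:
        marked = {sorted(planted)[0]} if planted else {sorted(net.nodes)[0]}
    truth.marked_sets[name] = marked
    return {name: marked}


def recovery_metrics(
    truth: PlantedTruth,
    found_edges: set[Edge] | None = None,
    found_partition: dict[Edge, int] | None = None,
) -> dict[str, float]:
    """Edge-level precision/recall/Jaccard and (optionally) a Rand index.

    The Rand index compares the found cluster partition with the planted
    group partition, restricted to planted edges that were assigned.
    """
    out: dict[str, float] = {}
    true_edges = truth.planted_edges
    if found_edges is not None:
        found = {canonical_edge(*e) for e in found_edges}
        tp = len(found & true_edges)
        out["precision"] = tp / len(found) if found else 0.0
        out["recall"] = tp / len(true_edges) if true_edges else 0.0
        union = len(found | true_edges)
        out["jaccard"] = tp / union if union else 0.0
    if found_partition is not None:
        planted_partition = truth.partition()
        common = sorted(set(planted_partition) & set(found_partition))
        if common:
            names = sorted({planted_partition[e] for e in common})
            name_id = {n: i for i, n in enumerate(names)}
            a = [name_id[planted_partition[e]] for e in common]
            b = [found_partition[e] for e in common]
            out["rand_index"] = float(rand_score(a, b))
    return out


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["gene", *expr.samples]) + "\n")
        for i, g in enumerate(expr.genes):
            vals = "\t".join(f"{v:.6g}" for v in expr.values[i])
            fh.write(f"{g}\t{vals}\n")


def write_design(design: StageDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstage\n")
        for s, st in design.assignment.items():
            fh.write(f"{s}\t{st}\n")


def write_network(net: Network, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


@dataclass
class SimulationConfig:
    """End-to-end dataset recipe for :func:`simulate`."""

    n_nodes: int = 300
    model: str = "scale-free"
    m: int = 3
    stage_sizes: tuple[int, ...] = DEFAULT_STAGE_SIZES
    stages: tuple[str, ...] = DEFAULT_STAGES
    groups: list[GroupSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    background_rate: float = 0.05
    enrichment_factor: float = 5.0

    def __post_init__(self) -> None:
        if not self.groups:
            K = len(self.stages)
            up = [0.0] * K
            down = [0.0] * K
            if K >= 3:
                up[1] = up[2] = 0.9
                down[0] = 0.9
                down[-1] = down[-2] = 0.9
            self.groups = [
                GroupSpec("group_early", up),
                GroupSpec("group_late", down),
            ]


def simulate(
    out_dir: str | Path, seed: int, config: SimulationConfig | None = None
) -> dict[str, Path]:
    """Generate a full dataset bundle and write it as plain-text files."""
    config = config or SimulationConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    net = generate_network(config.n_nodes, model=config.model, seed=seed, m=config.m)
    design = make_design(tuple(config.stage_sizes), tuple(config.stages))
    truth = plant_groups(net, config.groups, rng)
    expr = generate_expression(net, design, truth, noise_sd=config.noise_sd, seed=seed + 1)
    sets = mock_gene_sets(
        net, truth, rng,
        background_rate=config.background_rate,
        enrichment_factor=config.enrichment_factor,
    )
    paths = {
        "expression": out_dir / "expression.tsv",
        "design": out_dir / "design.tsv",
        "network": out_dir / "network.tsv",
        "gene_sets": out_dir / "genesets.gmt",
        "truth": out_dir / "truth.json",
    }
    write_expression(expr, paths["expression"])
    write_design(design, paths["design"])
    write_network(net, paths["network"])
    write_gene_sets(sets, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths
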