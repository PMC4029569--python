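"""Readers and writers for expression matrices, stage designs, interaction
networks, gene sets, and subnetwork outputs.

All genes and samples are plain string identifiers; no ID mapping is
performed.  Edges are canonicalized as sorted 2-tuples so that ``(a, b)``
and ``(b, a)`` denote the same undirected pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Edge = tuple[str, str]

#: header tokens recognized (case-insensitively) in edge-list files
_EDGE_HEADER_TOKENS = {
    "protein_a", "protein_b", "gene_a", "gene_b", "genea", "geneb",
    "source", "target", "node1", "node2", "from", "to",
    "interactor_a", "interactor_b",
}


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair ``{a, b}`` as a sorted tuple."""
    return (a, b) if a <= b else (b, a)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression intensities."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise FormatError(f"duplicate gene identifiers: {dup[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample identifiers")
        if np.isnan(self.values).any():
            raise FormatError("missing values in expression matrix are not allowed")
        self._gene_idx = {g: i for i, g in enumerate(self.genes)}
        self._sample_idx = {s: j for j, s in enumerate(self.samples)}

    def gene_index(self, gene: str) -> int:
        return self._gene_idx[gene]

    def sample_columns(self, samples: Iterable[str]) -> np.ndarray:
        return np.array([self._sample_idx[s] for s in samples], dtype=int)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_idx[gene]]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        cols = self.sample_columns(samples)
        return ExpressionMatrix(list(self.genes), list(samples), self.values[:, cols])


@dataclass
class StageDesign:
    """Ordered stage labels and the sample -> stage assignment.

    ``stages`` fixes the biological ordering (K stages, K - 1 transitions);
    the order is taken from the design file, first appearance wins.
    """

    stages: list[str]
    assignment: dict[str, str]

    MIN_SAMPLES_PER_STAGE = 3

    def __post_init__(self) -> None:
        unknown = {v for v in self.assignment.values()} - set(self.stages)
        if unknown:
            raise FormatError(f"assignment references unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            n = len(self.samples_of(stage))
            if n < self.MIN_SAMPLES_PER_STAGE:
                raise FormatError(
                    f"stage {stage!r} has {n} samples; "
                    f"at least {self.MIN_SAMPLES_PER_STAGE} required"
                )

    @property
    def K(self) -> int:
        return len(self.stages)

    @property
    def n_transitions(self) -> int:
        return len(self.stages) - 1

    def samples_of(self, stage: str) -> list[str]:
        return [s for s, st in self.assignment.items() if st == stage]

    def stage_sizes(self) -> list[int]:
        return [len(self.samples_of(st)) for st in self.stages]

    def transitions(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    def transition_label(self, k: int) -> str:
        a, b = self.transitions()[k]
        return f"{a}-{b}"

    def reversed(self) -> "StageDesign":
        return StageDesign(list(reversed(self.stages)), dict(self.assignment))


@dataclass
class Network:
    """A simple undirected graph over gene identifiers."""

    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {canonical_edge(a, b) for a, b in self.edges if a != b}
        self._adj: dict[str, set[str]] | None = None

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {}
            for a, b in self.edges:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            self._adj = adj
        return self._adj

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed")
        self.edges.add(canonical_edge(a, b))
        self._adj = None

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def degree(self, node: str) -> int:
        return len(self.adjacency().get(node, ()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(sorted(self.edges))
        return g


def read_expression(path: str | Path, design_path: str | Path) -> tuple[ExpressionMatrix, StageDesign]:
    """Read a genes x samples TSV and its sample -> stage design.

    Samples present in the design but absent from the matrix are an error;
    matrix samples missing from the design are dropped with a warning.
    """
    path, design_path = Path(path), Path(design_path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"malformed expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate gene IDs {dup[:5]}")

    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in design_df.columns}
    if "sample" not in cols or "stage" not in cols:
        raise FormatError(f"{design_path}: design needs 'sample' and 'stage' columns")
    assignment: dict[str, str] = {}
    stages: list[str] = []
    for _, row in design_df.iterrows():
        s, st = row[cols["sample"]], row[cols["stage"]]
        if s in assignment:
            raise FormatError(f"{design_path}: sample {s!r} assigned twice")
        assignment[s] = st
        if st not in stages:
            stages.append(st)

    matrix_samples = [str(c) for c in df.columns]
    missing = [s for s in assignment if s not in set(matrix_samples)]
    if missing:
        raise FormatError(f"design samples absent from expression matrix: {missing[:5]}")
    unassigned = [s for s in matrix_samples if s not in assignment]
    if unassigned:
        log.warning(
            "dropping %d expression samples not assigned to any stage: %s",
            len(unassigned), unassigned[:5],
        )
    kept = [s for s in matrix_samples if s in assignment]
    expr = ExpressionMatrix(
        [str(g) for g in df.index], kept, df[kept].to_numpy(dtype=float)
    )
    design = StageDesign(stages, assignment)
    return expr, design


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.lower() in _EDGE_HEADER_TOKENS for f in fields[:2])


def read_network(path: str | Path) -> Network:
    """Read an undirected edge list (two-column TSV, or SIF for ``.sif``).

    Extra columns are ignored; duplicate edges and self-loops are removed
    with their counts logged.  Rereading a SIF file written by
    :func:`write_subnetwork` yields an identical edge set.
    """
    path = Path(path)
    sif = path.suffix.lower() == ".sif"
    edges: set[Edge] = set()
    n_dup = n_loop = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if sif:
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: SIF row needs 3 fields")
                a, b = fields[0], fields[2]
            else:
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: edge row needs 2 columns")
                a, b = fields[0], fields[1]
            if lineno == 1 and not sif and _looks_like_header(fields):
                continue
            n_rows += 1
            if a == b:
                n_loop += 1
                continue
            e = canonical_edge(a, b)
            if e in edges:
                n_dup += 1
            edges.add(e)
    if n_rows == 0:
        raise FormatError(f"{path}: empty edge list")
    if n_dup or n_loop:
        log.info("%s: removed %d duplicate edges and %d self-loops", path, n_dup, n_loop)
    return Network(edges)


def restrict_network(net: Network, expr: ExpressionMatrix) -> Network:
    """Induced subgraph on the genes present in the expression matrix."""
    genes = set(expr.genes)
    edges = {e for e in net.edges if e[0] in genes and e[1] in genes}
    if not edges:
        raise ValueError("no network edge has both endpoints in the expression matrix")
    return Network(edges)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (name, description, genes; tab-separated)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = sorted(sets[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_subnetwork(sub, prefix: str | Path) -> dict[str, Path]:
    """Write a subnetwork as SIF + edge-attribute TSV + GraphML.

    ``sub`` is duck-typed: it must expose ``edges`` (iterable of canonical
    pairs) and may expose ``edge_attributes`` (edge -> {name: value}) whose
    values are written per edge (per-stage r, per-transition dC, cluster id).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edges = sorted(sub.edges)
    attrs: Mapping[Edge, Mapping[str, object]] = getattr(sub, "edge_attributes", {}) or {}
    attr_names = sorted({k for d in attrs.values() for k in d})

    sif_path = prefix.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\tpp\t{b}\n")

    tsv_path = Path(str(prefix) + ".edges.tsv")
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(["node_a", "node_b", *attr_names]) + "\n")
        for e in edges:
            row = [e[0], e[1]]
            d = attrs.get(e, {})
            for name in attr_names:
                v = d.get(name, "")
                row.append(f"{v:.6g}" if isinstance(v, float) else str(v))
            fh.write("\t".join(row) + "\n")

    g = nx.Graph()
    for e in edges:
        clean = {k: v for k, v in attrs.get(e, {}).items() if v is not None}
        g.add_edge(*e, **clean)
    graphml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    return {"sif": sif_path, "edges_tsv": tsv_path, "graphml": graphml_path}


def read_subnetwork(prefix: str | Path) -> tuple[set[Edge], dict[Edge, dict[str, str]]]:
    """Read back the SIF + edge-attribute TSV written by :func:`write_subnetwork`."""
    prefix = Path(prefix)
    net = read_network(prefix.with_suffix(".sif"))
    attrs: dict[Edge, dict[str, str]] = {}
    tsv_path = Path(str(prefix) + ".edges.tsv")
    if tsv_path.exists():
        df = pd.read_csv(tsv_path, sep="\t", dtype=str)
        for _, row in df.iterrows():
            e = canonical_edge(row["node_a"], row["node_b"])
            attrs[e] = {c: row[c] for c in df.columns if c not in ("node_a", "node_b")}
    return net.edges, attrs
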