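"""Seed ranking and seed-quality diagnostics.

Edges are ranked per transition by |dC| (differentially co-expressed
pairs, DCPs); genes by absolute log fold change of stage means
(differentially expressed genes, DEGs).  Differentially co-expressed
genes (DCGs) are the endpoints of DCPs.  Diagnostics: hypergeometric
gene-set enrichment and mean shortest-path compactness in the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import networkx as nx
import numpy as np
from scipy import stats

from .network_io import Edge, ExpressionMatrix, Network, StageDesign
from .stage_correlation import EdgeProfile


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass
class SeedSet:
    """Top-ranked items for one transition, at a given top-fraction level."""

    transition: int
    kind: Literal["DEG", "DCP", "DCG"]
    members: list
    fraction: float
    scores: list[float]


def rank_dcps(
    profiles: dict[Edge, EdgeProfile], transition: int
) -> list[tuple[Edge, float]]:
    """Edges in decreasing |dC(transition)|; ties broken by edge name."""
    scored = [(e, abs(float(p.dC[transition]))) for e, p in profiles.items()]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def rank_degs(
    expr: ExpressionMatrix, design: StageDesign, transition: int
) -> list[tuple[str, float]]:
    """Genes in decreasing |mean(stage k+1) - mean(stage k)|.

    Expression is assumed log-scale, so the difference of means is a log
    fold change.
    """
    a, b = design.transitions()[transition]
    cols_a = expr.sample_columns(design.samples_of(a))
    cols_b = expr.sample_columns(design.samples_of(b))
    lfc = expr.values[:, cols_b].mean(axis=1) - expr.values[:, cols_a].mean(axis=1)
    scored = [(g, abs(float(v))) for g, v in zip(expr.genes, lfc)]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def top_fraction(
    ranked: list[tuple],
    fraction: float,
    kind: Literal["DEG", "DCP"] = "DCP",
    transition: int = 0,
) -> SeedSet:
    """First round_half_up(fraction * N) items of a ranked list."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    count = round_half_up(fraction * len(ranked))
    if count == 0:
        raise ValueError(
            f"top fraction {fraction} of {len(ranked)} items selects nothing"
        )
    head = ranked[:count]
    return SeedSet(
        transition=transition,
        kind=kind,
        members=[m for m, _ in head],
        fraction=fraction,
        scores=[s for _, s in head],
    )


def dcgs_from_dcps(seed_edges: Iterable[Edge]) -> set[str]:
    """Union of edge endpoints."""
    return {g for e in seed_edges for g in e}


def set_enrichment(
    foreground: set[str], annotated: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric enrichment of ``annotated`` in ``foreground``.

    Returns (overlap count, p of observing >= overlap annotated genes in
    |foreground| draws without replacement from the universe).
    """
    if not universe:
        raise ValueError("universe is empty")
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    annotated_u = annotated & universe
    overlap = len(foreground & annotated_u)
    p = float(
        stats.hypergeom.sf(
            overlap - 1, len(universe), len(annotated_u), len(foreground)
        )
    )
    return overlap, p


def mean_shortest_path(
    genes: set[str], net: Network
) -> tuple[float, float, int]:
    """Mean and sample SD of shortest-path lengths between gene pairs.

    Paths run through the full network; pairs with no connecting path (or
    with an endpoint absent from the network) are excluded and counted.
    A single usable pair reports SD 0.
    """
    genes = set(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    g = net.to_networkx()
    members = sorted(genes)
    present = [m for m in members if m in g]
    n_total_pairs = len(members) * (len(members) - 1) // 2
    lengths: list[int] = []
    for i, src in enumerate(present):
        dist = nx.single_source_shortest_path_length(g, src)
        for tgt in present[i + 1:]:
            if tgt in dist:
                lengths.append(dist[tgt])
    excluded = n_total_pairs - len(lengths)
    if not lengths:
        raise ValueError("all gene pairs are disconnected")
    arr = np.array(lengths, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, excluded


def deg_ttest(
    expr: ExpressionMatrix,
    design: StageDesign,
    gene: str,
    stage_a: str,
    stage_b: str,
    alpha: float = 0.05,
) -> tuple[str | None, float]:
    """Welch t-test of a gene between two stages.

    Returns (label, p); label is "up"/"down" (stage_b relative to stage_a)
    only when p < alpha, else None.
    """
    xa = expr.row(gene)[expr.sample_columns(design.samples_of(stage_a))]
    xb = expr.row(gene)[expr.sample_columns(design.samples_of(stage_b))]
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each stage needs at least 2 samples")
    diff = float(xb.mean() - xa.mean())
    if xa.std() == 0 and xb.std() == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(stats.ttest_ind(xb, xa, equal_var=False).pvalue)
    if p < alpha and diff != 0:
        return ("up" if diff > 0 else "down"), p
    return None, p
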