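"""Post-processing of transition-wise subnetworks: hubs, recurrent edges,
gene-set coverage, and per-stage significance pattern labels (NS/HP/HN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from statsmodels.stats.multitest import multipletests

from .edms_core import Subnetwork
from .network_io import Edge, StageDesign, canonical_edge
from .seed_analysis import set_enrichment
from .stage_correlation import EdgeProfile, correlation_pvalue

#: a hub has more than six connections
HUB_MIN_DEGREE = 7


@dataclass
class SubnetworkSummary:
    """Headline statistics of one transition-wise subnetwork."""

    transition: int
    transition_label: str
    n_nodes: int
    n_edges: int
    gene_set_overlap: dict[str, int] = field(default_factory=dict)
    gene_set_pvalue: dict[str, float] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)


def find_hubs(sub: Subnetwork, min_degree: int = HUB_MIN_DEGREE) -> list[str]:
    """Nodes with degree >= min_degree within the subnetwork, sorted."""
    g = sub.to_networkx()
    return sorted(n for n, d in g.degree() if d >= min_degree)


def recurrent_edges(subs: list[Subnetwork]) -> dict[Edge, set[int]]:
    """Edges appearing in at least two transition subnetworks."""
    if len(subs) < 2:
        raise ValueError("need at least 2 subnetworks")
    seen: dict[Edge, set[int]] = {}
    for i, sub in enumerate(subs):
        t = sub.transition if sub.transition is not None else i
        for e in sub.edges:
            seen.setdefault(e, set()).add(t)
    return {e: ts for e, ts in seen.items() if len(ts) >= 2}


def stage_pattern_labels(
    edges: set[Edge] | list[Edge],
    profiles: dict[Edge, EdgeProfile],
    design: StageDesign,
    fdr: float = 0.25,
) -> dict[Edge, list[str]]:
    """Per-stage NS/HP/HN label for each edge in the set.

    Within each stage, raw two-sided correlation p-values of the edge set
    form one BH family; labels are HP (significant, r > 0), HN
    (significant, r < 0), or NS, at the given FDR level.  The family is the
    edge set under scrutiny, so the labels depend on which edges are passed
    together.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    edge_list = sorted(canonical_edge(*e) for e in set(edges))
    missing = [e for e in edge_list if e not in profiles]
    if missing:
        raise ValueError(f"edges without profiles: {missing[:5]}")
    labels: dict[Edge, list[str]] = {e: [] for e in edge_list}
    sizes = design.stage_sizes()
    for k in range(design.K):
        n = sizes[k]
        pvals = [correlation_pvalue(float(profiles[e].r[k]), n) for e in edge_list]
        reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for e, sig in zip(edge_list, reject):
            r = float(profiles[e].r[k])
            if sig and r > 0:
                labels[e].append("HP")
            elif sig and r < 0:
                labels[e].append("HN")
            else:
                labels[e].append("NS")
    return labels


def pattern_string(labels: list[str]) -> str:
    return "-".join(labels)


def implied_r_cutoff(
    edges: set[Edge] | list[Edge],
    profiles: dict[Edge, EdgeProfile],
    design: StageDesign,
    stage: str,
    fdr: float = 0.25,
) -> float | None:
    """Smallest |r| among edges significant in ``stage`` at the given FDR.

    Exposes the implied threshold behind statements like "significant at
    FDR 0.25, equivalent to |r| > c".  Returns None when nothing is
    significant.
    """
    labels = stage_pattern_labels(edges, profiles, design, fdr=fdr)
    k = design.stages.index(stage)
    sig_r = [
        abs(float(profiles[canonical_edge(*e)].r[k]))
        for e, lab in labels.items()
        if lab[k] != "NS"
    ]
    return min(sig_r) if sig_r else None


def summarize_subnetwork(
    sub: Subnetwork,
    design: StageDesign,
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> SubnetworkSummary:
    """Node/edge counts, per-gene-set overlap and enrichment p, hub list."""
    nodes = sub.nodes
    overlap: dict[str, int] = {}
    pvals: dict[str, float] = {}
    for name, genes in gene_sets.items():
        overlap[name], pvals[name] = set_enrichment(nodes & universe, genes, universe)
    t = sub.transition if sub.transition is not None else 0
    return SubnetworkSummary(
        transition=t,
        transition_label=design.transition_label(t),
        n_nodes=len(nodes),
        n_edges=len(sub.edges),
        gene_set_overlap=overlap,
        gene_set_pvalue=pvals,
        hubs=find_hubs(sub),
    )


def write_summary_table(summaries: list[SubnetworkSummary], path) -> None:
    """TSV mirroring the transition / nodes / edges / gene-set / hubs layout."""
    set_names = sorted({n for s in summaries for n in s.gene_set_overlap})
    with open(path, "w") as fh:
        cols = ["transition", "n_nodes", "n_edges"]
        for n in set_names:
            cols += [f"{n}_overlap", f"{n}_p"]
        cols.append("hubs")
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            row = [s.transition_label, str(s.n_nodes), str(s.n_edges)]
            for n in set_names:
                row.append(str(s.gene_set_overlap.get(n, "")))
                p = s.gene_set_pvalue.get(n)
                row.append(f"{p:.3g}" if p is not None else "")
            row.append(",".join(s.hubs))
            fh.write("\t".join(row) + "\n")
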