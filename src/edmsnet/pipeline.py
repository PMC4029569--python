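"""End-to-end orchestration: profiles -> seeds -> per-transition module
search -> union -> trajectory clustering -> enrichment -> reports."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import (
    edms_core,
    enrichment,
    network_io,
    processwise_modules,
    seed_analysis,
    stage_correlation,
    synthetic_data,
    transition_analysis,
)
from .edms_core import ModuleSearchConfig, Subnetwork

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def parse_delta_grid(text: str) -> tuple[float, ...]:
    """Parse "start:stop:step" (inclusive) or a comma-separated list."""
    if ":" in text:
        start, stop, step = (float(x) for x in text.split(":"))
        if step <= 0:
            raise ValueError("delta grid step must be positive")
        n = int(round((stop - start) / step))
        return tuple(round(start + i * step, 10) for i in range(n + 1))
    return tuple(float(x) for x in text.split(","))


@dataclass
class RunConfig:
    """Validated inputs and knobs for one pipeline run."""

    expression: str
    design: str
    network: str
    out_dir: str
    gene_sets: str | None = None
    annotation: str | None = None
    hierarchy: str | None = None
    truth: str | None = None
    seed: int = 0
    seed_fraction: float = 0.001
    delta_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(round(0.01 * i, 2) for i in range(11))
    )
    max_iterations: int = 100
    min_component_genes: int = 5
    k_clusters: int = 6
    alpha: float = 0.001
    fdr: float = 0.25
    min_enriched_foreground: int = 5

    def __post_init__(self) -> None:
        for name in ("expression", "design", "network"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", f"missing {name} file: {p}")
        for name in ("gene_sets", "annotation", "hierarchy", "truth"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"missing {name} file: {p}")
        self.delta_grid = tuple(float(d) for d in self.delta_grid)
        self.search_config = ModuleSearchConfig(
            delta_grid=self.delta_grid,
            max_iterations=self.max_iterations,
            min_component_genes=self.min_component_genes,
            seed_fraction=self.seed_fraction,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise PipelineError("config", f"{path} is not a YAML mapping")
        if isinstance(raw.get("delta_grid"), str):
            raw["delta_grid"] = parse_delta_grid(raw["delta_grid"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> str:
        d = {k: v for k, v in asdict(self).items()}
        return yaml.safe_dump(d, sort_keys=True)


def _stage(name: str):
    """Decorator-free helper: wrap exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("edmsnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    echoed = yaml.safe_load(config.echo())
    echoed.pop("out_dir", None)  # outputs must not depend on their own location
    summary: dict = {"config": echoed}
    log.info("run configuration:\n%s", config.echo())

    try:
        with _stage("read_inputs"):
            expr, design = network_io.read_expression(config.expression, config.design)
            net = network_io.read_network(config.network)
            net = network_io.restrict_network(net, expr)
            gene_sets = (
                network_io.read_gene_sets(config.gene_sets) if config.gene_sets else {}
            )
            annotation = (
                network_io.read_gene_sets(config.annotation) if config.annotation else {}
            )
            hierarchy = (
                enrichment.read_hierarchy(config.hierarchy) if config.hierarchy else None
            )
            summary["n_genes"] = len(expr.genes)
            summary["n_samples"] = len(expr.samples)
            summary["stages"] = list(design.stages)
            summary["network_nodes"] = net.n_nodes
            summary["network_edges"] = net.n_edges

        with _stage("profiles"):
            profiles = stage_correlation.edge_profiles(expr, design, net)
            stage_correlation.write_profile_table(profiles, design, out / "edge_profiles.tsv")

        subnets: list[Subnetwork] = []
        summaries = []
        with _stage("transition_search"):
            for k in range(design.n_transitions):
                label = design.transition_label(k)
                ranked = seed_analysis.rank_dcps(profiles, k)
                seeds = seed_analysis.top_fraction(
                    ranked, config.seed_fraction, kind="DCP", transition=k
                )
                dc_map = {e: float(p.dC[k]) for e, p in profiles.items()}
                best_delta, report = edms_core.scan_delta(
                    net, dc_map, seeds.members, config.search_config
                )
                cfg = ModuleSearchConfig(
                    delta=best_delta,
                    delta_grid=config.delta_grid,
                    max_iterations=config.max_iterations,
                    min_component_genes=config.min_component_genes,
                    seed_fraction=config.seed_fraction,
                )
                sub = edms_core.edms(net, dc_map, seeds.members, cfg, transition=k)
                for e in sub.edges:
                    p = profiles[e]
                    sub.edge_attributes[e] = {
                        **{f"r_{s}": float(p.r[i]) for i, s in enumerate(design.stages)},
                        **{
                            f"dC_{design.transition_label(i)}": float(p.dC[i])
                            for i in range(design.n_transitions)
                        },
                    }
                network_io.write_subnetwork(sub, out / f"subnetwork_{label}")
                with open(out / f"delta_scan_{label}.tsv", "w") as fh:
                    fh.write("delta\tscore\tn_edges\tn_nodes\tn_components\n")
                    for row in report:
                        score = "" if row["score"] is None else f"{row['score']:.6g}"
                        fh.write(
                            f"{row['delta']}\t{score}\t{row['n_edges']}"
                            f"\t{row['n_nodes']}\t{row['n_components']}\n"
                        )
                subnets.append(sub)
                summaries.append(
                    transition_analysis.summarize_subnetwork(
                        sub, design, gene_sets, set(net.nodes)
                    )
                )
                log.info(
                    "transition %s: delta=%.2f, %d nodes, %d edges",
                    label, best_delta, len(sub.nodes), len(sub.edges),
                )
            transition_analysis.write_summary_table(summaries, out / "transition_summary.tsv")
            summary["transitions"] = [
                {
                    "label": s.transition_label,
                    "n_nodes": s.n_nodes,
                    "n_edges": s.n_edges,
                    "hubs": s.hubs,
                }
                for s in summaries
            ]

        with _stage("recurrence"):
            if len(subnets) >= 2:
                rec = transition_analysis.recurrent_edges(subnets)
                summary["n_recurrent_edges"] = len(rec)
                if rec:
                    labels = transition_analysis.stage_pattern_labels(
                        set(rec), profiles, design, fdr=config.fdr
                    )
                    with open(out / "recurrent_edges.tsv", "w") as fh:
                        fh.write("node_a\tnode_b\ttransitions\tpattern\n")
                        for e in sorted(rec):
                            ts = ",".join(
                                design.transition_label(t) for t in sorted(rec[e])
                            )
                            fh.write(
                                f"{e[0]}\t{e[1]}\t{ts}\t"
                                f"{transition_analysis.pattern_string(labels[e])}\n"
                            )

        with _stage("clustering"):
            union_net, dc_vectors = processwise_modules.union_subnetworks(subnets, profiles)
            k = min(config.k_clusters, len(dc_vectors))
            assignment = processwise_modules.cluster_edges(dc_vectors, k)
            processwise_modules.write_cluster_assignment(
                assignment, out / "cluster_assignment.tsv"
            )
            comp_stats = processwise_modules.cluster_components(assignment)
            trajectories = processwise_modules.cluster_trajectory(assignment, profiles)
            processwise_modules.write_trajectories(
                trajectories, list(design.stages), out / "cluster_trajectories.tsv"
            )
            interfacing = processwise_modules.interfacing_proteins(assignment)
            ranking = processwise_modules.betweenness_ranking(union_net)
            with open(out / "processwise_summary.tsv", "w") as fh:
                fh.write("cluster\tn_nodes\tn_edges\tn_components_ge5\tlargest_component\n")
                for st in comp_stats:
                    fh.write(
                        f"{st.cluster}\t{st.n_nodes}\t{st.n_edges}"
                        f"\t{st.n_components_min_size}\t{st.largest_component}\n"
                    )
            with open(out / "interfacing_proteins.tsv", "w") as fh:
                fh.write("node\tclusters\tall_clusters\n")
                for node, cs in interfacing.items():
                    all_flag = "yes" if len(cs) == assignment.k else "no"
                    fh.write(f"{node}\t{','.join(map(str, sorted(cs)))}\t{all_flag}\n")
            with open(out / "betweenness.tsv", "w") as fh:
                fh.write("node\tbetweenness\n")
                for node, b in ranking:
                    fh.write(f"{node}\t{b:.6g}\n")
            union_sub = Subnetwork(
                set(dc_vectors),
                {e: float(v[0]) for e, v in dc_vectors.items()},
                edge_attributes={
                    e: {
                        "cluster": assignment.assignment[e],
                        **{
                            f"dC_{design.transition_label(i)}": float(v)
                            for i, v in enumerate(dc_vectors[e])
                        },
                    }
                    for e in dc_vectors
                },
            )
            network_io.write_subnetwork(union_sub, out / "union_subnetwork")
            summary["union_edges"] = union_net.n_edges
            summary["union_nodes"] = union_net.n_nodes
            summary["k_clusters"] = assignment.k
            summary["n_interfacing"] = len(interfacing)
            summary["top_betweenness"] = [n for n, _ in ranking[:3]]

        with _stage("enrichment"):
            if annotation:
                universe = set(net.nodes)
                rows = []
                for c in assignment.clusters:
                    fg = {
                        g for e in assignment.edges_of(c) for g in e
                    } & universe
                    res = enrichment.term_enrichment(fg, annotation, universe)
                    kept = enrichment.adjust_and_filter(
                        res,
                        min_foreground=config.min_enriched_foreground,
                        alpha=config.alpha,
                        annotation_graph=hierarchy,
                    )
                    for r in kept:
                        rows.append((c, r))
                with open(out / "cluster_enrichment.tsv", "w") as fh:
                    fh.write("cluster\tterm\tname\texpected\tobserved\tp\tp_adj\n")
                    for c, r in rows:
                        fh.write(
                            f"{c}\t{r.term}\t{r.name}\t{r.expected:.4g}"
                            f"\t{r.observed}\t{r.p:.4g}\t{r.p_adj:.4g}\n"
                        )
                summary["n_enriched_terms"] = len(rows)

        with _stage("recovery"):
            if config.truth:
                truth = synthetic_data.PlantedTruth.from_json(config.truth)
                union_edges = set(dc_vectors)
                metrics = synthetic_data.recovery_metrics(
                    truth,
                    found_edges=union_edges,
                    found_partition=assignment.assignment,
                )
                summary["recovery"] = metrics

        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
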