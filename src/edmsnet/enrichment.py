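"""Term enrichment with hypergeometric tests, BH adjustment, and the
minimum-foreground / leaf-term reporting rules."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term: str
    name: str
    expected: float
    observed: int
    p: float
    p_adj: float | None = None


def term_enrichment(
    foreground: set[str],
    annotation: Mapping[str, set[str]],
    universe: set[str],
    names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p per term, foreground drawn from universe.

    expected = |foreground| * |term genes in universe| / |universe|.
    Terms with no genes in the universe are skipped with a warning.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    names = names or {}
    results: list[EnrichmentResult] = []
    M, N = len(universe), len(foreground)
    for term in sorted(annotation):
        genes_u = annotation[term] & universe
        if not genes_u:
            log.warning("term %s has no genes in the universe; skipped", term)
            continue
        K = len(genes_u)
        observed = len(foreground & genes_u)
        p = float(stats.hypergeom.sf(observed - 1, M, K, N))
        results.append(
            EnrichmentResult(
                term=term,
                name=names.get(term, term),
                expected=N * K / M,
                observed=observed,
                p=p,
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def _retained_descendant(
    term: str, retained: set[str], children: Mapping[str, set[str]]
) -> bool:
    stack = list(children.get(term, ()))
    seen: set[str] = set()
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        if t in retained:
            return True
        stack.extend(children.get(t, ()))
    return False


def adjust_and_filter(
    results: list[EnrichmentResult],
    min_foreground: int = 5,
    alpha: float = 0.001,
    annotation_graph: Mapping[str, set[str]] | None = None,
) -> list[EnrichmentResult]:
    """Apply the reporting rules, in order:

    1. drop terms with observed < min_foreground (before adjustment, so
       the BH family size m reflects the survivors);
    2. BH-adjust the survivors' raw p-values;
    3. drop adjusted p > alpha;
    4. if a parent -> children hierarchy is given, keep only the most
       specific terms (no retained descendant).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    survivors = [r for r in results if r.observed >= min_foreground]
    if not survivors:
        return []
    pvals = [r.p for r in survivors]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    adjusted = []
    for r, pa in zip(survivors, p_adj):
        adjusted.append(
            EnrichmentResult(r.term, r.name, r.expected, r.observed, r.p, float(pa))
        )
    retained = [r for r in adjusted if r.p_adj <= alpha]
    if annotation_graph:
        keep_ids = {r.term for r in retained}
        retained = [
            r for r in retained
            if not _retained_descendant(r.term, keep_ids - {r.term}, annotation_graph)
        ]
    retained.sort(key=lambda r: (r.p_adj, r.term))
    return retained


def read_hierarchy(path) -> dict[str, set[str]]:
    """Parent -> children map from a two-column (parent, child) TSV."""
    children: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: hierarchy row needs 2 columns")
            if lineno == 1 and fields[0].lower() == "parent":
                continue
            children.setdefault(fields[0], set()).add(fields[1])
    return children


def write_enrichment_table(results: list[EnrichmentResult], path) -> None:
    """TSV: term, name, expected, observed, raw p, adjusted p."""
    with open(path, "w") as fh:
        fh.write("term\tname\texpected\tobserved\tp\tp_adj\n")
        for r in results:
            pa = f"{r.p_adj:.4g}" if r.p_adj is not None else ""
            fh.write(
                f"{r.term}\t{r.name}\t{r.expected:.4g}\t{r.observed}\t{r.p:.4g}\t{pa}\n"
            )
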