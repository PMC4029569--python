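"""Per-stage edge correlations, the Fisher z transform, and dC vectors.

For every network edge, a Pearson correlation r_k is computed over the
samples of each of the K stages; r_k is mapped to R_k = atanh(r_k) (a soft
threshold that emphasizes large |r|), and the differential-correlation
vector dC(k) = R_{k+1} - R_k over the K - 1 consecutive-stage transitions
quantifies co-expression change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network_io import Edge, ExpressionMatrix, Network, StageDesign, canonical_edge

#: default clamp for |r| -> 1, where atanh diverges
CLAMP_EPS = 1e-7


def fisher_transform(r, clamp_eps: float = CLAMP_EPS):
    """0.5 * ln((1 + r) / (1 - r)), with |r| clamped to 1 - clamp_eps.

    Accepts scalars or arrays; |r| > 1 is an error.  Odd and strictly
    increasing on (-1, 1).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlation magnitude exceeds 1")
    clamped = np.clip(arr, -1 + clamp_eps, 1 - clamp_eps)
    out = np.arctanh(clamped)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


@dataclass
class EdgeProfile:
    """Stage-wise correlation profile of one network edge.

    ``r`` has length K, ``R`` its Fisher transform, ``dC`` length K - 1 with
    dC[k] = R[k+1] - R[k].  ``zero_variance[k]`` flags stages where an
    endpoint gene had zero variance (r defined as 0 there).
    """

    edge: Edge
    r: np.ndarray
    R: np.ndarray
    dC: np.ndarray
    zero_variance: np.ndarray

    def __post_init__(self) -> None:
        if len(self.dC) != len(self.r) - 1:
            raise ValueError("dC length must be K - 1")


def _stage_correlations(
    expr: ExpressionMatrix,
    samples: list[str],
    ia: np.ndarray,
    ib: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r for index pairs (ia, ib) over the given samples.

    Returns (r, zero_variance_flag); r is 0 where either gene is constant.
    """
    X = expr.values[:, expr.sample_columns(samples)]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    Xn = Xc / safe[:, None]
    r = np.einsum("ij,ij->i", Xn[ia], Xn[ib])
    flag = zero[ia] | zero[ib]
    r = np.where(flag, 0.0, np.clip(r, -1.0, 1.0))
    return r, flag


def edge_profiles(
    expr: ExpressionMatrix,
    design: StageDesign,
    net: Network,
    clamp_eps: float = CLAMP_EPS,
) -> dict[Edge, EdgeProfile]:
    """Compute an :class:`EdgeProfile` for every edge of ``net``.

    The network must already be restricted to the expression genes.
    """
    edges = sorted(net.edges)
    missing = {g for e in edges for g in e} - set(expr.genes)
    if missing:
        raise ValueError(f"network genes absent from expression matrix: {sorted(missing)[:5]}")
    ia = np.array([expr.gene_index(a) for a, _ in edges], dtype=int)
    ib = np.array([expr.gene_index(b) for _, b in edges], dtype=int)

    r_stages = np.empty((len(edges), design.K))
    flags = np.zeros((len(edges), design.K), dtype=bool)
    for k, stage in enumerate(design.stages):
        r_stages[:, k], flags[:, k] = _stage_correlations(
            expr, design.samples_of(stage), ia, ib
        )
    R = fisher_transform(r_stages, clamp_eps=clamp_eps)
    dC = np.diff(R, axis=1)
    return {
        e: EdgeProfile(e, r_stages[i], R[i], dC[i], flags[i])
        for i, e in enumerate(edges)
    }


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r from n samples (t on n - 2 df)."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    if abs(r) > 1:
        raise ValueError("correlation magnitude exceeds 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def ks_background_test(
    edge_abs_r: np.ndarray,
    background_abs_r: np.ndarray,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Two-sample KS test that edge |r| values exceed the background.

    ``alternative="greater"`` (default) is one-sided: edge values
    stochastically larger than background.  ``"two-sided"`` is available
    for symmetric comparisons.
    """
    edge_abs_r = np.asarray(edge_abs_r, float)
    background_abs_r = np.asarray(background_abs_r, float)
    if edge_abs_r.size == 0 or background_abs_r.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative == "greater":
        # data1 stochastically larger <=> CDF of data1 lies below background's
        res = stats.ks_2samp(edge_abs_r, background_abs_r, alternative="less")
    elif alternative == "two-sided":
        res = stats.ks_2samp(edge_abs_r, background_abs_r, alternative="two-sided")
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(res.statistic), float(res.pvalue)


def sample_background_abs_r(
    expr: ExpressionMatrix,
    samples: list[str],
    net: Network,
    size: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """|r| for ``size`` random non-edge gene pairs over the given samples.

    All-pairs background is quadratic in gene count; a seeded random sample
    of non-interacting pairs stands in for it.
    """
    rng = rng or np.random.default_rng()
    genes = np.array(expr.genes)
    n_genes = len(genes)
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    ia_list: list[np.ndarray] = []
    ib_list: list[np.ndarray] = []
    need = size
    while need > 0:
        cand_a = rng.integers(0, n_genes, size=need * 2)
        cand_b = rng.integers(0, n_genes, size=need * 2)
        ok = cand_a != cand_b
        cand_a, cand_b = cand_a[ok], cand_b[ok]
        keep = np.fromiter(
            (not net.has_edge(genes[x], genes[y]) for x, y in zip(cand_a, cand_b)),
            dtype=bool,
            count=len(cand_a),
        )
        cand_a, cand_b = cand_a[keep][:need], cand_b[keep][:need]
        ia_list.append(cand_a)
        ib_list.append(cand_b)
        need -= len(cand_a)
    ia = np.concatenate(ia_list)
    ib = np.concatenate(ib_list)
    r, _ = _stage_correlations(expr, samples, ia, ib)
    return np.abs(r)


def cross_dataset_dc_correlation(
    profiles_a: dict[Edge, EdgeProfile],
    profiles_b: dict[Edge, EdgeProfile],
    edges: set[Edge] | list[Edge],
    transition: int,
) -> tuple[float, float]:
    """Pearson correlation of dC values for one transition across two datasets.

    Only edges profiled in both datasets contribute; fewer than 3 shared
    edges is an error.
    """
    shared = sorted(
        canonical_edge(*e) for e in edges
        if canonical_edge(*e) in profiles_a and canonical_edge(*e) in profiles_b
    )
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared edges; need >= 3")
    x = np.array([profiles_a[e].dC[transition] for e in shared])
    y = np.array([profiles_b[e].dC[transition] for e in shared])
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def write_profile_table(profiles: dict[Edge, EdgeProfile], design: StageDesign, path) -> None:
    """TSV with edge, r_1..r_K, dC_1..dC_{K-1}."""
    with open(path, "w") as fh:
        r_cols = [f"r_{s}" for s in design.stages]
        dc_cols = [f"dC_{design.transition_label(k)}" for k in range(design.n_transitions)]
        fh.write("\t".join(["node_a", "node_b", *r_cols, *dc_cols]) + "\n")
        for e in sorted(profiles):
            p = profiles[e]
            vals = [f"{v:.6g}" for v in (*p.r, *p.dC)]
            fh.write("\t".join([e[0], e[1], *vals]) + "\n")
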