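"""Shared fixtures: tiny on-disk datasets and synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from edmsnet import network_io, synthetic_data
from edmsnet.network_io import ExpressionMatrix, Network, StageDesign


@pytest.fixture
def tiny_expression_files(tmp_path):
    """4 genes x 6 samples TSV with a 2-stage design (3 samples each)."""
    expr_path = tmp_path / "expr.tsv"
    rows = [
        "gene\ts1\ts2\ts3\ts4\ts5\ts6",
        "gA\t1.0\t2.0\t3.0\t4.0\t5.0\t6.0",
        "gB\t2.0\t4.0\t6.0\t1.0\t1.5\t2.0",
        "gC\t0.5\t0.1\t0.9\t0.2\t0.8\t0.3",
        "gD\t3.0\t3.0\t3.0\t3.0\t3.0\t3.0",
    ]
    expr_path.write_text("\n".join(rows) + "\n")
    design_path = tmp_path / "design.tsv"
    design_path.write_text(
        "sample\tstage\n"
        "s1\tearly\ns2\tearly\ns3\tearly\n"
        "s4\tlate\ns5\tlate\ns6\tlate\n"
    )
    return expr_path, design_path


@pytest.fixture
def tiny_network() -> Network:
    return Network({("gA", "gB"), ("gB", "gC"), ("gA", "gC"), ("gC", "gD")})


def make_expression(
    genes: list[str], stage_sizes: list[int], stages: list[str], values: np.ndarray
) -> tuple[ExpressionMatrix, StageDesign]:
    """Build an in-memory matrix + design from an explicit value array."""
    samples = []
    assignment = {}
    i = 0
    for stage, n in zip(stages, stage_sizes):
        for _ in range(n):
            i += 1
            s = f"s{i:03d}"
            samples.append(s)
            assignment[s] = stage
    return ExpressionMatrix(genes, samples, values), StageDesign(list(stages), assignment)


@pytest.fixture
def planted_bundle():
    """A moderately sized synthetic dataset with two planted groups.

    50 samples per stage so that sample correlations sit close to their
    targets; group trajectories are active at different transitions.
    """
    seed = 11
    rng = np.random.default_rng(seed)
    net = synthetic_data.generate_network(300, model="scale-free", seed=seed)
    design = synthetic_data.make_design((50,) * 5)
    truth = synthetic_data.plant_groups(
        net,
        [
            synthetic_data.GroupSpec("early", [0.0, 0.9, 0.9, 0.0, 0.0]),
            synthetic_data.GroupSpec("late", [0.0, 0.0, 0.9, 0.9, 0.0]),
        ],
        rng,
    )
    expr = synthetic_data.generate_expression(net, design, truth, seed=seed + 1)
    return net, design, truth, expr


@pytest.fixture
def simulated_dir(tmp_path):
    """A full simulate() bundle written to disk."""
    out = tmp_path / "sim"
    paths = synthetic_data.simulate(out, seed=5)
    return out, paths
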