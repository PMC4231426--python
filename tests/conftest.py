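"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from pgtr.dataset import ExpressionDataset
from pgtr.examples import demo_graph
from pgtr.perturbation import PerturbationGraph
from pgtr.simulate import SyntheticConfig, generate_topology, simulate_knockouts


@pytest.fixture
def demo_pg() -> PerturbationGraph:
    return demo_graph()


@pytest.fixture(scope="session")
def small_benchmark():
    """A 20-gene synthetic network with a low-noise knockout compendium."""
    cfg = SyntheticConfig(n=20, K=1.5, noise_label="LL", seed=11)
    net = generate_topology(cfg)
    ds = simulate_knockouts(net, cfg)
    return net, ds


@pytest.fixture
def random_dataset():
    rng = np.random.default_rng(5)
    n = 8
    wt = rng.uniform(0.5, 2.0, n)
    ko = rng.uniform(0.2, 2.5, (n, n))
    return ExpressionDataset([f"G{k + 1}" for k in range(n)], wt, ko)


def random_pg(
    rng: np.random.Generator,
    n: int,
    p: float = 0.3,
    signed: bool = True,
) -> PerturbationGraph:
    """Random signed weighted digraph for property tests."""
    edges: dict[tuple[int, int], int] = {}
    weights: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                edges[(i, j)] = int(rng.choice([1, -1])) if signed else 0
                weights[(i, j)] = float(rng.uniform(0.05, 0.95))
    gene_ids = [f"G{k + 1}" for k in range(n)]
    return PerturbationGraph.from_edges(gene_ids, edges, weights)


def enumerate_qualifying_paths(
    pg: PerturbationGraph,
    source: int,
    target: int,
    required_sign: int | None,
    max_len: int | None,
    weight_bound: float | None,
    excluded_edge: tuple[int, int],
    removed: set | None = None,
) -> list[list[int]]:
    """Exhaustive simple-path oracle built on networkx enumeration."""
    g = nx.DiGraph()
    g.add_nodes_from(range(pg.n))
    for e, s in pg.edges.items():
        if e == excluded_edge or (removed and e in removed):
            continue
        g.add_edge(*e)
    cutoff = max_len if max_len is not None else pg.n - 1
    hits = []
    for nodes in nx.all_simple_paths(g, source, target, cutoff=cutoff):
        pairs = list(zip(nodes[:-1], nodes[1:]))
        sign = 1
        ok = True
        for e in pairs:
            s = pg.edges[e]
            sign *= -1 if s < 0 else 1
            if weight_bound is not None and not (pg.Wt[e] < weight_bound):
                ok = False
                break
        if not ok:
            continue
        if required_sign is not None and sign != required_sign:
            continue
        hits.append(nodes)
    return hits


def curve_areas_bruteforce(is_gold: list[bool]) -> tuple[float, float]:
    """Pure-python PR and ROC areas: one curve point per rank, trapezoids,
    PR anchored at (0, precision at rank 1), ROC anchored at (0, 0)."""
    g = sum(is_gold)
    m = len(is_gold)
    tp = fp = 0
    pr_pts, roc_pts = [], [(0.0, 0.0)]
    for flag in is_gold:
        if flag:
            tp += 1
        else:
            fp += 1
        pr_pts.append((tp / g, tp / (tp + fp)))
        roc_pts.append((fp / (m - g) if m > g else 0.0, tp / g))
    pr_pts = [(0.0, pr_pts[0][1])] + pr_pts
    area_pr = sum(
        (r1 - r0) * (p0 + p1) / 2.0
        for (r0, p0), (r1, p1) in zip(pr_pts[:-1], pr_pts[1:])
    )
    area_roc = sum(
        (x1 - x0) * (y0 + y1) / 2.0
        for (x0, y0), (x1, y1) in zip(roc_pts[:-1], roc_pts[1:])
    )
    return area_pr, area_roc
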