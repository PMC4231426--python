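"""Synthetic gold-standard networks and simulated knockout compendia.

Topologies mimic transcriptional networks: heavy-tailed out-degrees (a few
master regulators), light exponential-tailed in-degrees, and a modular
block structure.  Steady-state expression is produced by a multiplicative
Hill-regulation model normalized so that an unregulated gene sits at its
basal level; a knockout clamps the gene to zero.  Two noise sources mirror
the benchmark design: gene-specific biological variability of synthesis and
degradation rates (sigma_theta, drawn once per network realization) and
multiplicative log-normal measurement noise (sigma_nu, drawn per
measurement).  The nine-point noise grid crosses three levels of each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from pgtr.dataset import ExpressionDataset
from pgtr.perturbation import PerturbationGraph

#: noise grid: label -> (sigma_theta, sigma_nu); first letter = biological
#: variance level, second = measurement-noise level
NOISE_GRID: dict[str, tuple[float, float]] = {
    "LL": (0.025, 0.025),
    "LM": (0.025, 0.050),
    "LH": (0.025, 0.100),
    "ML": (0.050, 0.025),
    "MM": (0.050, 0.050),
    "MH": (0.050, 0.100),
    "HL": (0.100, 0.025),
    "HM": (0.100, 0.050),
    "HH": (0.100, 0.100),
}

OUT_DEGREE_EXPONENT = 2.5
INTRA_MODULE_PROB = 0.7
THETA_FLOOR = 0.1
DAMPING = 0.5
FP_TOL = 1e-9
FP_MAX_ITER = 500


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n: int
    K: float = 1.5
    sigma_theta: float = 0.025
    sigma_nu: float = 0.025
    noise_label: str | None = None
    activation_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two genes")
        if self.noise_label is not None:
            if self.noise_label not in NOISE_GRID:
                raise ValueError(f"unknown noise label {self.noise_label!r}")
            st, sn = NOISE_GRID[self.noise_label]
            self.sigma_theta, self.sigma_nu = st, sn
        if self.sigma_theta < 0 or self.sigma_nu < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.activation_fraction <= 1:
            raise ValueError("activation_fraction must lie in [0, 1]")

    def rng_streams(self):
        """(topology, kinetics, noise) random generators, independent
        substreams of the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


@dataclass
class TrueNetwork:
    """Gold-standard signed digraph plus its kinetic parameters."""

    gene_ids: list[str]
    edges: dict[tuple[int, int], int]  # (i, j) -> +1 (activation) / -1
    theta_syn: np.ndarray
    theta_deg: np.ndarray
    strength: dict[tuple[int, int], float] = field(default_factory=dict)
    hill: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j) in self.edges:
            if i == j:
                raise ValueError("true networks have no self-loops")
            self.strength.setdefault((i, j), 1.0)
            self.hill.setdefault((i, j), 1.0)
        if (self.theta_syn <= 0).any() or (self.theta_deg <= 0).any():
            raise ValueError("rate multipliers must be positive")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def gold_edges(self) -> set[tuple[str, str]]:
        g = self.gene_ids
        return {(g[i], g[j]) for (i, j) in self.edges}


def _allocate_out_degrees(
    rng, n: int, m_target: int, mean_degree: float
) -> np.ndarray:
    """Out-degree sequence summing to m_target: stubs allocated over nodes
    with discrete power-law propensities, capped at n // 10 (with a small-n
    floor so tiny test networks remain feasible)."""
    cap = min(n - 1, max(n // 10, math.ceil(3 * max(mean_degree, 1.0))))
    prop = np.minimum(rng.zipf(OUT_DEGREE_EXPONENT, size=n), cap).astype(float)
    d = rng.multinomial(m_target, prop / prop.sum())
    for _ in range(1000):
        excess = np.maximum(d - cap, 0)
        rem = int(excess.sum())
        d = np.minimum(d, cap)
        if rem == 0:
            return d
        free = cap - d
        if free.sum() < rem:
            break
        w = prop * (free > 0)
        d = d + rng.multinomial(rem, w / w.sum())
    raise ValueError("infeasible out-degree sequence after 1000 rounds")


def generate_topology(cfg: SyntheticConfig) -> TrueNetwork:
    """Directed, signed scale-free-ish topology at target mean degree K.

    Out-degree stubs follow a capped discrete power law (exponent 2.5),
    targets are drawn with geometric in-degree propensities biased so that
    roughly 70% of edges stay within one of ceil(sqrt(n)/2) modules;
    self-loops and duplicate edges are rejected.  Edge signs are activating
    with probability ``activation_fraction``.  Kinetic rate multipliers
    theta are drawn once per gene from N(1, sigma_theta), floored at 0.1.
    """
    rng_topo, rng_kin, _ = cfg.rng_streams()
    n = cfg.n
    gene_ids = [f"G{k + 1}" for k in range(n)]
    m_target = int(round(n * cfg.K))

    edges: dict[tuple[int, int], int] = {}
    if m_target > 0:
        d = _allocate_out_degrees(rng_topo, n, m_target, cfg.K)
        q = rng_topo.geometric(0.4, size=n).astype(float)
        n_mod = max(1, math.ceil(math.sqrt(n) / 2))
        modules = rng_topo.integers(0, n_mod, size=n)
        mod_weight = np.bincount(modules, weights=q, minlength=n_mod)
        total_w = q.sum()
        boost = np.ones(n_mod)
        if n_mod > 1:
            for mmod in range(n_mod):
                w_in = mod_weight[mmod]
                if w_in > 0 and total_w > w_in:
                    boost[mmod] = (
                        INTRA_MODULE_PROB
                        / (1 - INTRA_MODULE_PROB)
                        * (total_w - w_in)
                        / w_in
                    )
        pair_list: list[tuple[int, int]] = []
        for i in np.flatnonzero(d):
            weights = q.copy()
            weights[modules == modules[i]] *= boost[modules[i]]
            weights[i] = 0.0
            cum = np.cumsum(weights)
            chosen: set[int] = set()
            rounds = 0
            while len(chosen) < d[i]:
                if rounds >= 1000:
                    raise ValueError(
                        "infeasible degree sequence after 1000 rejection rounds"
                    )
                k = d[i] - len(chosen)
                draws = np.searchsorted(cum, rng_topo.random(k) * cum[-1])
                chosen.update(int(t) for t in draws if t != i)
                rounds += 1
            pair_list.extend((int(i), t) for t in sorted(chosen))
        signs = rng_topo.random(len(pair_list)) < cfg.activation_fraction
        edges = {
            e: (1 if s else -1) for e, s in zip(pair_list, signs)
        }
        realized_K = len(edges) / n
        if abs(realized_K - cfg.K) > 0.1 * cfg.K:
            raise RuntimeError(
                f"realized mean degree {realized_K:.3f} deviates more than "
                f"10% from target {cfg.K}"
            )

    theta_syn = np.maximum(THETA_FLOOR, rng_kin.normal(1.0, cfg.sigma_theta, n))
    theta_deg = np.maximum(THETA_FLOOR, rng_kin.normal(1.0, cfg.sigma_theta, n))
    return TrueNetwork(gene_ids, edges, theta_syn, theta_deg)


def _steady_state(
    b: np.ndarray,
    src: np.ndarray,
    dst: np.ndarray,
    sgn: np.ndarray,
    a: np.ndarray,
    m: np.ndarray,
    clamp: int | None,
    label: str,
) -> np.ndarray:
    n = b.shape[0]
    x = b.copy()
    if clamp is not None:
        x[clamp] = 0.0
    for _ in range(FP_MAX_ITER):
        if len(src):
            xm = x[src] ** m
            H = xm / (xm + 1.0)
            up = 1.0 + a * H
            base = 1.0 + a / 2.0
            fac = np.where(sgn > 0, up / base, base / up)
            reg = np.exp(np.bincount(dst, weights=np.log(fac), minlength=n))
        else:
            reg = 1.0
        xn = b * reg
        if clamp is not None:
            xn[clamp] = 0.0
        x_next = (1.0 - DAMPING) * x + DAMPING * xn
        delta = np.max(np.abs(x_next - x))
        x = x_next
        if delta < FP_TOL:
            return x
    raise RuntimeError(f"steady state did not converge ({label})")


def simulate_knockouts(
    net: TrueNetwork, cfg: SyntheticConfig
) -> ExpressionDataset:
    """Steady-state expression of the wild type and every single knockout.

    Gene j relaxes to ``x_j = b_j * prod_i r(x_i)`` over its regulators i,
    with ``b_j = theta_syn_j / theta_deg_j`` and Hill-type regulation
    ``r = (1 + a*H) / (1 + a/2)`` for activators (inverse for inhibitors),
    ``H = x^m / (x^m + 1)``; solved by damped fixed-point iteration.
    Knockout of gene i clamps ``x_i = 0`` throughout.  Every reported value
    is finally multiplied by ``exp(nu)``, ``nu ~ N(0, sigma_nu)``.
    """
    _, _, rng_noise = cfg.rng_streams()
    n = net.n
    b = net.theta_syn / net.theta_deg
    ordered = sorted(net.edges)
    src = np.array([e[0] for e in ordered], dtype=int)
    dst = np.array([e[1] for e in ordered], dtype=int)
    sgn = np.array([net.edges[e] for e in ordered], dtype=int)
    a = np.array([net.strength[e] for e in ordered], dtype=float)
    m = np.array([net.hill[e] for e in ordered], dtype=float)

    wt = _steady_state(b, src, dst, sgn, a, m, None, "wild type")
    ko = np.empty((n, n))
    for i in range(n):
        ko[i] = _steady_state(
            b, src, dst, sgn, a, m, i, f"knockout of {net.gene_ids[i]}"
        )
    wt_meas = wt * np.exp(rng_noise.normal(0.0, cfg.sigma_nu, size=n))
    ko_meas = ko * np.exp(rng_noise.normal(0.0, cfg.sigma_nu, size=(n, n)))
    return ExpressionDataset(net.gene_ids, wt_meas, ko_meas)


# ---------------------------------------------------------------------------
# closure oracle
# ---------------------------------------------------------------------------


def transitive_closure(
    edges: dict[tuple[int, int], int], n: int
) -> dict[tuple[int, int], tuple[int, ...]]:
    """Signed transitive closure of an acyclic signed digraph.

    Returns ``{(i, j): signs}`` where ``signs`` lists every overall sign
    (+1/-1) realized by some path i => j.  The idealized noise-free
    perturbation graph of a true network is exactly this closure.  Cyclic
    input is refused.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("signed closure is only defined for acyclic input")
    pos = np.zeros((n, n), dtype=bool)
    neg = np.zeros((n, n), dtype=bool)
    for i in reversed(list(nx.topological_sort(g))):
        for k in g.successors(i):
            if edges[(i, k)] > 0:
                pos[i] |= pos[k]
                neg[i] |= neg[k]
                pos[i, k] = True
            else:
                pos[i] |= neg[k]
                neg[i] |= pos[k]
                neg[i, k] = True
    out: dict[tuple[int, int], tuple[int, ...]] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            signs = ()
            if pos[i, j]:
                signs += (1,)
            if neg[i, j]:
                signs += (-1,)
            if signs:
                out[(i, j)] = signs
    return out


def closure_perturbation_graph(
    edges: dict[tuple[int, int], int],
    n: int,
    gene_ids: list[str] | None = None,
    true_weight: float = 0.2,
    induced_weight: float = 0.8,
) -> PerturbationGraph:
    """Idealized PG of a true acyclic network: its signed transitive closure
    with true edges strictly more confident (lower TR weight) than induced
    ones.  Raises if any induced pair admits paths of both signs."""
    closure = transitive_closure(edges, n)
    gene_ids = gene_ids or [f"G{k + 1}" for k in range(n)]
    pg_edges: dict[tuple[int, int], int] = {}
    weights: dict[tuple[int, int], float] = {}
    for pair, signs in closure.items():
        if pair in edges:
            pg_edges[pair] = edges[pair]
            weights[pair] = true_weight
        else:
            if len(signs) != 1:
                raise ValueError(
                    f"pair {pair} has sign-ambiguous paths; the closure PG "
                    "is only defined for sign-unambiguous networks"
                )
            pg_edges[pair] = signs[0]
            weights[pair] = induced_weight
    wr = np.zeros((n, n))
    for pair, w in weights.items():
        wr[pair] = 1.0 - w
    np.fill_diagonal(wr, np.nan)
    return PerturbationGraph.from_edges(
        gene_ids, pg_edges, weights, wr, method_tag="closure"
    )


def random_signed_dag(
    n: int, mean_degree: float, rng: np.random.Generator
) -> dict[tuple[int, int], int]:
    """Random minimal signed DAG with path-sign coherence.

    Edges are drawn uniformly above a random topological order at the
    requested density and the DAG is transitively reduced, so no edge is
    parallel to an alternative path.  Signs derive from node potentials
    (s_ij = sigma_i * sigma_j), which makes every path between two nodes
    carry the same overall sign -- the regime in which a perfect PG (the
    signed closure) determines the true graph uniquely.
    """
    perm = rng.permutation(n)
    p = min(1.0, 2.0 * mean_degree / (n - 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(int(perm[i]), int(perm[j]))
    g = nx.transitive_reduction(g)
    sigma = rng.choice([1, -1], size=n)
    return {
        (u, v): int(sigma[u] * sigma[v]) for u, v in g.edges
    }


# ---------------------------------------------------------------------------
# benchmark suite
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSuite:
    """Factorial benchmark design: topologies x noise configurations.

    ``entries`` is the manifest (one row per dataset); datasets are
    materialized lazily via :meth:`realize`, so enumerating the full design
    costs nothing.
    """

    entries: list[dict]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def realize(self, entry: dict) -> tuple[TrueNetwork, ExpressionDataset]:
        cfg = SyntheticConfig(
            n=entry["n"],
            K=entry["K"],
            noise_label=entry["noise_label"],
            seed=entry["seed"],
        )
        net = generate_topology(cfg)
        return net, simulate_knockouts(net, cfg)


def make_benchmark_suite(
    n: int,
    K_list: tuple[float, ...] = (1.5, 2.0, 2.5),
    noise_labels: tuple[str, ...] = tuple(NOISE_GRID),
    replicates: int = 10,
    seed: int = 0,
) -> BenchmarkSuite:
    """Full factorial grid: ``replicates`` topologies per connectivity K,
    each simulated under every noise configuration (the published design is
    10 replicates x 3 connectivities x 9 noise points = 270 datasets).

    All noise configurations of one topology share a seed, so they differ
    only in the noise scales applied -- the grid varies noise, not wiring.
    """
    ss = np.random.SeedSequence(seed)
    n_topo = len(K_list) * replicates
    topo_seeds = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(max(n_topo, 1))
    ]
    entries: list[dict] = []
    t = 0
    for K in K_list:
        for rep in range(replicates):
            topo_seed = topo_seeds[t]
            for label in noise_labels:
                st, sn = NOISE_GRID[label]
                entries.append(
                    {
                        "dataset_id": f"n{n}_K{K}_rep{rep + 1}_{label}",
                        "n": n,
                        "K": K,
                        "replicate": rep + 1,
                        "noise_label": label,
                        "sigma_theta": st,
                        "sigma_nu": sn,
                        "seed": topo_seed,
                    }
                )
            t += 1
    return BenchmarkSuite(entries)
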