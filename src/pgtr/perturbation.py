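"""Perturbation-graph generation from knockout expression data.

Three PG flavours are implemented, differing in how candidate edges are
selected and weighted:

* ``pg1`` — z-score thresholding only; unsigned edges.
* ``pg2`` — z-score plus a minimal absolute deviation ``gamma``; signed by
  the direction of the expression change; TR weight ``1 - |c_ij|`` from
  conditional correlations.
* ``pgnew`` — z-score, conditional-correlation magnitude, and a
  sign-consistency filter (z-score and correlation must have opposite
  signs); TR weight ``1 - Zc`` where ``Zc`` is the per-target z-score of
  the absolute conditional correlations, shifted positive.

The z-score of a candidate edge i -> j is

    z_ij = (ko[i, j] - mu_j) / sigma_j

with ``mu_j``/``sigma_j`` taken over *all* measurements of gene j: its n
knockout measurements (including the self-knockout) plus the wild type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from pgtr.dataset import ExpressionDataset

EPS_ZC = 1e-6


class DegenerateDataWarning(UserWarning):
    """Raised when a gene or gene pair carries no variance (uninformative)."""


@dataclass
class ZScoreBundle:
    """Z-score matrix with the column statistics it was derived from."""

    Z: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    beta: float | None = None
    degenerate_columns: list[int] = field(default_factory=list)


@dataclass
class CorrelationBundle:
    """Conditional correlations and (optionally) their column z-scores.

    ``C[i, j]`` is the Pearson correlation of genes i and j over the
    wild-type row and the knockout rows retained by the exclusion rule
    (diagonal is NaN).  ``Zc`` standardizes ``|C|`` per target column and is
    shifted by a single global ``offset`` so its smallest off-diagonal entry
    equals ``EPS_ZC`` exactly.
    """

    C: np.ndarray
    Zc: np.ndarray | None = None
    offset: float | None = None
    gamma: float | None = None
    exclusion_rule: str = "drop_j"
    degenerate_pairs: list[tuple[int, int]] = field(default_factory=list)
    degenerate_columns: list[int] = field(default_factory=list)


@dataclass
class PerturbationGraph:
    """Signed directed candidate-edge graph with two weight matrices.

    ``edges`` maps ordered index pairs (i, j), i != j, to a sign in
    {+1, -1, 0} (0 = unsigned).  ``Wt`` holds the TR weight of each edge
    (``inf`` where no edge is present); lower weight = higher confidence.
    ``Wr`` holds ranking weights in [0, 1] for *all* ordered pairs
    (NaN diagonal); higher = more confident.
    """

    gene_ids: list[str]
    edges: dict[tuple[int, int], int]
    Wt: np.ndarray
    Wr: np.ndarray
    method_tag: str = "pg"

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed in a PG")
            if not np.isfinite(self.Wt[i, j]):
                raise ValueError(f"edge ({i}, {j}) lacks a finite TR weight")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self.edges

    def sign_of(self, i: int, j: int) -> int:
        return self.edges[(i, j)]

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges sorted lexicographically by (source id, target id)."""
        g = self.gene_ids
        return sorted(self.edges, key=lambda e: (g[e[0]], g[e[1]]))

    def adjacency(self, removed: set[tuple[int, int]] | None = None):
        """Out-adjacency ``{i: [(j, sign, weight), ...]}`` with neighbour
        lists sorted by target gene id (deterministic traversal order)."""
        adj: dict[int, list[tuple[int, int, float]]] = {
            i: [] for i in range(self.n)
        }
        for (i, j) in self.edge_list():
            if removed and (i, j) in removed:
                continue
            adj[i].append((j, self.edges[(i, j)], float(self.Wt[i, j])))
        return adj

    def without(self, removed: set[tuple[int, int]]) -> "PerturbationGraph":
        """Copy of the graph with ``removed`` edges deleted."""
        edges = {e: s for e, s in self.edges.items() if e not in removed}
        Wt = self.Wt.copy()
        for (i, j) in removed:
            Wt[i, j] = np.inf
        return PerturbationGraph(
            gene_ids=list(self.gene_ids),
            edges=edges,
            Wt=Wt,
            Wr=self.Wr,
            method_tag=self.method_tag,
        )

    @classmethod
    def from_edges(
        cls,
        gene_ids: list[str],
        edges: dict[tuple[int, int], int],
        weights: dict[tuple[int, int], float],
        wr: np.ndarray | None = None,
        method_tag: str = "pg",
    ) -> "PerturbationGraph":
        n = len(gene_ids)
        Wt = np.full((n, n), np.inf)
        for e, w in weights.items():
            Wt[e] = w
        if wr is None:
            wr = np.zeros((n, n))
            for e, w in weights.items():
                wr[e] = 1.0 - w
            np.fill_diagonal(wr, np.nan)
        return cls(gene_ids, dict(edges), Wt, wr, method_tag)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def zscore_matrix(
    wt: np.ndarray, ko: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Z-scores of an m-by-n knockout matrix against per-gene statistics.

    Column statistics pool the m knockout measurements of each gene with its
    wild-type value (m + 1 values).  Columns with zero standard deviation
    yield all-zero z-scores and are reported as degenerate.
    """
    wt = np.asarray(wt, float).reshape(-1)
    ko = np.asarray(ko, float)
    stacked = np.vstack([wt[np.newaxis, :], ko])
    mu = stacked.mean(axis=0)
    sigma = stacked.std(axis=0, ddof=ddof)
    degenerate = [int(j) for j in np.flatnonzero(sigma == 0)]
    safe = np.where(sigma > 0, sigma, 1.0)
    Z = (ko - mu[np.newaxis, :]) / safe[np.newaxis, :]
    if degenerate:
        Z[:, degenerate] = 0.0
        warnings.warn(
            f"zero-variance expression for gene column(s) {degenerate}; "
            "z-scores set to 0",
            DegenerateDataWarning,
            stacklevel=2,
        )
    return Z, mu, sigma, degenerate


def compute_zscores(
    dataset: ExpressionDataset, ddof: int = 1, beta: float | None = None
) -> ZScoreBundle:
    """Z-score matrix for every ordered gene pair (diagonal = self-effect)."""
    Z, mu, sigma, degenerate = zscore_matrix(dataset.wt, dataset.ko, ddof=ddof)
    return ZScoreBundle(Z=Z, mu=mu, sigma=sigma, beta=beta,
                        degenerate_columns=degenerate)


def _pearson(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of vector ``x`` against every column of ``Y`` (zero-variance
    columns give NaN, handled by the caller)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    num = xc @ Yc
    den = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


def conditional_correlation_matrix(
    wt: np.ndarray,
    ko: np.ndarray,
    row_of: np.ndarray | None = None,
    exclusion_rule: str = "drop_j",
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Conditional Pearson correlations ``c_ij`` over retained experiments.

    ``row_of[j]`` gives the knockout-row index of gene j (or -1 if gene j was
    never perturbed; relevant for partially perturbed designs).  Under the
    default ``drop_j`` rule, ``c_ij`` is computed over the wild type and all
    knockout rows except the one in which j itself was knocked out; the
    ``drop_i_and_j`` rule additionally discards the row perturbing i.
    """
    wt = np.asarray(wt, float).reshape(-1)
    ko = np.asarray(ko, float)
    m, n = ko.shape
    if row_of is None:
        if m != n:
            raise ValueError("row_of is required for non-square knockout data")
        row_of = np.arange(n)
    row_of = np.asarray(row_of, int)
    X = np.vstack([wt[np.newaxis, :], ko])  # (m+1, n); row r+1 = knockout r
    C = np.full((n, n), np.nan)
    degenerate: list[tuple[int, int]] = []

    if exclusion_rule == "drop_j":
        for j in range(n):
            keep = np.ones(m + 1, bool)
            if row_of[j] >= 0:
                keep[row_of[j] + 1] = False
            if keep.sum() < 3:
                raise ValueError(
                    "fewer than 3 experiments retained for correlation"
                )
            sub = X[keep]
            C[:, j] = _pearson(sub[:, j], sub)
    elif exclusion_rule == "drop_i_and_j":
        for j in range(n):
            for i in range(n):
                if i == j:
                    continue
                keep = np.ones(m + 1, bool)
                if row_of[j] >= 0:
                    keep[row_of[j] + 1] = False
                if row_of[i] >= 0:
                    keep[row_of[i] + 1] = False
                if keep.sum() < 3:
                    raise ValueError(
                        "fewer than 3 experiments retained for correlation"
                    )
                sub = X[keep]
                C[i, j] = _pearson(sub[:, j], sub[:, [i]])[0]
    else:
        raise ValueError(f"unknown exclusion rule {exclusion_rule!r}")

    np.fill_diagonal(C, np.nan)
    offdiag = ~np.eye(n, dtype=bool)
    bad = offdiag & ~np.isfinite(C)
    if bad.any():
        degenerate = [tuple(map(int, e)) for e in np.argwhere(bad)]
        C[bad] = 0.0
        warnings.warn(
            f"{len(degenerate)} gene pair(s) with zero variance over retained "
            "experiments; correlations set to 0",
            DegenerateDataWarning,
            stacklevel=2,
        )
    return C, degenerate


def compute_conditional_correlation(
    dataset: ExpressionDataset,
    exclusion_rule: str = "drop_j",
    gamma: float | None = None,
) -> CorrelationBundle:
    C, degenerate = conditional_correlation_matrix(
        dataset.wt, dataset.ko, exclusion_rule=exclusion_rule
    )
    return CorrelationBundle(
        C=C, gamma=gamma, exclusion_rule=exclusion_rule,
        degenerate_pairs=degenerate,
    )


def compute_zc(cb: CorrelationBundle, eps: float = EPS_ZC) -> CorrelationBundle:
    """Per-target-column z-scores of |C|, shifted globally positive.

    Each column j of ``|C|`` (off-diagonal entries only) is standardized by
    its own mean and sample standard deviation; a single global offset then
    makes the minimum off-diagonal entry equal ``eps`` exactly.
    """
    C = cb.C
    n = C.shape[0]
    A = np.abs(C)
    offdiag = ~np.eye(n, dtype=bool)
    Zc = np.full((n, n), np.nan)
    degenerate_cols: list[int] = []
    for j in range(n):
        col = A[offdiag[:, j], j]
        mean = col.mean()
        sd = col.std(ddof=1) if col.size > 1 else 0.0
        if sd == 0:
            Zc[offdiag[:, j], j] = 0.0
            degenerate_cols.append(j)
        else:
            Zc[offdiag[:, j], j] = (A[offdiag[:, j], j] - mean) / sd
    if degenerate_cols:
        warnings.warn(
            f"constant |correlation| column(s) {degenerate_cols}; "
            "standardized to 0 before shift",
            DegenerateDataWarning,
            stacklevel=2,
        )
    lo = np.nanmin(Zc[offdiag])
    offset = eps - lo
    # subtract-then-add keeps the minimum at exactly eps
    Zc[offdiag] = (Zc[offdiag] - lo) + eps
    cb.Zc = Zc
    cb.offset = float(offset)
    cb.degenerate_columns = degenerate_cols
    return cb


def minmax_offdiag(M: np.ndarray) -> np.ndarray:
    """Global min-max normalization of the off-diagonal entries to [0, 1]
    (NaN diagonal; a constant matrix maps to all zeros)."""
    n = M.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    vals = M[offdiag]
    lo, hi = vals.min(), vals.max()
    out = np.full((n, n), np.nan)
    if hi > lo:
        out[offdiag] = (M[offdiag] - lo) / (hi - lo)
    else:
        out[offdiag] = 0.0
    return out


# ---------------------------------------------------------------------------
# PG builders
# ---------------------------------------------------------------------------


def _edge_dict(mask: np.ndarray, signs: np.ndarray | None) -> dict:
    edges: dict[tuple[int, int], int] = {}
    for i, j in np.argwhere(mask):
        edges[(int(i), int(j))] = int(signs[i, j]) if signs is not None else 0
    return edges


def build_pg1(
    zb: ZScoreBundle, beta: float, gene_ids: list[str] | None = None
) -> PerturbationGraph:
    """Unsigned z-score PG: edge i -> j iff |z_ij| > beta (strict).

    TR weights are ``1 - minmax(|Z|)`` on present edges; ranking weights are
    ``minmax(|Z|)`` for all ordered pairs.
    """
    Z = zb.Z
    n = Z.shape[0]
    gene_ids = gene_ids or [f"G{k + 1}" for k in range(n)]
    absZ = np.abs(Z)
    offdiag = ~np.eye(n, dtype=bool)
    mask = (absZ > beta) & offdiag
    Wr = minmax_offdiag(absZ)
    Wt = np.full((n, n), np.inf)
    Wt[mask] = 1.0 - Wr[mask]
    return PerturbationGraph(gene_ids, _edge_dict(mask, None), Wt, Wr, "pg1")


def build_pg2(
    dataset: ExpressionDataset,
    zb: ZScoreBundle,
    cb: CorrelationBundle,
    beta: float,
    gamma: float,
) -> PerturbationGraph:
    """Signed two-threshold PG: edge i -> j iff |z_ij| > beta and
    |wt_j - ko_ij| > gamma; sign = sign(wt_j - ko_ij); TR weight
    ``1 - |c_ij|``."""
    Z, C = zb.Z, cb.C
    n = Z.shape[0]
    D = dataset.wt[np.newaxis, :] - dataset.ko
    offdiag = ~np.eye(n, dtype=bool)
    mask = (np.abs(Z) > beta) & (np.abs(D) > gamma) & offdiag
    signs = np.sign(D).astype(int)
    Wr = minmax_offdiag(np.abs(Z))
    Wt = np.full((n, n), np.inf)
    Wt[mask] = 1.0 - np.abs(C[mask])
    return PerturbationGraph(
        dataset.gene_ids, _edge_dict(mask, signs), Wt, Wr, "pg2"
    )


def build_pg_new(
    zb: ZScoreBundle,
    cb: CorrelationBundle,
    beta: float,
    gamma: float,
    gene_ids: list[str] | None = None,
) -> PerturbationGraph:
    """Sign-consistent correlation/z-score PG.

    Candidate set ``B = S1 & S2 & S3`` with S1: |Z| > beta, S2: |C| > gamma,
    S3: C*Z < 0 (knockout of an activator lowers the target, so a direct
    effect should pair a negative z-score with a positive correlation and
    vice versa).  Edges with z < 0 are activations (+), edges with z > 0
    repressions (-).  TR weight is ``1 - Zc``; ranking weight is
    ``minmax(|Z| + Zc)``.
    """
    if cb.Zc is None:
        raise ValueError("compute_zc must be called before build_pg_new")
    Z, C, Zc = zb.Z, cb.C, cb.Zc
    n = Z.shape[0]
    gene_ids = gene_ids or [f"G{k + 1}" for k in range(n)]
    offdiag = ~np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        mask = (
            (np.abs(Z) > beta)
            & (np.abs(C) > gamma)
            & (C * Z < 0)
            & offdiag
        )
    signs = np.where(Z < 0, 1, -1)
    Wr = minmax_offdiag(np.abs(Z) + Zc)
    Wt = np.full((n, n), np.inf)
    Wt[mask] = 1.0 - Zc[mask]
    return PerturbationGraph(gene_ids, _edge_dict(mask, signs), Wt, Wr, "pgnew")
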