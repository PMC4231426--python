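"""Transitive-reduction variants for signed, weighted perturbation graphs.

Three families are provided:

* ``transwesd`` — an edge is potentially removable if an alternative simple
  path of the same sign exists whose bottleneck (maximum) edge weight stays
  strictly below ``alpha * w_ij``.  Removal proceeds highest-weight-first;
  with ``full_check`` every edge of the original graph must stay explainable
  (present, or reachable through a still-qualifying path) after each
  deletion, otherwise the deletion is undone.
* ``ltr`` — local TR: only 2-paths (feed-forward loops) may explain an
  edge, with the multiplicative confidence rule
  ``alpha * Zc_ij <= Zc_ik * Zc_kj`` on ``Zc = 1 - Wt`` (here a *large*
  value means high confidence).  Removal proceeds lowest-confidence-first
  with the same re-checking discipline; always exact.
* ``drffl`` — the legacy rule: edges crossing strongly connected components
  with any unsigned, unweighted alternative path are removed simultaneously,
  candidates judged on the original graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pgtr.paths import (
    EdgeArrays,
    PathQuery,
    approx_path_exists,
    find_explaining_path,
    strongly_connected_components,
)
from pgtr.perturbation import PerturbationGraph

Edge = tuple[int, int]


@dataclass
class TRConfig:
    """Configuration of a transitive-reduction run.

    ``L`` is the maximal explaining-path length (None = unbounded; forced to
    2 for ``ltr``).  ``alpha`` is the confidence factor of the weight rule
    (strict bottleneck bound for transwesd, multiplicative non-strict rule
    for ltr; ``weighted=False`` drops the weight rule entirely, equivalent
    to ``alpha = inf`` for transwesd and ``alpha = 0`` for ltr).
    ``path_exact=False`` switches transwesd to the approximate walk-based
    search; ``full_check=False`` freezes removability decisions on the
    original graph.
    """

    method: str = "transwesd"
    signed: bool = True
    weighted: bool = True
    L: int | None = None
    alpha: float = 0.95
    path_exact: bool = True
    full_check: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("transwesd", "ltr", "drffl"):
            raise ValueError(f"unknown TR method {self.method!r}")
        if self.method == "ltr":
            self.L = 2
            self.path_exact = True
            self.full_check = True
        if self.alpha < 0:
            raise ValueError("alpha must be positive")


@dataclass
class ReductionResult:
    """Reduced graph plus a full audit trail of the removal process."""

    GT: PerturbationGraph
    R: set[Edge]
    removal_log: list[tuple[Edge, int]]
    kept_explainable: list[Edge] = field(default_factory=list)

    @property
    def removed(self) -> set[Edge]:
        return {e for e, _ in self.removal_log}


def _edge_query(pg: PerturbationGraph, e: Edge, cfg: TRConfig) -> PathQuery:
    i, j = e
    s = pg.edges[e]
    req = s if (cfg.signed and s != 0) else None
    bound = cfg.alpha * float(pg.Wt[i, j]) if cfg.weighted else None
    return PathQuery(
        source=i, target=j, required_sign=req, max_len=cfg.L,
        weight_bound=bound, excluded_edge=e,
    )


def identify_removable_transwesd(
    pg: PerturbationGraph, cfg: TRConfig
) -> set[Edge]:
    """Set R of edges with a qualifying explaining path in the full graph."""
    R: set[Edge] = set()
    arrays = None if cfg.path_exact else EdgeArrays(pg)
    for e in pg.edge_list():
        q = _edge_query(pg, e, cfg)
        if cfg.path_exact:
            found = find_explaining_path(pg, q, exact=True) is not None
        else:
            found = approx_path_exists(pg, q, arrays=arrays)
        if found:
            R.add(e)
    return R


def _witness_edges(nodes: list[int]) -> set[Edge]:
    return set(zip(nodes[:-1], nodes[1:]))


def reduce_transwesd(pg: PerturbationGraph, cfg: TRConfig) -> ReductionResult:
    """Iterative highest-weight-first removal with explainability re-checks.

    With ``full_check`` a cached explaining witness is kept for every edge
    removed so far; deleting a further edge re-derives exactly the witnesses
    it invalidates, and the deletion is rolled back if any removed edge (or
    the candidate itself) loses all qualifying paths.  Without
    ``full_check`` all decisions are frozen on the original graph and the
    whole set R is removed.
    """
    gid = pg.gene_ids
    R = identify_removable_transwesd(pg, cfg)
    order = sorted(R, key=lambda e: (-pg.Wt[e], gid[e[0]], gid[e[1]]))

    removal_log: list[tuple[Edge, int]] = []
    kept_explainable: list[Edge] = []
    removed: set[Edge] = set()

    if not cfg.full_check:
        for it, e in enumerate(order):
            removed.add(e)
            removal_log.append((e, it))
        return ReductionResult(pg.without(removed), R, removal_log, [])

    witnesses: dict[Edge, list[int]] = {}
    for it, e in enumerate(order):
        removed.add(e)
        wit = find_explaining_path(
            pg, _edge_query(pg, e, cfg), exact=cfg.path_exact, removed=removed
        )
        if wit is None:
            removed.discard(e)  # no longer explainable: keep silently
            continue
        affected = [
            r for r, nodes in witnesses.items() if e in _witness_edges(nodes)
        ]
        new_wits = {e: wit.node_sequence}
        ok = True
        for r in affected:
            rw = find_explaining_path(
                pg, _edge_query(pg, r, cfg), exact=cfg.path_exact,
                removed=removed,
            )
            if rw is None:
                ok = False
                break
            new_wits[r] = rw.node_sequence
        if ok:
            witnesses.update(new_wits)
            removal_log.append((e, it))
        else:
            removed.discard(e)
            kept_explainable.append(e)
    return ReductionResult(pg.without(removed), R, removal_log, kept_explainable)


# ---------------------------------------------------------------------------
# local TR
# ---------------------------------------------------------------------------


def _sgn(s: int) -> int:
    return -1 if s < 0 else 1


def _ltr_middles(
    pg: PerturbationGraph,
    e: Edge,
    cfg: TRConfig,
    Zc: np.ndarray,
    removed: set[Edge],
) -> list[int]:
    """Middle nodes whose 2-path satisfies the sign and weight rules,
    sorted by gene id."""
    i, j = e
    ks = []
    for k in range(pg.n):
        if k == i or k == j:
            continue
        if (i, k) in removed or (k, j) in removed:
            continue
        if not (pg.has_edge(i, k) and pg.has_edge(k, j)):
            continue
        if cfg.signed:
            s_ij = pg.edges[e]
            if s_ij != 0 and _sgn(s_ij) != _sgn(pg.edges[(i, k)]) * _sgn(
                pg.edges[(k, j)]
            ):
                continue
        if cfg.weighted and cfg.alpha > 0:
            if not (cfg.alpha * Zc[i, j] <= Zc[i, k] * Zc[k, j]):
                continue
        ks.append(k)
    ks.sort(key=lambda k: pg.gene_ids[k])
    return ks


def ltr_supported(
    removed: set[Edge], middles: dict[Edge, list[int]]
) -> set[Edge]:
    """Least fixpoint of well-founded 2-path support.

    A removed edge (i, j) is *supported* if some qualifying feed-forward
    middle k exists whose legs (i, k) and (k, j) are each still present or
    themselves supported removed edges.  Grounding is well-founded (least
    fixpoint), so circular justifications do not count: the net effect of
    every supported edge factors into a chain of present edges.
    """
    supported: set[Edge] = set()
    pending = set(removed)
    changed = True
    while changed:
        changed = False
        for r in sorted(pending):
            i, j = r
            for k in middles.get(r, ()):
                leg1, leg2 = (i, k), (k, j)
                if (leg1 not in removed or leg1 in supported) and (
                    leg2 not in removed or leg2 in supported
                ):
                    supported.add(r)
                    pending.discard(r)
                    changed = True
                    break
    return supported


def reduce_ltr(pg: PerturbationGraph, cfg: TRConfig) -> ReductionResult:
    """Local TR: 2-path explanations only, lowest-confidence-first removal.

    Confidence of an edge is ``Zc_ij = 1 - Wt_ij`` (large = confident), so
    candidates are deleted in ascending ``Zc`` order.  A deletion is kept
    only if afterwards *every* removed edge is still explained by a
    qualifying 2-path whose legs are present or themselves explained
    (see :func:`ltr_supported`); explanations may therefore chain through
    previously pruned indirect edges, which is what lets 2-path reduction
    recover graphs whose indirect effects stem from long paths.
    """
    if cfg.method != "ltr":
        cfg = replace(cfg, method="ltr")
    gid = pg.gene_ids
    Zc = 1.0 - pg.Wt

    # sign/weight conditions depend only on the original graph, so the
    # qualifying middle nodes of every candidate can be computed once
    middles: dict[Edge, list[int]] = {}
    for e in pg.edge_list():
        ks = _ltr_middles(pg, e, cfg, Zc, set())
        if ks:
            middles[e] = ks
    R = set(middles)

    order = sorted(R, key=lambda e: (Zc[e], gid[e[0]], gid[e[1]]))
    removed: set[Edge] = set()
    removal_log: list[tuple[Edge, int]] = []
    kept_explainable: list[Edge] = []

    for it, e in enumerate(order):
        trial = removed | {e}
        supported = ltr_supported(trial, middles)
        if trial <= supported:
            removed = trial
            removal_log.append((e, it))
        elif e in supported:
            kept_explainable.append(e)  # removable, but would strand others
    return ReductionResult(pg.without(removed), R, removal_log, kept_explainable)


def reduce_drffl(
    pg: PerturbationGraph, cfg: TRConfig | None = None
) -> ReductionResult:
    """Cross-component reduction: every edge joining two different strongly
    connected components with an unsigned, unweighted alternative path in
    the *original* graph is removed, all at once."""
    labels = strongly_connected_components(pg)
    adj: dict[int, list[int]] = {i: [] for i in range(pg.n)}
    for (i, j) in pg.edges:
        adj[i].append(j)
    removed: set[Edge] = set()
    for e in pg.edge_list():
        i, j = e
        if labels[i] == labels[j]:
            continue
        # BFS reachability i => j avoiding the edge itself
        seen = {i}
        stack = [i]
        found = False
        while stack and not found:
            u = stack.pop()
            for v in adj[u]:
                if (u, v) == e:
                    continue
                if v == j:
                    found = True
                    break
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if found:
            removed.add(e)
    log = [(e, 0) for e in sorted(removed, key=lambda e: (pg.gene_ids[e[0]],
                                                          pg.gene_ids[e[1]]))]
    return ReductionResult(pg.without(removed), set(removed), log, [])


def reduce(pg: PerturbationGraph, cfg: TRConfig) -> ReductionResult:
    """Dispatch to the configured TR variant."""
    if cfg.method == "transwesd":
        return reduce_transwesd(pg, cfg)
    if cfg.method == "ltr":
        return reduce_ltr(pg, cfg)
    if cfg.method == "drffl":
        return reduce_drffl(pg, cfg)
    raise ValueError(f"unknown TR method {cfg.method!r}")


def verify_explainability(
    pg: PerturbationGraph, result: ReductionResult, cfg: TRConfig
) -> bool:
    """True iff every edge of the original graph is either retained or
    explainable under the method's re-check semantics (qualifying path in
    the remaining graph for transwesd; well-founded 2-path support for
    ltr)."""
    removed = result.removed
    if cfg.method == "ltr":
        Zc = 1.0 - pg.Wt
        middles = {}
        for e in pg.edge_list():
            ks = _ltr_middles(pg, e, cfg, Zc, set())
            if ks:
                middles[e] = ks
        return removed <= ltr_supported(removed, middles)
    for e in pg.edge_list():
        if e not in removed:
            continue
        q = _edge_query(pg, e, cfg)
        if find_explaining_path(pg, q, exact=True, removed=removed) is None:
            return False
    return True
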