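"""Confidence ranking of gene pairs and scoring against a gold standard.

The ranked list always covers *all* n(n-1) ordered pairs: edges surviving
transitive reduction first (a tier offset guarantees this), then -- in the
three-tier scheme -- edges that were in the perturbation graph but removed,
then everything else; within a tier pairs sort by ranking weight.

AUPR integrates the precision-recall curve trapezoidally while sweeping the
ranking one pair at a time; AUROC equals the Mann-Whitney statistic of gold
versus non-gold rank positions (the ranking is a strict total order, so no
tie correction is needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pgtr.perturbation import PerturbationGraph
from pgtr.reduction import ReductionResult

TIER_OFFSET = 2.0  # per-tier shift on [0, 1] ranking weights; only order matters


@dataclass
class GoldStandard:
    """Directed reference edge set over an explicit node universe."""

    edges: set[tuple[str, str]]
    nodes: set[str] = field(default_factory=set)
    signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = {(str(a), str(b)) for a, b in self.edges}
        for a, b in self.edges:
            if a == b:
                raise ValueError("gold standard may not contain self-loops")
        if not self.nodes:
            self.nodes = {v for e in self.edges for v in e}
        else:
            self.nodes = set(map(str, self.nodes))


@dataclass
class RankedEdgeList:
    """All ordered gene pairs, best first.

    ``df`` has columns source, target, score, tier with tier in
    {"GT", "removed_from_PG", "other"}; scores are non-increasing.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.df["source"], self.df["target"]))

    def top(self, k: int) -> "RankedEdgeList":
        return RankedEdgeList(self.df.head(k).reset_index(drop=True))


@dataclass
class EvalReport:
    aupr: float
    auroc: float
    edges: int
    tp: int
    fp: int
    fn: int
    tp_at_k: int
    k: int

    def summary(self) -> dict:
        return {
            "AUPR": round(self.aupr, 4),
            "AUROC": round(self.auroc, 4),
            "edges": self.edges,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            f"TP@{self.k}": self.tp_at_k,
        }


def rank_edges(
    pg: PerturbationGraph,
    reduction: ReductionResult | None = None,
    scheme: str = "two_tier",
) -> RankedEdgeList:
    """Tiered confidence ordering of all ordered gene pairs.

    ``two_tier`` puts edges of the final graph above everything else;
    ``three_tier`` additionally ranks PG edges removed during TR above pairs
    that never made it into the PG.  Ties in score break lexicographically
    on (source id, target id), so the output is a pure function of the
    inputs.
    """
    if scheme not in ("two_tier", "three_tier"):
        raise ValueError(f"unknown ranking scheme {scheme!r}")
    n = pg.n
    gid = pg.gene_ids
    gt_edges = set(reduction.GT.edges) if reduction is not None else set(pg.edges)
    removed = reduction.removed if reduction is not None else set()

    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            wr = float(pg.Wr[i, j])
            if (i, j) in gt_edges:
                tier, level = "GT", 2
            elif (i, j) in removed:
                tier, level = "removed_from_PG", 1
            else:
                tier, level = "other", 0
            if scheme == "two_tier" and level == 1:
                level = 0
            rows.append((gid[i], gid[j], wr + TIER_OFFSET * level, tier))
    df = pd.DataFrame(rows, columns=["source", "target", "score", "tier"])
    df = df.sort_values(
        ["score", "source", "target"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return RankedEdgeList(df)


def confusion_counts(
    predicted: set[tuple[str, str]],
    gold: GoldStandard,
    predicted_universe: set[str] | None = None,
    restrict_to_common_nodes: bool = False,
) -> tuple[int, int, int]:
    """(TP, FP, FN) of a predicted edge set.

    With node restriction, predictions touching genes outside the gold
    universe are unscored and gold edges touching genes outside the
    prediction universe are dropped -- the discipline used when scoring
    against partially covering ("silver standard") references.
    """
    pred = {(str(a), str(b)) for a, b in predicted}
    gold_edges = set(gold.edges)
    if restrict_to_common_nodes:
        if predicted_universe is None:
            predicted_universe = {v for e in pred for v in e}
        pred = {
            (a, b) for a, b in pred if a in gold.nodes and b in gold.nodes
        }
        gold_edges = {
            (a, b)
            for a, b in gold_edges
            if a in predicted_universe and b in predicted_universe
        }
    tp = len(pred & gold_edges)
    fp = len(pred - gold_edges)
    fn = len(gold_edges - pred)
    return tp, fp, fn


def _gold_indicator(ranked: RankedEdgeList, gold: GoldStandard) -> np.ndarray:
    universe = set(ranked.df["source"]) | set(ranked.df["target"])
    usable = {
        e for e in gold.edges if e[0] in universe and e[1] in universe
    }
    if not usable:
        raise ValueError("gold standard is empty on the scored universe")
    return np.array(
        [(s, t) in usable for s, t in ranked.pairs()], dtype=bool
    )


def aupr(ranked: RankedEdgeList, gold: GoldStandard) -> float:
    """Area under the precision-recall curve of the full ranking.

    One PR point per rank; trapezoidal integration over recall with the
    curve anchored at (0, precision at rank 1).
    """
    y = _gold_indicator(ranked, gold)
    g = int(y.sum())
    m = len(y)
    tp = np.cumsum(y)
    precision = tp / np.arange(1, m + 1)
    recall = tp / g
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    return float(np.sum(np.diff(r) * (p[1:] + p[:-1]) / 2.0))


def auroc(ranked: RankedEdgeList, gold: GoldStandard) -> float:
    """Mann-Whitney AUROC: probability that a random gold pair outranks a
    random non-gold pair."""
    y = _gold_indicator(ranked, gold)
    g = int(y.sum())
    m = len(y)
    if g == m:
        raise ValueError("gold standard covers every ranked pair")
    # rank from worst (1) to best (m); list is best-first
    ranks_desc = np.arange(m, 0, -1)
    u = ranks_desc[y].sum() - g * (g + 1) / 2.0
    return float(u / (g * (m - g)))


def tp_at_k(ranked: RankedEdgeList, gold: GoldStandard, k: int = 100) -> int:
    """Number of gold edges among the k most confident pairs."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds list length {len(ranked)}")
    top = set(ranked.top(k).pairs())
    return len(top & gold.edges)


def hypergeom_pvalue(tp: int, k: int, n_gold: int, n_pairs: int) -> float:
    """Enrichment p-value of observing >= tp gold edges among k picks from
    n_pairs candidate pairs of which n_gold are gold."""
    return float(stats.hypergeom.sf(tp - 1, n_pairs, n_gold, k))


def evaluate(
    ranked: RankedEdgeList,
    predicted: set[tuple[str, str]],
    gold: GoldStandard,
    k: int = 100,
    restrict_to_common_nodes: bool = False,
) -> EvalReport:
    """Bundle AUPR/AUROC on the ranking with confusion counts at the cut
    defined by ``predicted`` (normally the reduced graph's edges)."""
    tp, fp, fn = confusion_counts(
        predicted, gold, restrict_to_common_nodes=restrict_to_common_nodes
    )
    kk = min(k, len(ranked))
    return EvalReport(
        aupr=aupr(ranked, gold),
        auroc=auroc(ranked, gold),
        edges=len(predicted),
        tp=tp,
        fp=fp,
        fn=fn,
        tp_at_k=tp_at_k(ranked, gold, kk),
        k=kk,
    )
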