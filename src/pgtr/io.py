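"""File formats, pipeline configuration, and the end-to-end driver.

Matrix files use the tab-separated dialect of the in-silico challenge data:
a header row of gene identifiers, then data rows (one for the wild-type
file, n for the knockout file whose row order equals the header order).
Gold standards are ``source<TAB>target<TAB>{0|1}`` edge lists; predictions
are ``source<TAB>target<TAB>confidence`` in descending confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pgtr.dataset import ExpressionDataset
from pgtr.perturbation import (
    CorrelationBundle,
    PerturbationGraph,
    build_pg1,
    build_pg2,
    build_pg_new,
    compute_conditional_correlation,
    compute_zc,
    compute_zscores,
    conditional_correlation_matrix,
    minmax_offdiag,
    zscore_matrix,
)
from pgtr.ranking import (
    EvalReport,
    GoldStandard,
    RankedEdgeList,
    evaluate,
    rank_edges,
)
from pgtr.reduction import ReductionResult, TRConfig, reduce

logger = logging.getLogger("pgtr")

#: benchmark parameter defaults: confidence factor by (method, locality)
DEFAULT_ALPHA = {
    ("transwesd", None): 0.95,
    ("transwesd", 2): 1.50,
    ("ltr", 2): 0.15,
}


def default_alpha(method: str, L: int | None) -> float:
    if method == "ltr":
        return DEFAULT_ALPHA[("ltr", 2)]
    return DEFAULT_ALPHA.get((method, L), 0.95)


@dataclass
class PipelineConfig:
    """Settings of a full PG -> TR -> ranking run (defaults mirror the
    benchmark settings: beta=2.0, gamma=0.05, alpha by TR method)."""

    pg_method: str = "pgnew"
    beta: float = 2.0
    gamma: float = 0.05
    tr: TRConfig | None = field(default_factory=lambda: TRConfig(method="ltr", alpha=0.15))
    rank_scheme: str = "two_tier"
    exclusion_rule: str = "drop_j"
    top_k: int = 100
    restrict_to_common_nodes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pg_method not in ("pg1", "pg2", "pgnew"):
            raise ValueError(f"unknown PG method {self.pg_method!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_matrix(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dups = sorted({g for g in header if header.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene identifier(s) {dups}")
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except Exception as exc:  # noqa: BLE001 - re-raised with file context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite expression value")
    return df


def read_expression(wildtype_path, knockout_path) -> ExpressionDataset:
    """Parse a wild-type/knockout file pair (headers must agree; knockout
    row i is the experiment deleting the i-th header gene)."""
    wt_df = _read_matrix(wildtype_path)
    ko_df = _read_matrix(knockout_path)
    if list(wt_df.columns) != list(ko_df.columns):
        raise ValueError(
            f"gene headers of {wildtype_path} and {knockout_path} differ"
        )
    genes = [str(c) for c in wt_df.columns]
    if len(wt_df) != 1:
        raise ValueError(
            f"{wildtype_path}: expected exactly 1 wild-type row, got {len(wt_df)}"
        )
    if len(ko_df) != len(genes):
        raise ValueError(
            f"{knockout_path}: expected {len(genes)} knockout rows, got {len(ko_df)}"
        )
    return ExpressionDataset(genes, wt_df.to_numpy(float)[0], ko_df.to_numpy(float))


def write_expression(dataset: ExpressionDataset, wildtype_path, knockout_path) -> None:
    pd.DataFrame([dataset.wt], columns=dataset.gene_ids).to_csv(
        wildtype_path, sep="\t", index=False
    )
    pd.DataFrame(dataset.ko, columns=dataset.gene_ids).to_csv(
        knockout_path, sep="\t", index=False
    )


def read_gold(path) -> GoldStandard:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["source", "target", "label"],
        dtype={"source": str, "target": str},
    )
    if df["label"].isna().any():
        df["label"] = df["label"].fillna(1)
    edges = {
        (r.source, r.target) for r in df.itertuples() if int(r.label) == 1
    }
    nodes = set(df["source"]) | set(df["target"])
    return GoldStandard(edges=edges, nodes=nodes)


def write_gold(gold: GoldStandard, path) -> None:
    rows = sorted(gold.edges)
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in rows:
            fh.write(f"{s}\t{t}\t1\n")


def write_predictions(ranked: RankedEdgeList, path, top: int | None = None) -> None:
    df = ranked.df if top is None else ranked.df.head(top)
    df[["source", "target", "score"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.10g"
    )


def read_predictions(path) -> RankedEdgeList:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["source", "target", "score"],
        dtype={"source": str, "target": str},
    )
    df["tier"] = "other"
    return RankedEdgeList(df)


def write_pg(pg: PerturbationGraph, prefix) -> None:
    """Serialize a PG as ``<prefix>.edges.tsv`` (source, target, sign,
    tr_weight) plus ``<prefix>.wr.tsv`` (full ranking-weight matrix)."""
    gid = pg.gene_ids
    rows = [
        (gid[i], gid[j], pg.edges[(i, j)], pg.Wt[i, j])
        for (i, j) in pg.edge_list()
    ]
    pd.DataFrame(rows, columns=["source", "target", "sign", "tr_weight"]).to_csv(
        f"{prefix}.edges.tsv", sep="\t", index=False, float_format="%.12g"
    )
    pd.DataFrame(pg.Wr, columns=gid).to_csv(
        f"{prefix}.wr.tsv", sep="\t", index=False, float_format="%.12g"
    )


def read_pg(prefix, method_tag: str = "pg") -> PerturbationGraph:
    wr_df = pd.read_csv(f"{prefix}.wr.tsv", sep="\t", header=0)
    gid = [str(c) for c in wr_df.columns]
    idx = {g: k for k, g in enumerate(gid)}
    n = len(gid)
    Wr = wr_df.to_numpy(float)
    edf = pd.read_csv(
        f"{prefix}.edges.tsv", sep="\t", header=0,
        dtype={"source": str, "target": str},
    )
    edges: dict[tuple[int, int], int] = {}
    Wt = np.full((n, n), np.inf)
    for r in edf.itertuples():
        e = (idx[r.source], idx[r.target])
        edges[e] = int(r.sign)
        Wt[e] = float(r.tr_weight)
    return PerturbationGraph(gid, edges, Wt, Wr, method_tag)


def write_edge_set(edges: list[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in edges:
            fh.write(f"{s}\t{t}\n")


def read_edge_set(path) -> list[tuple[str, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                s, t = line.split("\t")[:2]
                out.append((s, t))
    return out


def lfc_to_expression(L):
    """Invert log2-fold changes to the expression scale: G = 2**L.

    Values above 1 mean the target rose after the knockout (the deleted
    gene repressed it); values below 1 indicate activation.
    """
    arr = np.asarray(L, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("log-fold-change matrix contains non-finite entries")
    out = np.power(2.0, arr)
    if isinstance(L, pd.DataFrame):
        return pd.DataFrame(out, index=L.index, columns=L.columns)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def build_pg(dataset: ExpressionDataset, cfg: PipelineConfig) -> PerturbationGraph:
    """Construct the configured PG variant from an expression dataset."""
    zb = compute_zscores(dataset, beta=cfg.beta)
    if cfg.pg_method == "pg1":
        return build_pg1(zb, cfg.beta, gene_ids=dataset.gene_ids)
    cb = compute_conditional_correlation(
        dataset, exclusion_rule=cfg.exclusion_rule, gamma=cfg.gamma
    )
    if cfg.pg_method == "pg2":
        return build_pg2(dataset, zb, cb, cfg.beta, cfg.gamma)
    cb = compute_zc(cb)
    return build_pg_new(zb, cb, cfg.beta, cfg.gamma, gene_ids=dataset.gene_ids)


def run_pipeline(
    dataset: ExpressionDataset,
    cfg: PipelineConfig,
    gold: GoldStandard | None = None,
) -> tuple[RankedEdgeList, EvalReport | None, dict]:
    """PG generation -> transitive reduction -> ranking (-> evaluation).

    Returns the complete ranked edge list, the evaluation report when a
    gold standard is supplied, and a stage-statistics dictionary (edge
    counts before/after TR, plus the confusion summary when scored).
    """
    pg = build_pg(dataset, cfg)
    stats: dict = {"pg_method": pg.method_tag, "pg_edges": len(pg.edges)}
    logger.info("PG (%s): %d candidate edges", pg.method_tag, len(pg.edges))

    reduction: ReductionResult | None = None
    if cfg.tr is not None:
        reduction = reduce(pg, cfg.tr)
        stats["tr_method"] = cfg.tr.method
        stats["removable"] = len(reduction.R)
        stats["removed"] = len(reduction.removed)
        stats["gt_edges"] = len(reduction.GT.edges)
        logger.info(
            "TR (%s): %d removable, %d removed, %d edges kept",
            cfg.tr.method, len(reduction.R), len(reduction.removed),
            len(reduction.GT.edges),
        )
    ranked = rank_edges(pg, reduction, scheme=cfg.rank_scheme)

    report = None
    if gold is not None:
        final = reduction.GT if reduction is not None else pg
        predicted = {
            (final.gene_ids[i], final.gene_ids[j]) for (i, j) in final.edges
        }
        report = evaluate(
            ranked, predicted, gold, k=cfg.top_k,
            restrict_to_common_nodes=cfg.restrict_to_common_nodes,
        )
        stats["summary"] = report.summary()
        logger.info("evaluation: %s", report.summary())
    return ranked, report, stats


# ---------------------------------------------------------------------------
# partially perturbed designs
# ---------------------------------------------------------------------------


@dataclass
class PartialResult:
    """Output of inference on a dataset where only m of n genes were
    perturbed: full inference among the perturbed genes, plus PG-only
    candidate edges from perturbed to unperturbed genes (no TR is possible
    there -- no paths exist between unperturbed targets)."""

    sub_ranked: RankedEdgeList
    sub_report: EvalReport | None
    sub_stats: dict
    cross_edges: pd.DataFrame


def handle_partial_perturbation(
    gene_ids: list[str],
    wt: np.ndarray,
    ko: np.ndarray,
    perturbed: list[str],
    cfg: PipelineConfig,
    gold: GoldStandard | None = None,
) -> PartialResult:
    """Two-part reconstruction for an m-by-n knockout design (m < n allowed).

    ``ko`` has one row per perturbed gene (order given by ``perturbed``)
    and one column per gene in ``gene_ids``.
    """
    m = len(perturbed)
    if m < 3:
        raise ValueError("need at least 3 perturbed genes (correlations undefined)")
    wt = np.asarray(wt, float).reshape(-1)
    ko = np.asarray(ko, float)
    n = len(gene_ids)
    if ko.shape != (m, n):
        raise ValueError(f"knockout matrix has shape {ko.shape}, expected {(m, n)}")
    col = {g: k for k, g in enumerate(gene_ids)}
    missing = [g for g in perturbed if g not in col]
    if missing:
        raise ValueError(f"perturbed gene(s) {missing} not in gene_ids")
    pcols = [col[g] for g in perturbed]

    # (i) complete sub-network over the perturbed genes
    sub = ExpressionDataset(list(perturbed), wt[pcols], ko[:, pcols])
    sub_ranked, sub_report, sub_stats = run_pipeline(sub, cfg, gold=gold)

    # (ii) PG-only candidates from perturbed to unperturbed genes
    Z, _, _, _ = zscore_matrix(wt, ko)
    row_of = np.full(n, -1, dtype=int)
    for r, g in enumerate(perturbed):
        row_of[col[g]] = r
    C, _ = conditional_correlation_matrix(
        wt, ko, row_of=row_of, exclusion_rule=cfg.exclusion_rule
    )
    unperturbed = [g for g in gene_ids if g not in set(perturbed)]
    rows = []
    if unperturbed:
        # column-indexed z-score matrix restricted to perturbed sources
        Zfull = np.full((n, n), np.nan)
        for r, g in enumerate(perturbed):
            Zfull[col[g], :] = Z[r, :]
        cb = compute_zc(CorrelationBundle(C=C))
        if cfg.pg_method == "pgnew":
            score_raw = np.abs(Zfull) + cb.Zc
        else:
            score_raw = np.abs(Zfull)
        score = minmax_offdiag(np.where(np.isnan(score_raw), 0.0, score_raw))
        for g in perturbed:
            i = col[g]
            r = row_of[i]  # knockout row of the source gene
            for h in unperturbed:
                j = col[h]
                z = Zfull[i, j]
                keep = abs(z) > cfg.beta
                if cfg.pg_method == "pg2":
                    keep = keep and abs(wt[j] - ko[r, j]) > cfg.gamma
                    sign = int(np.sign(wt[j] - ko[r, j]))
                elif cfg.pg_method == "pgnew":
                    keep = keep and abs(C[i, j]) > cfg.gamma and C[i, j] * z < 0
                    sign = 1 if z < 0 else -1
                else:
                    sign = 0
                if not keep:
                    continue
                rows.append((g, h, sign, float(score[i, j])))
    cross = pd.DataFrame(rows, columns=["source", "target", "sign", "score"])
    cross = cross.sort_values(
        ["score", "source", "target"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return PartialResult(sub_ranked, sub_report, sub_stats, cross)
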