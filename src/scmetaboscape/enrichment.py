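"""Per-cell gene-set scoring and enrichment tests.

Three related rank-based tools:

* :func:`gsva_scores` — GSVA-style per-cell pathway scores: a per-gene
  (kernel-smoothed) cumulative-density statistic across cells, per-cell
  cross-gene ranking into a symmetric rank statistic, and a weighted
  Kolmogorov-Smirnov random walk per gene set.
* :func:`rank_genes_auc` + :func:`preranked_gsea` — two-group AUC ranking
  statistic per gene feeding a classical preranked GSEA running sum with a
  gene-permutation null.
* :func:`vi_wilcoxon_gene_set_test` — competitive gene-set test on per-gene
  log2 fold changes, with a variance-inflation correction for the average
  pairwise correlation between member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, DataError, ExpressionMatrix, PathwayCollection

logger = logging.getLogger(__name__)


@dataclass
class PerCellScoreMatrix:
    """Pathway x cell GSVA scores plus the parameters that produced them."""

    scores: pd.DataFrame
    method: str = "gsva"
    kernel: str = "gaussian"
    tau: float = 1.0

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores.index)


# ---------------------------------------------------------------------------
# GSVA


def _kernel_cdf(X: np.ndarray, kernel: str) -> np.ndarray:
    """Per-gene cumulative-density statistic across cells.

    gaussian: smoothed ECDF with bandwidth sd/4 per gene (the conventional
    choice); poisson: mean Poisson CDF with per-cell rates x+0.5, for raw
    counts; ecdf: plain empirical CDF (exact rank transform — invariant to
    any strictly monotone per-gene map).
    """
    n_genes, n_cells = X.shape
    Z = np.empty_like(X, dtype=float)
    if kernel == "gaussian":
        for g in range(n_genes):
            x = X[g]
            h = np.std(x) / 4.0
            if h <= 0:
                Z[g] = 0.5
                continue
            Z[g] = scipy.special.ndtr((x[:, None] - x[None, :]) / h).mean(axis=1)
    elif kernel == "poisson":
        for g in range(n_genes):
            x = X[g]
            lam = x + 0.5
            Z[g] = scipy.stats.poisson.cdf(x[:, None], lam[None, :]).mean(axis=1)
    elif kernel == "ecdf":
        for g in range(n_genes):
            Z[g] = scipy.stats.rankdata(X[g], method="average") / n_cells
    else:
        raise ConfigError(f"unknown kernel {kernel!r}; expected gaussian, poisson or ecdf")
    return Z


def _rank_statistic(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell ordering (genes sorted by decreasing statistic, ties by gene
    index) and the symmetric rank statistic in that order.

    Gene at sorted position k (0-based) carries rank value (p - k); the
    statistic is |rank value - p/2|, largest at both extremes of the list.
    """
    n_genes, n_cells = Z.shape
    # stable argsort of -Z gives decreasing Z with ties broken by gene index
    order = np.argsort(-Z, axis=0, kind="stable")
    ranks = n_genes - np.arange(n_genes)  # p, p-1, ..., 1 along sorted order
    stat_sorted = np.abs(ranks - n_genes / 2.0)
    stat_sorted = np.broadcast_to(stat_sorted[:, None], (n_genes, n_cells))
    return order, stat_sorted


def _walk_scores(
    order: np.ndarray,
    stat_sorted: np.ndarray,
    member_mask: np.ndarray,
    tau: float,
    max_diff: bool,
) -> np.ndarray:
    """Weighted KS random walk over the per-cell ranked gene list.

    Returns one score per cell: with ``max_diff`` the magnitude-difference
    statistic max(0, max v) + min(0, min v); otherwise the maximum deviation
    with its sign.
    """
    n_genes, n_cells = order.shape
    mem_sorted = member_mask[order]  # ordered per cell
    w = np.where(mem_sorted, np.abs(stat_sorted) ** tau, 0.0)
    denom_hit = w.sum(axis=0)
    denom_hit[denom_hit == 0] = np.nan
    n_out = n_genes - member_mask.sum()
    if n_out == 0:
        return np.full(n_cells, np.nan)
    hit = np.cumsum(w, axis=0) / denom_hit[None, :]
    miss = np.cumsum(~mem_sorted, axis=0) / n_out
    v = hit - miss
    if max_diff:
        return np.maximum(v.max(axis=0), 0.0) + np.minimum(v.min(axis=0), 0.0)
    idx = np.argmax(np.abs(v), axis=0)
    return v[idx, np.arange(n_cells)]


def gsva_scores(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    tau: float = 1.0,
    kernel: str = "gaussian",
    max_diff: bool = True,
    min_genes: int = 3,
) -> PerCellScoreMatrix:
    """GSVA-style enrichment score of each pathway in each cell.

    Constant gene rows are dropped (no ranking information); pathways with
    fewer than ``min_genes`` measured genes are skipped. Supply
    log-transformed expression with the gaussian kernel, raw counts with the
    poisson kernel.
    """
    if expr.n_columns < 2:
        raise DataError("gsva_scores needs >= 2 columns")
    X = expr.values
    keep = X.std(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%d constant gene row(s) dropped before GSVA", dropped)
    X = X[keep]
    gene_ids = expr.gene_ids[keep]
    if X.shape[0] < min_genes + 1:
        raise DataError("too few non-constant genes for GSVA")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    Z = _kernel_cdf(X, kernel)
    order, stat_sorted = _rank_statistic(Z)

    rows = {}
    for name in pathways.names:
        members = [g for g in pathways[name] if g in gene_pos]
        if len(members) < min_genes:
            logger.warning("pathway %s: %d measured genes < %d; skipped",
                           name, len(members), min_genes)
            continue
        mask = np.zeros(X.shape[0], dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        rows[name] = _walk_scores(order, stat_sorted, mask, tau, max_diff)
    if not rows:
        raise DataError("no pathway had enough measured genes for GSVA")
    scores = pd.DataFrame(rows, index=expr.column_ids).T
    return PerCellScoreMatrix(scores=scores, kernel=kernel, tau=tau)


# ---------------------------------------------------------------------------
# AUC ranking + preranked GSEA


@dataclass
class RankedGeneList:
    """Genes with a ranking statistic, sorted descending (ties by gene id)."""

    statistic: pd.Series  # index = gene ids, sorted descending
    kind: str = "auc"

    def __post_init__(self) -> None:
        s = self.statistic
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
        self.statistic = s.iloc[order]

    @property
    def genes(self) -> list[str]:
        return list(self.statistic.index)


def rank_genes_auc(
    expr: ExpressionMatrix, group_a: np.ndarray | pd.Series, group_b: np.ndarray | pd.Series
) -> RankedGeneList:
    """Per-gene AUC = P(a-cell value > b-cell value) + 0.5 P(tie), as the
    signed ranking statistic AUC - 0.5, sorted descending."""
    a_idx = _column_indices(expr, group_a)
    b_idx = _column_indices(expr, group_b)
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise DataError("both groups must be non-empty")
    A = expr.values[:, a_idx]
    B = expr.values[:, b_idx]
    combined = np.concatenate([A, B], axis=1)
    ranks = scipy.stats.rankdata(combined, axis=1, method="average")
    ra = ranks[:, : A.shape[1]].sum(axis=1)
    n_a, n_b = A.shape[1], B.shape[1]
    auc = (ra - n_a * (n_a + 1) / 2.0) / (n_a * n_b)
    stat = pd.Series(auc - 0.5, index=expr.gene_ids, name="auc_minus_half")
    return RankedGeneList(stat, kind="auc")


def _column_indices(expr: ExpressionMatrix, sel) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        return np.flatnonzero(sel)
    return expr.column_ids.get_indexer(pd.Index(sel))


@dataclass
class GseaResult:
    """Per gene set: ES, NES, p, q and the leading-edge gene list."""

    table: pd.DataFrame           # index = set name
    leading_edge: dict[str, list] = field(default_factory=dict)


def _running_es(stats: np.ndarray, member: np.ndarray, weight: float = 1.0):
    """Running-sum enrichment walk over a ranked statistic vector.

    Returns (ES, peak index). Hits increment proportionally to
    |statistic|^weight, misses decrement uniformly.
    """
    n = len(stats)
    m = int(member.sum())
    if m == 0 or m == n:
        return np.nan, -1
    w = np.where(member, np.abs(stats) ** weight, 0.0)
    denom = w.sum()
    if denom == 0:
        w = member.astype(float)
        denom = float(m)
    hit = np.cumsum(w) / denom
    miss = np.cumsum(~member) / (n - m)
    v = hit - miss
    peak = int(np.argmax(np.abs(v)))
    return float(v[peak]), peak


def preranked_gsea(
    ranked: RankedGeneList,
    sets: PathwayCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_genes: int = 3,
) -> GseaResult:
    """Classical preranked GSEA with a gene-label permutation null.

    Positive and negative enrichment scores are normalized separately by the
    mean magnitude of same-sign null scores; BH adjustment within sign. Sets
    covering the entire ranking (no misses) are undefined and flagged.
    """
    stats = ranked.statistic.values.astype(float)
    genes = ranked.statistic.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    n = len(genes)

    records = []
    leading: dict[str, list] = {}
    null_cache: dict[int, np.ndarray] = {}
    for name in sets.names:
        members = [g for g in sets[name] if g in gene_pos]
        m = len(members)
        if m < min_genes:
            logger.warning("set %s: %d ranked genes < %d; skipped", name, m, min_genes)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        es, peak = _running_es(stats, mask, weight)
        if not np.isfinite(es):
            logger.warning("set %s covers the whole ranking; ES undefined", name)
            records.append(
                {"set": name, "size": m, "es": np.nan, "nes": np.nan,
                 "p": np.nan, "q": np.nan}
            )
            continue
        if m not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                pmask = np.zeros(n, dtype=bool)
                pmask[rng.choice(n, size=m, replace=False)] = True
                null[i], _ = _running_es(stats, pmask, weight)
            null_cache[m] = null
        null = null_cache[m]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
            nes = es / np.mean(np.abs(same_sign))
        if es >= 0:
            le = [g for g in genes[: peak + 1] if mask[gene_pos[g]]]
        else:
            le = [g for g in genes[peak:] if mask[gene_pos[g]]]
        leading[name] = le
        records.append({"set": name, "size": m, "es": es, "nes": nes, "p": p, "q": np.nan})

    table = pd.DataFrame(records).set_index("set") if records else pd.DataFrame(
        columns=["size", "es", "nes", "p", "q"]
    )
    if len(table):
        for sign_mask in (table["es"] >= 0, table["es"] < 0):
            idx = table.index[sign_mask & table["p"].notna()]
            if len(idx):
                table.loc[idx, "q"] = multipletests(
                    table.loc[idx, "p"].values, method="fdr_bh"
                )[1]
    return GseaResult(table=table, leading_edge=leading)


# ---------------------------------------------------------------------------
# variance-inflated Wilcoxon gene-set test


def vi_wilcoxon_gene_set_test(
    log_expr: ExpressionMatrix,
    labels: str | pd.Series,
    sets: PathwayCollection,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Competitive gene-set test per cluster on per-gene log2 fold changes.

    Per cluster, each gene's statistic is its log2FC between the cluster and
    all other cells; a gene set is tested by a Wilcoxon rank-sum of its
    member genes' log2FCs against non-member genes, with the normal-theory
    variance inflated by 1 + (m-1) * rho-bar, where rho-bar is the mean
    pairwise correlation of the member genes' log expression (competitive
    tests are anti-conservative when member genes are correlated).
    Two-sided p; BH across sets within each cluster.
    """
    if isinstance(labels, str):
        labels = log_expr.annotation(labels)
    labels = pd.Series(labels, index=log_expr.column_ids)
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        raise DataError("vi_wilcoxon_gene_set_test needs >= 2 clusters")
    X = log_expr.values
    gene_pos = {g: i for i, g in enumerate(log_expr.gene_ids)}
    records = []
    for cl in clusters:
        in_cl = (labels == cl).values
        mean_in = np.expm1(X[:, in_cl]).mean(axis=1)
        mean_out = np.expm1(X[:, ~in_cl]).mean(axis=1)
        log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
        fc_ranks = scipy.stats.rankdata(log2fc)
        n = len(log2fc)
        for name in sets.names:
            members = [g for g in sets[name] if g in gene_pos]
            m = len(members)
            if m < min_genes:
                continue
            idx = [gene_pos[g] for g in members]
            r_sum = fc_ranks[idx].sum()
            mu = m * (n + 1) / 2.0
            var = m * (n - m) * (n + 1) / 12.0
            sub = X[idx][:, in_cl]
            rho = _mean_pairwise_correlation(sub)
            vif = max(1.0 + (m - 1) * rho, 1.0)
            z = (r_sum - mu) / np.sqrt(var * vif)
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            records.append(
                {"cluster": cl, "set": name, "size": m,
                 "median_log2fc": float(np.median(log2fc[idx])),
                 "statistic": float(z), "vif": float(vif), "p": float(p)}
            )
    out = pd.DataFrame(records)
    if len(out):
        out["q"] = np.nan
        for cl in clusters:
            sel = out["cluster"] == cl
            if sel.any():
                out.loc[sel, "q"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    return out


def _mean_pairwise_correlation(sub: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation of rows (0 when degenerate)."""
    if sub.shape[0] < 2 or sub.shape[1] < 3:
        return 0.0
    sd = sub.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(sub[ok])
    m = c.shape[0]
    off = (c.sum() - m) / (m * (m - 1))
    return float(np.clip(off, -0.99, 0.99))
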