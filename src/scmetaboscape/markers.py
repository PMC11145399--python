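"""Marker detection between cell groups and top-N signature extraction.

The marker test mirrors the convention of the standard single-cell marker
tools: genes pre-filtered on detection fraction (min_pct) and absolute log2
fold change, then a Wilcoxon rank-sum test on normalized log expression,
Benjamini-Hochberg adjusted per contrast. A signature is the top-N genes of
one contrast by log2FC (or p-value rank) among the significant ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene, per-contrast differential-expression table.

    Columns: contrast, gene, log2fc, auc, pct1, pct2, p, q.
    """

    table: pd.DataFrame
    parameters: dict = field(default_factory=dict)

    def contrast(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == name]
        if not len(sub):
            raise DataError(f"no contrast {name!r} in DE result")
        return sub


@dataclass
class Signature:
    name: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DataError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)


def _rank_sum_test(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum with tie-corrected normal
    approximation; returns (auc, p) per gene (rows)."""
    n_a, n_b = A.shape[1], B.shape[1]
    combined = np.concatenate([A, B], axis=1)
    ranks = scipy.stats.rankdata(combined, axis=1, method="average")
    ra = ranks[:, :n_a].sum(axis=1)
    u = ra - n_a * (n_a + 1) / 2.0
    auc = u / (n_a * n_b)
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    # tie correction per gene
    tie_term = np.zeros(combined.shape[0])
    srt = np.sort(combined, axis=1)
    for g in range(combined.shape[0]):
        _, counts = np.unique(srt[g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 1e-12)
    z = (u - mu) / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    # constant genes (all values tied): no evidence
    p[var <= 1e-10] = 1.0
    return auc, p


def _log2fc(A_log: np.ndarray, B_log: np.ndarray) -> np.ndarray:
    """log2 ratio of de-logged group means with pseudo-count 1."""
    mean_a = np.expm1(A_log).mean(axis=1)
    mean_b = np.expm1(B_log).mean(axis=1)
    return np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)


def find_markers(
    log_expr: ExpressionMatrix,
    labels: str | pd.Series = "cell_type",
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    min_cells: int = 3,
) -> DEResult:
    """One-vs-rest marker detection for every label.

    Genes enter the test only when detected in >= ``min_pct`` of either
    group and |log2FC| >= ``logfc_threshold``; Wilcoxon rank-sum p on the
    log-normalized values, BH within contrast. Groups below ``min_cells``
    are skipped with a warning.
    """
    if isinstance(labels, str):
        labels = log_expr.annotation(labels)
    labels = pd.Series(labels, index=log_expr.column_ids)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise DataError("find_markers needs >= 2 labels")
    X = log_expr.values
    records = []
    for g in groups:
        in_g = (labels == g).values
        if in_g.sum() < min_cells or (~in_g).sum() < min_cells:
            logger.warning("group %s has < %d cells on one side; contrast skipped", g, min_cells)
            continue
        A, B = X[:, in_g], X[:, ~in_g]
        pct1 = (A > 0).mean(axis=1)
        pct2 = (B > 0).mean(axis=1)
        log2fc = _log2fc(A, B)
        tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(log2fc) >= logfc_threshold)
        if not tested.any():
            continue
        auc = np.full(X.shape[0], np.nan)
        p = np.full(X.shape[0], np.nan)
        auc[tested], p[tested] = _rank_sum_test(A[tested], B[tested])
        q = np.full(X.shape[0], np.nan)
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
        idx = np.flatnonzero(tested)
        for i in idx:
            records.append(
                {
                    "contrast": g,
                    "gene": log_expr.gene_ids[i],
                    "log2fc": log2fc[i],
                    "auc": auc[i],
                    "pct1": pct1[i],
                    "pct2": pct2[i],
                    "p": p[i],
                    "q": q[i],
                }
            )
    table = pd.DataFrame(
        records,
        columns=["contrast", "gene", "log2fc", "auc", "pct1", "pct2", "p", "q"],
    )
    return DEResult(
        table,
        parameters={"min_pct": min_pct, "logfc_threshold": logfc_threshold},
    )


def top_n_signature(
    de: DEResult,
    contrast: str,
    n: int,
    direction: str = "up",
    q_max: float = 0.05,
    rank_by: str = "log2fc",
) -> Signature:
    """Top-N signature of one contrast among genes significant at q < q_max.

    ``rank_by``: "log2fc" (default; descending for direction "up",
    ascending for "down") or "p" (most significant first). Rank ties break
    lexicographically by gene id. Returns a shorter signature with a warning
    when fewer than ``n`` genes qualify.
    """
    if n < 1:
        raise ConfigError("signature size n must be >= 1")
    if direction not in ("up", "down"):
        raise ConfigError("direction must be 'up' or 'down'")
    sub = de.contrast(contrast)
    sig = sub[sub["q"] < q_max]
    sig = sig[sig["log2fc"] > 0] if direction == "up" else sig[sig["log2fc"] < 0]
    if rank_by == "log2fc":
        key = -sig["log2fc"] if direction == "up" else sig["log2fc"]
    elif rank_by == "p":
        key = sig["p"]
    else:
        raise ConfigError("rank_by must be 'log2fc' or 'p'")
    order = sorted(range(len(sig)), key=lambda i: (key.iloc[i], sig["gene"].iloc[i]))
    genes = [sig["gene"].iloc[i] for i in order[:n]]
    if len(genes) < n:
        logger.warning(
            "contrast %s: only %d significant %s-regulated genes for a top-%d signature",
            contrast, len(genes), direction, n,
        )
    return Signature(
        name=f"{contrast}_top{n}_{direction}",
        genes=genes,
        provenance={
            "contrast": contrast, "n": n, "direction": direction,
            "q_max": q_max, "rank_by": rank_by,
        },
    )
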