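"""Relative-expression weighted pathway activity per cell type, with a
permutation null.

The statistic: for gene g and cell type t, the *relative expression*
r_gt is the gene's mean expression in type t divided by the unweighted
average of its per-type means (1 = parity across types). A pathway's
activity in type t is the weighted mean of r_gt over the pathway's measured
genes, with weight w_g = 1 / (number of pathways containing g), after
excluding outlier genes. Significance comes from shuffling cell-type labels
across cells (within condition) and recomputing the whole statistic;
p = (1 + #{permuted |score-1| >= observed |score-1|}) / (1 + n_perm),
Benjamini-Hochberg adjusted across all defined (pathway, type) entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, DataError, ExpressionMatrix, PathwayCollection

logger = logging.getLogger(__name__)

MIN_USABLE_GENES = 3


@dataclass
class ActivityTable:
    """Pathway x cell-type activity scores with permutation significance.

    Undefined entries (too few usable genes) are NaN, never zero.
    """

    score: pd.DataFrame
    p_value: pd.DataFrame | None = None
    q_value: pd.DataFrame | None = None
    n_genes_used: pd.DataFrame | None = None
    condition: str | None = None

    def to_long(self, category: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for pw in self.score.index:
            for ct in self.score.columns:
                rows.append(
                    {
                        "condition": self.condition,
                        "cell_type": ct,
                        "pathway": pw,
                        "category": (category or {}).get(pw, "uncategorized"),
                        "score": self.score.loc[pw, ct],
                        "n_genes": (
                            self.n_genes_used.loc[pw, ct]
                            if self.n_genes_used is not None
                            else np.nan
                        ),
                        "p": (
                            self.p_value.loc[pw, ct]
                            if self.p_value is not None
                            else np.nan
                        ),
                        "q": (
                            self.q_value.loc[pw, ct]
                            if self.q_value is not None
                            else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def celltype_means(
    expr: ExpressionMatrix, by: str | pd.Series = "cell_type"
) -> pd.DataFrame:
    """Arithmetic mean of each gene within each cell type (genes x types)."""
    if expr.n_columns == 0 or expr.n_genes == 0:
        raise DataError("cannot average an empty expression matrix")
    labels = expr.annotation(by) if isinstance(by, str) else pd.Series(by, index=expr.column_ids)
    out = {}
    for ct in pd.unique(labels):
        cols = np.flatnonzero((labels == ct).values)
        if len(cols) == 0:
            logger.warning("cell type %s has no cells; excluded", ct)
            continue
        out[ct] = expr.values[:, cols].mean(axis=1)
    return pd.DataFrame(out, index=expr.gene_ids)


def relative_expression(means: pd.DataFrame) -> pd.DataFrame:
    """r_gt = mean_gt / unweighted average of the gene's per-type means.

    Genes whose cross-type average is zero are NaN (undefined, not zero).
    Requires >= 2 cell types.
    """
    if means.shape[1] < 2:
        raise DataError("relative expression needs >= 2 cell types")
    avg = means.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = means.values / avg.values[:, None]
    rel[avg.values == 0] = np.nan
    return pd.DataFrame(rel, index=means.index, columns=means.columns)


def iqr_outlier_rule(rel_block: np.ndarray) -> np.ndarray:
    """Default outlier rule for one pathway: a gene is excluded when its
    maximum relative expression over types exceeds Q3 + 3*IQR of the pooled
    finite r values of the pathway's genes. Returns a keep-mask per gene."""
    finite = rel_block[np.isfinite(rel_block)]
    if finite.size == 0:
        return np.zeros(rel_block.shape[0], dtype=bool)
    q1, q3 = np.quantile(finite, [0.25, 0.75])
    upper = q3 + 3.0 * (q3 - q1)
    gene_max = np.where(np.isfinite(rel_block), rel_block, -np.inf).max(axis=1)
    keep = gene_max <= upper
    keep &= np.isfinite(rel_block).all(axis=1)
    return keep


def pathway_scores(
    rel: pd.DataFrame,
    pathways: PathwayCollection,
    outlier_rule=iqr_outlier_rule,
    min_genes: int = MIN_USABLE_GENES,
) -> ActivityTable:
    """Weighted mean of relative expression per (pathway, type).

    ``outlier_rule`` maps a (genes x types) block of r values to a boolean
    keep-mask (pass ``None`` to disable outlier exclusion). Pathways with
    fewer than ``min_genes`` usable genes are NaN.
    """
    mult = pathways.multiplicity()
    types = rel.columns
    score = pd.DataFrame(np.nan, index=pathways.names, columns=types)
    n_used = pd.DataFrame(0, index=pathways.names, columns=types)
    gene_pos = {g: i for i, g in enumerate(rel.index)}
    rel_values = rel.values
    for pw in pathways.names:
        members = [g for g in pathways[pw] if g in gene_pos]
        if len(members) < min_genes:
            logger.info("pathway %s: %d measured genes < %d; undefined", pw, len(members), min_genes)
            continue
        idx = np.array([gene_pos[g] for g in members])
        block = rel_values[idx]
        if outlier_rule is not None:
            keep = outlier_rule(block)
        else:
            keep = np.isfinite(block).all(axis=1)
        if keep.sum() < min_genes:
            logger.info("pathway %s: %d usable genes after outlier/NA exclusion; undefined", pw, int(keep.sum()))
            continue
        w = np.array([1.0 / mult[g] for g in members])[keep]
        block = block[keep]
        score.loc[pw] = (w[:, None] * block).sum(axis=0) / w.sum()
        n_used.loc[pw] = int(keep.sum())
    return ActivityTable(score=score, n_genes_used=n_used)


def score_pipeline(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    by: str | pd.Series = "cell_type",
    outlier_rule=iqr_outlier_rule,
) -> ActivityTable:
    """celltype_means -> relative_expression -> pathway_scores."""
    means = celltype_means(expr, by=by)
    rel = relative_expression(means)
    return pathway_scores(rel, pathways, outlier_rule=outlier_rule)


# ---------------------------------------------------------------------------
# permutation test


def _scores_for_labels_stacked(
    X: np.ndarray,
    label_codes: np.ndarray,
    n_types: int,
    pathway_index: list[np.ndarray],
    weights: list[np.ndarray],
    outlier: bool,
    min_genes: int,
) -> np.ndarray:
    """Vectorized score computation for a stack of label vectors.

    ``label_codes``: (n_perm, n_cells) integer type codes. Returns
    (n_perm, n_pathways, n_types) scores (NaN where undefined).
    """
    n_perm, n_cells = label_codes.shape
    n_genes = X.shape[0]
    # one-hot with 1/count weights: cells x (n_perm*n_types)
    counts = np.zeros((n_perm, n_types))
    for t in range(n_types):
        counts[:, t] = (label_codes == t).sum(axis=1)
    H = np.zeros((n_cells, n_perm * n_types))
    rows = np.repeat(np.arange(n_perm), n_cells)
    cols = rows * n_types + label_codes.ravel()
    np.add.at(H, (np.tile(np.arange(n_cells), n_perm), cols), 1.0)
    cnt_flat = counts.reshape(-1)
    cnt_flat[cnt_flat == 0] = np.nan
    H = H / cnt_flat[None, :]
    means = X @ H  # genes x (n_perm*n_types)
    means = means.reshape(n_genes, n_perm, n_types)
    avg = means.mean(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = means / avg[:, :, None]
    rel[avg == 0] = np.nan

    out = np.full((n_perm, len(pathway_index), n_types), np.nan)
    for k, (idx, w) in enumerate(zip(pathway_index, weights)):
        block = rel[idx]  # m x n_perm x n_types
        finite = np.isfinite(block).all(axis=2)  # m x n_perm
        if outlier:
            # per-perm pooled Q1/Q3 over the pathway's finite r values
            keep = np.zeros_like(finite)
            for p in range(n_perm):
                vals = block[:, p, :][finite[:, p]]
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    continue
                q1p, q3p = np.quantile(vals, [0.25, 0.75])
                upper = q3p + 3.0 * (q3p - q1p)
                gmax = np.where(
                    np.isfinite(block[:, p, :]), block[:, p, :], -np.inf
                ).max(axis=1)
                keep[:, p] = finite[:, p] & (gmax <= upper)
        else:
            keep = finite
        usable = keep.sum(axis=0)  # per perm
        wk = w[:, None] * keep  # m x n_perm
        wsum = wk.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sc = np.einsum("mp,mpt->pt", wk, np.nan_to_num(block)) / wsum[:, None]
        sc[usable < min_genes] = np.nan
        out[:, k, :] = sc
    return out


def permutation_test(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    observed: ActivityTable,
    n_perm: int = 1000,
    seed: int = 0,
    by: str | pd.Series = "cell_type",
    outlier: bool = True,
    batch_size: int = 100,
) -> ActivityTable:
    """Permutation p- and q-values for an observed ActivityTable.

    Cell-type labels are shuffled across cells and the full score pipeline
    (means -> relative expression -> outlier exclusion -> weighted mean)
    recomputed per permutation. Deviation = |score - 1| (two-sided).
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    labels = expr.annotation(by) if isinstance(by, str) else pd.Series(by, index=expr.column_ids)
    types = list(observed.score.columns)
    code_of = {t: i for i, t in enumerate(types)}
    base_codes = np.array([code_of[t] for t in labels])

    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    mult = pathways.multiplicity()
    pathway_index, weights = [], []
    for pw in observed.score.index:
        members = [g for g in pathways[pw] if g in gene_pos]
        pathway_index.append(np.array([gene_pos[g] for g in members], dtype=int))
        weights.append(np.array([1.0 / mult[g] for g in members]))

    obs_dev = np.abs(observed.score.values - 1.0)
    exceed = np.zeros_like(obs_dev)
    rng = np.random.default_rng(seed)
    X = expr.values
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        perm_codes = np.empty((b, len(base_codes)), dtype=int)
        for i in range(b):
            perm_codes[i] = rng.permutation(base_codes)
        perm_scores = _scores_for_labels_stacked(
            X, perm_codes, len(types), pathway_index, weights,
            outlier=outlier, min_genes=MIN_USABLE_GENES,
        )
        dev = np.abs(perm_scores - 1.0)
        with np.errstate(invalid="ignore"):
            exceed += np.nansum(dev >= obs_dev[None, :, :], axis=0)
        done += b

    p = (1.0 + exceed) / (1.0 + n_perm)
    p[~np.isfinite(obs_dev)] = np.nan
    p_frame = pd.DataFrame(p, index=observed.score.index, columns=types)
    q_frame = bh_adjust(p_frame)
    return ActivityTable(
        score=observed.score,
        p_value=p_frame,
        q_value=q_frame,
        n_genes_used=observed.n_genes_used,
        condition=observed.condition,
    )


def bh_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg over all defined entries of a p-value table."""
    flat = p.values.ravel()
    mask = np.isfinite(flat)
    q = np.full_like(flat, np.nan)
    if mask.sum():
        q[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    return pd.DataFrame(q.reshape(p.shape), index=p.index, columns=p.columns)


def activity_heat_table(
    tumor: ActivityTable,
    normal: ActivityTable | None = None,
    pathways: PathwayCollection | None = None,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Long-format export for plotting: scores with q > q_max masked (NaN).

    When both conditions are given the result is their outer join on
    (pathway, cell_type); sorted by category then pathway.
    """
    category = pathways.category if pathways is not None else {}
    frames = []
    for tab, cond in ((tumor, tumor.condition or "tumor"),
                      (normal, None if normal is None else normal.condition or "normal")):
        if tab is None:
            continue
        long = tab.to_long(category)
        long["condition"] = cond
        masked = long["q"].notna() & (long["q"] > q_max)
        long.loc[masked, "score"] = np.nan
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["category", "pathway", "condition", "cell_type"]).reset_index(
        drop=True
    )
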