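"""QC filtering, dropout-aware imputation and size-factor normalization.

Imputation follows the thresholded-decision-rule design of scImpute-style
methods: within each sample, a two-component mixture on log(TPM+1)
separates a low "dropout" mode from a normal expression mode per gene; each
observation gets a posterior dropout probability d_gc, and only genes whose
observation is likely a dropout (d_gc > drop_thre) are re-estimated from the
cell's most similar neighbours by non-negative regression on the reliable
genes. Entries deemed reliable are never touched.

Size factors come in four flavours — RLE (median-of-ratios), upper-quartile,
TMM and the pooled-deconvolution estimator — all rescaled to geometric mean
one. Deconvolution pools cells along a library-size-ordered ring, equates
each pool's summed profile to the average pseudo-cell, and solves the
resulting linear system for the per-cell factors by least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg

from .io import ConfigError, DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_POOL_SIZES = tuple(range(21, 102, 10))


@dataclass
class QCThresholds:
    """Cell-level quality-control thresholds (boundary inclusive)."""

    min_genes: int = 500
    min_umis: int = 1000
    max_mito_fraction: float = 0.20
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.min_umis < 0:
            raise ConfigError("min_genes and min_umis must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must lie in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_low_genes: int
    removed_low_umis: int
    removed_high_mito: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["input", "kept", "low_genes", "low_umis", "high_mito"],
                "cells": [
                    self.n_input,
                    self.n_kept,
                    self.removed_low_genes,
                    self.removed_low_umis,
                    self.removed_high_mito,
                ],
            }
        )


def qc_filter_cells(
    counts: ExpressionMatrix, thresholds: QCThresholds | None = None
) -> tuple[ExpressionMatrix, QCReport]:
    """Keep cells with detected genes >= min_genes, UMIs >= min_umis and
    mitochondrial fraction <= max_mito_fraction (all boundaries inclusive)."""
    thresholds = thresholds or QCThresholds()
    X = counts.values
    detected = (X > 0).sum(axis=0)
    umis = X.sum(axis=0)
    mito = np.array(
        [g.startswith(thresholds.mito_gene_prefix) for g in counts.gene_ids]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, X[mito].sum(axis=0) / np.maximum(umis, 1), 1.0)
    ok_genes = detected >= thresholds.min_genes
    ok_umis = umis >= thresholds.min_umis
    ok_mito = mito_frac <= thresholds.max_mito_fraction
    keep = ok_genes & ok_umis & ok_mito
    report = QCReport(
        n_input=counts.n_columns,
        n_kept=int(keep.sum()),
        removed_low_genes=int((~ok_genes).sum()),
        removed_low_umis=int((~ok_umis).sum()),
        removed_high_mito=int((~ok_mito).sum()),
    )
    if report.n_kept == 0:
        raise DataError("QC removed every cell; pipeline cannot proceed")
    return counts.subset_columns(keep), report


# ---------------------------------------------------------------------------
# dropout model


@dataclass
class DropoutModel:
    """Per-(gene, cell) posterior dropout probabilities plus the mixture
    parameters that produced them, fitted within cell groups (samples)."""

    dropout_probability: np.ndarray          # gene x cell, in [0, 1]
    mixture_weight: pd.DataFrame             # gene x group lambda of dropout mode
    groups: pd.Series                        # per cell group label
    gene_ids: pd.Index
    unimputable: pd.DataFrame | None = None  # gene x group bool (all-zero genes)
    skipped_groups: list = field(default_factory=list)
    gene_gate: np.ndarray | None = None      # genes eligible for imputation


def _em_two_component(y: np.ndarray, max_iter: int = 60, tol: float = 1e-6):
    """EM for the dropout mixture on log(TPM+1) values of one gene.

    The dropout component is a low mode anchored at zero (mean fixed at 0,
    scale estimated) — dropouts are zeros or near-zeros regardless of the
    gene's expression level — while the expression component is a free
    normal. Returns (lam, mu0, sd0, mu1, sd1, posterior-of-dropout).
    """
    mu0 = 0.0
    nonzero = y[y > 0]
    if len(nonzero) == 0:
        return 1.0, 0.0, 0.1, 0.0, 0.1, np.ones_like(y)
    r = (y <= 1e-8).astype(float)
    lam = float(np.clip(r.mean(), 1e-3, 1 - 1e-3))
    sd0 = 0.3
    mu1 = float(nonzero.mean())
    sd1 = float(max(nonzero.std(), 0.2))
    ll_old = -np.inf
    for _ in range(max_iter):
        p0 = lam * _normal_pdf(y, mu0, sd0)
        p1 = (1 - lam) * _normal_pdf(y, mu1, sd1)
        tot = p0 + p1
        tot[tot == 0] = 1e-300
        r = p0 / tot
        lam = float(np.clip(r.mean(), 1e-4, 1 - 1e-4))
        w0, w1 = r.sum(), (1 - r).sum()
        sd0 = float(np.sqrt((r * y**2).sum() / max(w0, 1e-12)))
        sd0 = min(max(sd0, 0.2), 1.0)
        mu1 = float(((1 - r) * y).sum() / max(w1, 1e-12))
        sd1 = float(np.sqrt(((1 - r) * (y - mu1) ** 2).sum() / max(w1, 1e-12)))
        sd1 = max(sd1, 0.2)
        mu1 = max(mu1, 0.0)
        ll = float(np.log(tot).sum())
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return lam, mu0, sd0, mu1, sd1, r


def _normal_pdf(y, mu, sd):
    return np.exp(-0.5 * ((y - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def fit_dropout_model(
    tpm: ExpressionMatrix,
    groups: pd.Series | str = "sample",
    min_group_size: int = 10,
    zero_rate_gate: float = 0.5,
) -> DropoutModel:
    """Fit the per-gene dropout mixture within each cell group.

    ``groups`` may be an annotation key (default ``"sample"``) or a Series
    aligned to the columns. Genes with zero counts everywhere in a group get
    d_gc = 1 and are flagged unimputable. Genes with no zeros and (near)
    constant positive expression get d_gc ~ 0. The gene-level gate records
    which genes have a zero rate above ``zero_rate_gate`` — only those are
    candidates for imputation.
    """
    if isinstance(groups, str):
        groups = tpm.annotation(groups)
    groups = pd.Series(groups, index=tpm.column_ids)
    X = tpm.values
    log_x = np.log1p(X)
    n_genes, n_cells = X.shape
    d = np.zeros((n_genes, n_cells))
    group_names = list(pd.unique(groups))
    lam_frame = pd.DataFrame(0.0, index=tpm.gene_ids, columns=group_names)
    unimputable = pd.DataFrame(False, index=tpm.gene_ids, columns=group_names)
    skipped: list[str] = []
    for gname in group_names:
        cols = np.flatnonzero((groups == gname).values)
        if len(cols) < min_group_size:
            skipped.append(gname)
            logger.warning(
                "group %s has %d cells (< %d); dropout model skipped",
                gname, len(cols), min_group_size,
            )
            continue
        sub = log_x[:, cols]
        zero_frac = (sub == 0).mean(axis=1)
        for g in range(n_genes):
            y = sub[g]
            if zero_frac[g] == 1.0:
                d[g, cols] = 1.0
                lam_frame.iloc[g, lam_frame.columns.get_loc(gname)] = 1.0
                unimputable.iloc[g, unimputable.columns.get_loc(gname)] = True
                continue
            if zero_frac[g] == 0.0 and np.ptp(y) < 1e-8:
                # constant positive expression: no dropout signal
                continue
            if zero_frac[g] == 0.0 and np.std(y) < 0.05:
                continue
            lam, mu0, sd0, mu1, sd1, r = _em_two_component(y)
            # expression mode collapsed onto the zero mode: the gene is
            # essentially unexpressed; no usable dropout signal
            if mu1 - mu0 < 0.2:
                continue
            d[g, cols] = r
            lam_frame.iloc[g, lam_frame.columns.get_loc(gname)] = lam
    gate = (X == 0).mean(axis=1) > zero_rate_gate
    return DropoutModel(
        dropout_probability=d,
        mixture_weight=lam_frame,
        groups=groups,
        gene_ids=tpm.gene_ids,
        unimputable=unimputable,
        skipped_groups=skipped,
        gene_gate=gate,
    )


def impute_dropouts(
    tpm: ExpressionMatrix,
    model: DropoutModel,
    drop_thre: float = 0.5,
    n_neighbors: int = 20,
    min_neighbors: int = 3,
    apply_gene_gate: bool = True,
) -> ExpressionMatrix:
    """Re-estimate likely-dropout entries from similar cells.

    For each cell, entries with d_gc > ``drop_thre`` (and, when
    ``apply_gene_gate``, genes whose overall zero rate exceeds 50%) are
    replaced by a non-negative least-squares prediction from the cell's top
    correlated neighbours within the same group, fitted on the cell's
    reliable genes. Reliable entries are returned bit-identical.
    """
    if not 0.0 < drop_thre <= 1.0:
        raise ConfigError("drop_thre must lie in (0, 1]")
    X = tpm.values.copy()
    log_x = np.log1p(tpm.values)
    d = model.dropout_probability
    gate = model.gene_gate if (apply_gene_gate and model.gene_gate is not None) else np.ones(
        tpm.n_genes, dtype=bool
    )
    for gname in pd.unique(model.groups):
        if gname in model.skipped_groups:
            continue
        cols = np.flatnonzero((model.groups == gname).values)
        if len(cols) < min_neighbors + 1:
            logger.warning("group %s too small to impute; left as is", gname)
            continue
        sub_log = log_x[:, cols]
        sub_d = d[:, cols]
        k = min(n_neighbors, len(cols) - 1)
        for j_local, j in enumerate(cols):
            target = sub_d[:, j_local] > drop_thre
            target &= gate
            if not target.any():
                continue
            reliable = (sub_d[:, j_local] <= drop_thre) & ~target
            if reliable.sum() < 5:
                logger.warning("cell %s: too few reliable genes; skipped", j)
                continue
            # similarity on reliable genes
            y = sub_log[reliable][:, j_local]
            others = np.delete(np.arange(len(cols)), j_local)
            A = sub_log[reliable][:, others]
            sd_a = A.std(axis=0)
            valid = sd_a > 0
            corr = np.zeros(len(others))
            if y.std() > 0 and valid.any():
                yc = (y - y.mean()) / y.std()
                Ac = (A[:, valid] - A[:, valid].mean(axis=0)) / sd_a[valid]
                corr[valid] = yc @ Ac / len(y)
            order = np.argsort(-corr)[:k]
            nbr = others[order]
            if len(nbr) < min_neighbors:
                continue
            B = sub_log[reliable][:, nbr]
            coef, _ = scipy.optimize.nnls(B, y)
            pred_log = sub_log[target][:, nbr] @ coef
            X[target, j] = np.expm1(np.maximum(pred_log, 0.0))
    return tpm.with_values(X)


# ---------------------------------------------------------------------------
# size factors


@dataclass
class SizeFactors:
    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise DataError("size factors must be strictly positive")

    @property
    def values(self) -> np.ndarray:
        return self.factors.values


def _rescale_geomean(f: np.ndarray) -> np.ndarray:
    return f / np.exp(np.mean(np.log(f)))


def _rle_factors(X: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_x = np.where(X > 0, np.log(X), np.nan)
    all_pos = ~np.isnan(log_x).any(axis=1)
    if not all_pos.any():
        raise DataError("RLE undefined: no gene is positive in every cell")
    ref = np.exp(log_x[all_pos].mean(axis=1))
    ratios = X[all_pos] / ref[:, None]
    return np.median(ratios, axis=0)


def _upperquartile_factors(X: np.ndarray, q: float = 0.75) -> np.ndarray:
    f = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        nz = X[:, j][X[:, j] > 0]
        if len(nz) == 0:
            raise DataError(f"column {j} is all zero; upper-quartile undefined")
        f[j] = np.quantile(nz, q)
    return f


def _tmm_factors(X: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    lib = X.sum(axis=0)
    # reference column: library size closest to the median
    ref_j = int(np.argmin(np.abs(lib - np.median(lib))))
    ref = X[:, ref_j]
    f = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        obs = X[:, j]
        both = (obs > 0) & (ref > 0)
        if both.sum() < 2:
            f[j] = 1.0
            continue
        p_obs = obs[both] / lib[j]
        p_ref = ref[both] / lib[ref_j]
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # weights: inverse asymptotic variance of M
        w = (lib[j] - obs[both]) / (lib[j] * obs[both]) + (
            lib[ref_j] - ref[both]
        ) / (lib[ref_j] * ref[both])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            f[j] = 1.0
            continue
        tmm = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        # TMM is a composition correction; combine with library size
        f[j] = lib[j] * 2.0 ** tmm
    return f


def _deconvolution_factors(
    X: np.ndarray, pool_sizes=DEFAULT_POOL_SIZES, low_weight: float = 0.1
) -> np.ndarray:
    n = X.shape[1]
    pool_sizes = [s for s in pool_sizes if s <= n]
    if not pool_sizes:
        pool_sizes = [max(2, n // 2)]
    lib = X.sum(axis=0)
    order = np.argsort(lib)
    # alternate low/high library sizes around the ring so pools are balanced
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2:][::-1]
    ref = X.mean(axis=1)  # average pseudo-cell
    pos = ref > 0
    Xr = X[pos][:, ring]
    refp = ref[pos]
    # ring-wrapped pooled sums via cumulative sums: pool(start, s) =
    # cum[start+s] - cum[start], wrapping past n
    cum = np.concatenate(
        [np.zeros((Xr.shape[0], 1)), np.cumsum(Xr, axis=1)], axis=1
    )
    rows, cols_idx, vals, rhs = [], [], [], []
    eq = 0
    starts = np.arange(n)
    for s in pool_sizes:
        end = starts + s
        wrap = end > n
        pooled = cum[:, np.minimum(end, n)] - cum[:, starts]
        if wrap.any():
            pooled[:, wrap] += cum[:, end[wrap] - n]
        theta = np.median(pooled / refp[:, None], axis=0)
        member_idx = (starts[:, None] + np.arange(s)[None, :]) % n
        rows.append(np.repeat(eq + starts, s))
        cols_idx.append(ring[member_idx].ravel())
        vals.append(np.ones(n * s))
        rhs.append(theta)
        eq += n
    # low-weight anchors tying each factor to its library-size estimate
    lib_est = lib / np.mean(lib)
    rows.append(eq + np.arange(n))
    cols_idx.append(np.arange(n))
    vals.append(np.full(n, low_weight))
    rhs.append(low_weight * lib_est)
    eq += n
    A = scipy.sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols_idx))),
        shape=(eq, n),
    )
    sol = scipy.sparse.linalg.lsqr(A, np.concatenate(rhs), atol=1e-10, btol=1e-10)[0]
    if np.any(sol <= 0):
        smallest_pos = sol[sol > 0].min() if np.any(sol > 0) else 1.0
        logger.warning(
            "deconvolution produced %d non-positive factors; clipped",
            int((sol <= 0).sum()),
        )
        sol = np.where(sol <= 0, smallest_pos, sol)
    return sol


def size_factors(
    counts: ExpressionMatrix,
    method: str = "deconvolution",
    pool_sizes=DEFAULT_POOL_SIZES,
) -> SizeFactors:
    """Estimate per-cell size factors; geometric mean rescaled to one."""
    X = counts.values
    if np.any(X < 0):
        raise DataError("size factors require non-negative counts")
    if method == "RLE":
        f = _rle_factors(X)
    elif method == "upperquartile":
        f = _upperquartile_factors(X)
    elif method == "TMM":
        f = _tmm_factors(X)
    elif method == "deconvolution":
        f = _deconvolution_factors(X, pool_sizes=pool_sizes)
    else:
        raise ConfigError(
            f"unknown size-factor method {method!r}; "
            "expected deconvolution, RLE, TMM or upperquartile"
        )
    f = _rescale_geomean(np.asarray(f, dtype=float))
    return SizeFactors(pd.Series(f, index=counts.column_ids), method)


def size_factor_stability(
    counts: ExpressionMatrix,
    method: str,
    n_subsamples: int = 5,
    gene_fraction: float = 0.8,
    seed: int = 0,
) -> float:
    """Diagnostic: mean coefficient of variation of the factor estimates
    under random gene subsampling (smaller = more stable)."""
    rng = np.random.default_rng(seed)
    n_genes = counts.n_genes
    estimates = []
    for _ in range(n_subsamples):
        idx = rng.choice(n_genes, size=int(gene_fraction * n_genes), replace=False)
        sub = ExpressionMatrix(
            counts.values[idx],
            counts.gene_ids[idx],
            counts.column_ids,
            counts.column_annotation,
            units=counts.units,
        )
        estimates.append(size_factors(sub, method=method).values)
    est = np.vstack(estimates)
    cv = est.std(axis=0) / est.mean(axis=0)
    return float(np.mean(cv))


def normalize(
    counts: ExpressionMatrix,
    factors: SizeFactors,
    log_transform: bool = False,
) -> ExpressionMatrix:
    """Divide each column by its size factor; optional log1p."""
    f = factors.factors.reindex(counts.column_ids)
    if f.isna().any():
        raise DataError("size factors missing for some columns")
    if (f <= 0).any():
        raise DataError("size factors must be positive")
    X = counts.values / f.values[None, :]
    units = "normalized"
    if log_transform:
        X = np.log1p(X)
        units = "lognorm"
    return counts.with_values(X, units=units)
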