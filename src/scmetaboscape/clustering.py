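"""Metabolic subcluster discovery.

Malignant cells are split into high/low metabolic subclusters by
agglomerative clustering (complete linkage, Euclidean distance, tree cut at
k = 2) on their per-cell pathway scores; the "high"/"low" names are assigned
afterwards from the data. The low subcluster can be re-clustered on
expression (PCA -> shared-nearest-neighbour graph -> modularity community
detection), and subtype-composition differences are tested with chi-square
tests on 2x2 tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .enrichment import PerCellScoreMatrix
from .io import ConfigError, DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    labels: pd.Series                       # cell -> label
    method: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def vocabulary(self) -> list:
        return sorted(pd.unique(self.labels), key=str)

    def __len__(self) -> int:
        return len(self.labels)


def _score_matrix(scores: PerCellScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(scores, PerCellScoreMatrix):
        return scores.scores
    return scores


def hierarchical_split(
    scores: PerCellScoreMatrix | pd.DataFrame,
    k: int = 2,
    standardize: bool = True,
) -> ClusterAssignment:
    """Complete-linkage agglomerative clustering of cells on pathway scores.

    Scores are z-scored per pathway across cells first (so no single
    high-variance pathway dominates the Euclidean metric; switch off with
    ``standardize=False``), then the pairwise Euclidean distance matrix is
    clustered and the tree cut into ``k`` groups.
    """
    frame = _score_matrix(scores)
    cells = frame.columns
    X = frame.values.T.astype(float)  # cells x pathways
    if k > X.shape[0]:
        raise ConfigError(f"k={k} exceeds the number of cells ({X.shape[0]})")
    if not np.isfinite(X).all():
        raise DataError("pathway scores contain non-finite values")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    d = scipy.spatial.distance.pdist(X, metric="euclidean")
    link = scipy.cluster.hierarchy.linkage(d, method="complete")
    raw = scipy.cluster.hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series([f"cluster{i}" for i in raw], index=cells, name="metabolic_cluster")
    return ClusterAssignment(
        labels, method="hierarchical_complete",
        parameters={"k": k, "standardize": standardize, "metric": "euclidean"},
    )


def label_high_low(
    assign: ClusterAssignment, scores: PerCellScoreMatrix | pd.DataFrame
) -> ClusterAssignment:
    """Name the two clusters "high"/"low" by mean per-cell mean pathway score."""
    frame = _score_matrix(scores)
    vocab = assign.vocabulary
    if len(vocab) != 2:
        raise DataError(f"label_high_low needs exactly 2 clusters, got {len(vocab)}")
    cell_mean = frame.mean(axis=0)  # per-cell mean over pathways
    means = {v: cell_mean[assign.labels == v].mean() for v in vocab}
    a, b = vocab
    if means[a] == means[b]:
        logger.warning("cluster mean scores tie exactly; first cluster labelled high")
        high = a
    else:
        high = a if means[a] > means[b] else b
    mapping = {v: ("high" if v == high else "low") for v in vocab}
    labels = assign.labels.map(mapping).rename("metabolic_group")
    return ClusterAssignment(
        labels, method=assign.method + "+high_low",
        parameters={**assign.parameters, "cluster_means": {str(k): float(v) for k, v in means.items()}},
    )


def pca_on_scores(
    scores: PerCellScoreMatrix | pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of cells in pathway-score space.

    Sign convention: each component's largest-magnitude loading is positive.
    Returns (cells x components coordinates, variance-explained ratios).
    """
    frame = _score_matrix(scores)
    X = frame.values.T.astype(float)
    if X.std() == 0:
        raise DataError("constant score matrix; PCA undefined")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    out = pd.DataFrame(
        coords, index=frame.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return out, pca.explained_variance_ratio_


def subcluster_cells(
    expr: ExpressionMatrix,
    n_pcs: int = 10,
    resolution: float = 0.1,
    seed: int = 0,
    n_top_genes: int = 2000,
    min_cells: int = 50,
    prefix: str = "lmCluster",
) -> ClusterAssignment:
    """Graph-community re-clustering of one cell subset.

    Log-normalized highly variable genes -> PCA (``n_pcs``) ->
    shared-nearest-neighbour graph -> Leiden modularity communities at the
    given resolution. Labels ``lmCluster0..m`` ordered by decreasing size.
    """
    import scanpy as sc

    from .io import to_anndata

    if expr.n_columns < min_cells:
        raise DataError(f"subclustering needs >= {min_cells} cells, got {expr.n_columns}")
    adata = to_anndata(expr)
    if expr.units == "counts":
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
    elif expr.units != "lognorm":
        adata.X = np.log1p(adata.X)
    n_hvg = min(n_top_genes, adata.n_vars - 1)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg)
    adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(adata, max_value=10)
    n_comps = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    sc.tl.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_pcs=n_comps, random_state=seed)
    import warnings

    with warnings.catch_warnings():
        # scanpy warns about the future default flavor; we pin leidenalg
        warnings.filterwarnings("ignore", category=FutureWarning)
        sc.tl.leiden(
            adata, resolution=resolution, random_state=seed, key_added="community",
            flavor="leidenalg",
        )
    raw = adata.obs["community"].astype(str)
    sizes = raw.value_counts()
    rename = {old: f"{prefix}{i}" for i, old in enumerate(sizes.index)}
    labels = pd.Series(
        raw.map(rename).values, index=expr.column_ids, name="subcluster"
    )
    return ClusterAssignment(
        labels, method="snn_leiden",
        parameters={"n_pcs": n_comps, "resolution": resolution, "hvg": n_hvg},
        seed=seed,
    )


def proportion_test(
    assign: ClusterAssignment,
    stratum: pd.Series,
    expected_min: float = 5.0,
) -> pd.DataFrame:
    """Pairwise chi-square tests of high/low composition across strata.

    For each pair of strata a 2x2 table (cluster label x stratum) is tested
    with Pearson chi-square (no continuity correction); when any expected
    count falls below ``expected_min`` Fisher's exact test is used instead
    (flagged in the output). BH across pairs.
    """
    stratum = pd.Series(stratum).reindex(assign.labels.index)
    strata = sorted(pd.unique(stratum.dropna()), key=str)
    if len(strata) < 2:
        raise DataError("proportion_test needs >= 2 strata")
    vocab = assign.vocabulary
    if len(vocab) != 2:
        raise DataError("proportion_test expects a 2-cluster assignment")
    records = []
    for s1, s2 in combinations(strata, 2):
        table = np.array(
            [
                [
                    int(((assign.labels == v) & (stratum == s)).sum())
                    for s in (s1, s2)
                ]
                for v in vocab
            ]
        )
        exact = False
        if table.sum() == 0:
            continue
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected < expected_min).any():
            logger.warning(
                "pair (%s, %s): expected count < %g; Fisher exact fallback",
                s1, s2, expected_min,
            )
            _, p = scipy.stats.fisher_exact(table)
            stat = np.nan
            exact = True
        else:
            stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        records.append(
            {"stratum_1": s1, "stratum_2": s2, "chi2": stat, "p": p, "exact": exact}
        )
    out = pd.DataFrame(records)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
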