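"""Data containers and readers/writers for the formats the pipeline touches.

The pipeline's substrate is a genes x columns expression matrix (columns are
cells for single-cell data, samples for bulk data) with per-column annotation,
plus named gene-set collections (GMT) and a gene-length table used for TPM
conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: KEGG's eleven top-level metabolic classes; the `description` column of a
#: GMT line is parsed as a category when it case-insensitively matches one.
KEGG_METABOLIC_CLASSES = (
    "Amino acid metabolism",
    "Biosynthesis of other secondary metabolites",
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Glycan biosynthesis and metabolism",
    "Lipid metabolism",
    "Metabolism of cofactors and vitamins",
    "Metabolism of other amino acids",
    "Metabolism of terpenoids and polyketides",
    "Nucleotide metabolism",
    "Xenobiotics biodegradation and metabolism",
)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration or parameter value."""


@dataclass
class ExpressionMatrix:
    """Genes x columns numeric matrix with identifiers and column annotation.

    Parameters
    ----------
    values
        2-D array, genes on rows, cells/samples on columns. Stored dense.
    gene_ids, column_ids
        Unique string identifiers for rows / columns.
    column_annotation
        Data frame indexed by ``column_ids`` (same order); free-form columns
        such as ``sample``, ``condition`` ({tumor, normal}), ``cell_type``.
    units
        One of ``counts``, ``TPM``, ``normalized``, ``lognorm``; counts and
        TPM must be non-negative.
    """

    values: np.ndarray
    gene_ids: pd.Index
    column_ids: pd.Index
    column_annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    units: str = "counts"

    def __post_init__(self) -> None:
        if scipy.sparse.issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=float)
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        self.column_ids = pd.Index(self.column_ids, dtype=object)
        if self.column_annotation is None:
            self.column_annotation = pd.DataFrame(index=self.column_ids)
        n_genes, n_cols = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise DataError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.column_ids) != n_cols:
            raise DataError(
                f"{len(self.column_ids)} column ids for {n_cols} matrix columns"
            )
        if self.gene_ids.has_duplicates:
            dup = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene identifiers: {dup[:5]}")
        if self.column_ids.has_duplicates:
            dup = self.column_ids[self.column_ids.duplicated()].unique().tolist()
            raise DataError(f"duplicate column identifiers: {dup[:5]}")
        if not self.column_annotation.index.equals(self.column_ids):
            missing = self.column_ids.difference(self.column_annotation.index)
            if len(missing):
                raise DataError(
                    f"annotation missing for columns: {missing.tolist()[:5]}"
                )
            # same set, different order: realign
            self.column_annotation = self.column_annotation.loc[self.column_ids]
        if self.units in ("counts", "TPM") and np.any(self.values < 0):
            raise DataError(f"negative values in a matrix tagged units={self.units}")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def annotation(self, key: str) -> pd.Series:
        if key not in self.column_annotation.columns:
            raise DataError(f"column annotation has no field {key!r}")
        return self.column_annotation[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    def subset_columns(self, mask_or_ids) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, (pd.Index, list, tuple)):
            idx = self.column_ids.get_indexer(pd.Index(mask_or_ids))
            if np.any(idx < 0):
                raise DataError("unknown column ids in subset request")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            self.column_ids[idx],
            self.column_annotation.iloc[idx],
            units=self.units,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise DataError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[idx],
            self.gene_ids[idx],
            self.column_ids,
            self.column_annotation,
            units=self.units,
        )

    def with_values(self, values: np.ndarray, units: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values,
            self.gene_ids,
            self.column_ids,
            self.column_annotation,
            units=self.units if units is None else units,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.gene_ids.copy(),
            self.column_ids.copy(),
            self.column_annotation.copy(),
            units=self.units,
        )


@dataclass
class PathwayCollection:
    """Named gene sets with category labels.

    ``pathways`` preserves file order; gene lists are de-duplicated within a
    pathway but a gene may belong to several pathways — its *multiplicity*
    (number of containing pathways) supplies the 1/multiplicity weights used
    by pathway activity scoring.
    """

    pathways: dict[str, list[str]]
    category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise DataError(f"pathway {name!r} is empty")
            deduped = list(dict.fromkeys(genes))
            self.pathways[name] = deduped
        for name in self.pathways:
            self.category.setdefault(name, "uncategorized")

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    @property
    def universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.pathways.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    def multiplicity(self) -> dict[str, int]:
        mult: dict[str, int] = {}
        for genes in self.pathways.values():
            for g in genes:
                mult[g] = mult.get(g, 0) + 1
        return mult

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> list[str]:
        return self.pathways[name]

    def subset(self, names: Iterable[str]) -> "PathwayCollection":
        names = list(names)
        return PathwayCollection(
            {n: list(self.pathways[n]) for n in names},
            {n: self.category[n] for n in names},
        )

    def restricted_to(self, genes: Iterable[str], min_genes: int = 1) -> "PathwayCollection":
        """Drop unmeasured genes from every pathway; drop pathways that fall
        below ``min_genes`` members (logged, never silently zero-scored)."""
        keep = set(genes)
        out: dict[str, list[str]] = {}
        for name, members in self.pathways.items():
            measured = [g for g in members if g in keep]
            dropped = len(members) - len(measured)
            if dropped:
                logger.info("pathway %s: %d unmeasured gene(s) dropped", name, dropped)
            if len(measured) >= min_genes:
                out[name] = measured
            else:
                logger.warning(
                    "pathway %s dropped: %d measured gene(s) < %d",
                    name, len(measured), min_genes,
                )
        return PathwayCollection(out, {n: self.category[n] for n in out})


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: one gene set per line, ``name<TAB>description<TAB>genes...``.

    The description field becomes the pathway category when it matches one of
    the eleven KEGG metabolic classes (case-insensitive), else
    ``"uncategorized"``.
    """
    path = Path(path)
    class_lookup = {c.lower(): c for c in KEGG_METABOLIC_CLASSES}
    pathways: dict[str, list[str]] = {}
    category: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in pathways:
                raise DataError(f"{path.name}:{lineno}: duplicate pathway name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise DataError(f"{path.name}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = list(dict.fromkeys(genes))
            category[name] = class_lookup.get(desc.strip().lower(), "uncategorized")
    return PathwayCollection(pathways, category)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.pathways.items():
            desc = collection.category.get(name, "uncategorized")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``gene_id<TAB>length`` into a Series (bases)."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"])
    lengths = pd.Series(tab["length"].values, index=pd.Index(tab["gene_id"], dtype=object))
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise DataError(f"non-positive gene lengths for: {bad[:5]}")
    return lengths.astype(float)


def read_expression(
    matrix_path: str | Path,
    fmt: str,
    annotation_path: str | Path | None = None,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    units: str = "counts",
) -> ExpressionMatrix:
    """Read an expression matrix from MTX (+ genes/barcodes sidecars) or CSV.

    CSV layout: genes on rows (first column = gene id), columns = cell/sample
    ids. The optional annotation TSV must be indexed by column id and cover
    every column of the matrix.
    """
    matrix_path = Path(matrix_path)
    if fmt == "mtx":
        if genes_path is None or barcodes_path is None:
            raise ConfigError("mtx format requires genes_path and barcodes_path")
        values = scipy.io.mmread(matrix_path)
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0]
        if values.shape != (len(genes), len(barcodes)):
            raise DataError(
                f"matrix is {values.shape}, sidecars give "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        gene_ids, column_ids = pd.Index(genes, dtype=object), pd.Index(barcodes, dtype=object)
    elif fmt == "csv":
        frame = pd.read_csv(matrix_path, index_col=0)
        values = frame.values
        gene_ids = pd.Index(frame.index.astype(str), dtype=object)
        column_ids = pd.Index(frame.columns.astype(str), dtype=object)
    else:
        raise ConfigError(f"unknown expression format {fmt!r} (expected mtx or csv)")

    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
        annotation.index = annotation.index.astype(str)
        missing = column_ids.difference(annotation.index)
        if len(missing):
            raise DataError(f"annotation missing for columns: {missing.tolist()[:10]}")
        annotation = annotation.loc[column_ids]
    return ExpressionMatrix(values, gene_ids, column_ids, annotation, units=units)


def write_expression_mtx(expr: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` +
    ``cell_metadata.tsv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(expr.values)
    scipy.io.mmwrite(out_dir / "matrix.mtx", sparse)
    pd.Series(expr.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(expr.column_ids).to_csv(
        out_dir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    expr.column_annotation.to_csv(out_dir / "cell_metadata.tsv", sep="\t")


def write_expression_csv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path)


def counts_to_tpm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Length-normalize counts to transcripts-per-million.

    Per column: ``rate_g = count_g / length_g``; ``TPM_g = rate_g / sum(rate)
    * 1e6``. All-zero columns stay all-zero. Every gene must have a length.
    """
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise DataError(f"genes without length information: {missing.tolist()[:10]}")
    lens = lengths.loc[counts.gene_ids].values.astype(float)
    rate = counts.values / lens[:, None]
    colsum = rate.sum(axis=0)
    safe = np.where(colsum > 0, colsum, 1.0)
    tpm = rate / safe[None, :] * 1e6
    return counts.with_values(tpm, units="TPM")


def to_anndata(expr: ExpressionMatrix):
    """Cells-as-observations AnnData view of the matrix (transposed)."""
    import anndata

    return anndata.AnnData(
        X=expr.values.T.copy(),
        obs=expr.column_annotation.copy(),
        var=pd.DataFrame(index=expr.gene_ids),
    )
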