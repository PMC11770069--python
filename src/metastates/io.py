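"""Loading, validation and on-disk formats.

Expression matrices are stored gene-by-column (columns are cells for
single-cell data or samples for bulk data), either dense or sparse.
Supported formats: the 10x MTX triplet (matrix.mtx[.gz] plus
features/genes.tsv and barcodes.tsv) and dense TSV with genes in rows.
Gene sets travel as standard GMT; annotations and survival tables as TSV.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "load_expression",
    "write_dense_tsv",
    "write_mtx_10x",
    "filter_cells",
    "read_gmt",
    "write_gmt",
    "load_annotations",
    "load_survival",
]

LAYERS = ("counts", "normalized", "residuals")


def _canonical(genes: Iterable[str]) -> list[str]:
    """Trim whitespace; case-preserving exact symbols (no alias mapping)."""
    return [str(g).strip() for g in genes]


@dataclass
class ExpressionMatrix:
    """Gene-by-column expression matrix with a layer tag.

    Parameters
    ----------
    genes : sequence of str
        Unique gene symbols (rows).
    columns : sequence of str
        Cell barcodes or sample identifiers.
    values : ndarray or sparse matrix, shape (n_genes, n_columns)
    layer : {"counts", "normalized", "residuals"}
        Units of ``values``. The counts layer must be non-negative and
        integer-valued.
    """

    genes: list[str]
    columns: list[str]
    values: np.ndarray | sp.spmatrix
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.genes = _canonical(self.genes)
        self.columns = [str(c) for c in self.columns]
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.columns)} columns"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols; collapse before construction")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column identifiers")
        if self.layer == "counts":
            data = self.values.data if sp.issparse(self.values) else self.values
            if data.size and float(np.min(data)) < 0:
                raise ValueError("counts layer contains negative values")

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.genes, columns=self.columns)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)

    def subset_columns(self, keep: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.columns)}
        idx = [pos[c] for c in keep]
        vals = self.values[:, idx] if not sp.issparse(self.values) else self.values.tocsc()[:, idx].tocsr()
        return ExpressionMatrix(list(self.genes), list(keep), vals, self.layer)

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in keep]
        vals = self.values[idx, :] if not sp.issparse(self.values) else self.values.tocsr()[idx, :]
        return ExpressionMatrix(list(keep), list(self.columns), vals, self.layer)

    def column_sums(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def genes_detected_per_column(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray((self.values > 0).sum(axis=0)).ravel()
        return (self.values > 0).sum(axis=0)


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def _collapse_duplicates(genes: list[str], values, layer: str):
    """Collapse duplicate gene rows: sum for counts, mean otherwise."""
    idx = pd.Index(genes)
    if idx.is_unique:
        return genes, values
    dense = np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values)
    df = pd.DataFrame(dense)
    df.insert(0, "_gene", genes)
    how = "sum" if layer == "counts" else "mean"
    collapsed = df.groupby("_gene", sort=False).agg(how)
    dup = idx[idx.duplicated()].unique().tolist()
    warnings.warn(
        f"collapsed {len(dup)} duplicated gene symbol(s) by {how}: "
        + ", ".join(map(str, dup[:10])),
        stacklevel=3,
    )
    return collapsed.index.tolist(), collapsed.to_numpy()


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find_10x_files(d: Path) -> tuple[Path, Path, Path]:
    def pick(names):
        for n in names:
            p = d / n
            if p.exists():
                return p
        raise FileNotFoundError(f"none of {names} found in {d}")

    matrix = pick(["matrix.mtx", "matrix.mtx.gz"])
    features = pick(["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"])
    barcodes = pick(["barcodes.tsv", "barcodes.tsv.gz"])
    return matrix, features, barcodes


def load_expression(path: str | Path, format: str = "dense_tsv") -> ExpressionMatrix:
    """Load an expression matrix as a validated counts layer.

    ``format="mtx_10x"`` expects ``path`` to be a directory with the 10x
    triplet; ``format="dense_tsv"`` a genes-in-rows TSV with a header of
    column ids. Duplicate gene symbols are collapsed by summation with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "mtx_10x":
        mtx_p, feat_p, bc_p = _find_10x_files(path)
        mat = sp.csr_matrix(scipy.io.mmread(str(mtx_p)))
        with _open_maybe_gz(feat_p) as fh:
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        genes = [r[1] if len(r) > 1 else r[0] for r in rows]
        with _open_maybe_gz(bc_p) as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"features file lists {len(genes)} genes but matrix has {mat.shape[0]} rows"
            )
        if mat.shape[1] != len(barcodes):
            raise ValueError(
                f"barcodes file lists {len(barcodes)} cells but matrix has {mat.shape[1]} columns"
            )
        genes = _canonical(genes)
        genes, values = _collapse_duplicates(genes, mat, "counts")
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = _canonical(df.index)
        barcodes = [str(c) for c in df.columns]
        genes, values = _collapse_duplicates(genes, df.to_numpy(), "counts")
    else:
        raise ValueError(f"unknown format {format!r}")
    values = np.asarray(values) if not sp.issparse(values) else values
    # sparse storage when density < 50%
    dense = np.asarray(values.todense()) if sp.issparse(values) else values
    density = np.count_nonzero(dense) / max(dense.size, 1)
    stored = sp.csr_matrix(dense) if density < 0.5 else dense
    return ExpressionMatrix(genes, barcodes, stored, layer="counts")


def write_dense_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_frame()
    if m.layer == "counts":
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t")


def write_mtx_10x(m: ExpressionMatrix, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(m.values)
    scipy.io.mmwrite(str(d / "matrix.mtx"), mat, field="integer" if m.layer == "counts" else "real")
    with open(d / "features.tsv", "w") as fh:
        for g in m.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(d / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(m.columns) + "\n")


def filter_cells(m: ExpressionMatrix, min_genes: int = 500, min_counts: int = 1000) -> ExpressionMatrix:
    """Exclude low-quality cells (detected genes < ``min_genes`` or total
    counts < ``min_counts``); boundary values are kept. Idempotent."""
    if m.layer != "counts":
        raise ValueError("filter_cells requires the counts layer")
    n_genes = m.genes_detected_per_column()
    n_counts = m.column_sums()
    keep = (n_genes >= min_genes) & (n_counts >= min_counts)
    if not keep.any():
        raise ValueError(
            f"no cells pass QC (min_genes={min_genes}, min_counts={min_counts})"
        )
    if keep.all():
        return m
    kept = [c for c, k in zip(m.columns, keep) if k]
    return m.subset_columns(kept)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{ln}: set {name!r} has no genes")
            sets[name] = _canonical(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def load_annotations(
    path: str | Path,
    matrix: ExpressionMatrix | None = None,
    vocabulary: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell annotation TSV with columns cell_id, sample_id, cell_type
    (optional dataset_id). Validated against a companion matrix when given."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "sample_id", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if matrix is not None:
        unknown = set(df["cell_id"]) - set(matrix.columns)
        if unknown:
            raise ValueError(
                f"{len(unknown)} annotated cell_id(s) absent from matrix, e.g. "
                + next(iter(unknown))
            )
    if vocabulary is not None:
        bad = set(df["cell_type"]) - set(vocabulary)
        if bad:
            raise ValueError(f"cell_type values outside vocabulary: {sorted(bad)}")
    return df


def load_survival(path: str | Path) -> pd.DataFrame:
    """Survival TSV: sample_id, time, event, then covariate columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"])
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df
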