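"""Count-matrix container and plain-text readers/writers.

The central container is :class:`CountMatrix`: integer UMI (or bulk read)
counts laid out genes x columns, where a column is a cell (single-cell data)
or a sample (bulk data).  Matrices travel on disk either as MatrixMarket
sparse triplets with gene/barcode TSV sidecars (the droplet-pipeline
convention) or as a single dense TSV.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("dmhseq")

#: column-label fields every CountMatrix carries
REQUIRED_LABELS = ("sample", "condition")


@dataclasses.dataclass
class CountMatrix:
    """Non-negative integer counts, genes x columns, with aligned identifiers.

    Parameters
    ----------
    values
        Sparse or dense matrix of shape ``(n_genes, n_columns)``; coerced to
        CSR.  Entries must be non-negative.
    gene_ids
        Unique gene identifiers, length ``n_genes``.
    column_ids
        Unique cell barcodes or sample names, length ``n_columns``.
    column_labels
        DataFrame indexed by ``column_ids`` with at least ``sample`` and
        ``condition`` columns.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    column_ids: np.ndarray
    column_labels: pd.DataFrame

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.column_ids = np.asarray(self.column_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("column_ids are not unique")
        if not isinstance(self.column_labels, pd.DataFrame):
            self.column_labels = pd.DataFrame(self.column_labels)
        missing = [c for c in REQUIRED_LABELS if c not in self.column_labels.columns]
        if missing:
            raise ValueError(f"column_labels missing fields: {missing}")
        if not np.array_equal(
            self.column_labels.index.to_numpy(dtype=object), self.column_ids
        ):
            raise ValueError("column_labels index does not align with column_ids")

    # ------------------------------------------------------------------ shape
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    # --------------------------------------------------------------- summaries
    def column_totals(self) -> np.ndarray:
        """Total counts per column (library size)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Row indices of ``gene_ids``; missing genes raise KeyError."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view (genes x columns); for small matrices only."""
        return pd.DataFrame(
            self.values.toarray(), index=self.gene_ids, columns=self.column_ids
        )

    # ---------------------------------------------------------------- subsets
    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.values[keep],
            self.gene_ids[keep],
            self.column_ids,
            self.column_labels,
        )

    def subset_columns(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.values[:, keep],
            self.gene_ids,
            self.column_ids[keep],
            self.column_labels.iloc[keep],
        )

    # ----------------------------------------------------------------- concat
    @classmethod
    def concat(cls, matrices: Sequence["CountMatrix"]) -> "CountMatrix":
        """Column-wise merge of per-sample matrices sharing one gene universe."""
        if not matrices:
            raise ValueError("nothing to concatenate")
        first = matrices[0]
        for m in matrices[1:]:
            if not np.array_equal(m.gene_ids, first.gene_ids):
                raise ValueError("gene identifiers differ between matrices")
        return cls(
            sp.hstack([m.values for m in matrices]).tocsr(),
            first.gene_ids,
            np.concatenate([m.column_ids for m in matrices]),
            pd.concat([m.column_labels for m in matrices]),
        )


# ---------------------------------------------------------------------- disk
def write_count_matrix(m: CountMatrix, directory: str | Path, fmt: str = "mtx") -> None:
    """Write ``matrix.mtx + genes.tsv + barcodes.tsv`` or a dense TSV pair."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = m.column_labels.reset_index(names="column_id")
    if fmt == "mtx":
        mmwrite(str(directory / "matrix.mtx"), m.values.tocoo(), field="integer")
        pd.Series(m.gene_ids, name="gene_id").to_csv(
            directory / "genes.tsv", sep="\t", index=False
        )
        labels.to_csv(directory / "barcodes.tsv", sep="\t", index=False)
    elif fmt == "tsv":
        m.to_frame().rename_axis("gene_id").to_csv(directory / "counts.tsv", sep="\t")
        labels.to_csv(directory / "columns.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'mtx' or 'tsv'")


def read_count_matrix(directory: str | Path, fmt: str = "mtx") -> CountMatrix:
    directory = Path(directory)
    if fmt == "mtx":
        values = sp.csr_matrix(mmread(directory / "matrix.mtx")).astype(np.int64)
        genes = pd.read_csv(directory / "genes.tsv", sep="\t")["gene_id"].to_numpy()
        labels = pd.read_csv(directory / "barcodes.tsv", sep="\t").set_index("column_id")
    elif fmt == "tsv":
        frame = pd.read_csv(directory / "counts.tsv", sep="\t", index_col="gene_id")
        values = sp.csr_matrix(frame.to_numpy(dtype=np.int64))
        genes = frame.index.to_numpy()
        labels = pd.read_csv(directory / "columns.tsv", sep="\t").set_index("column_id")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'mtx' or 'tsv'")
    return CountMatrix(values, genes, labels.index.to_numpy(), labels)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (sample_id, condition, n_cells)."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "n_cells"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    if (meta["n_cells"] < 0).any():
        raise ValueError("n_cells must be non-negative")
    return meta


def total_cell_count(metadata: pd.DataFrame) -> int:
    """Total cell count across per-sample records of a merged experiment."""
    return int(metadata["n_cells"].sum())
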