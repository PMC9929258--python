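"""Cell- and gene-level quality filtering.

Filtering order is fixed: cells first (UMI floor and mitochondrial-fraction
ceiling), then genes (minimum count in a minimum number of cells).
Boundary semantics follow the filtering rules literally: a cell with fewer
than ``min_umi`` total UMIs is discarded (strict), a cell with a
mitochondrial fraction strictly above ``max_mito`` is discarded (a fraction
exactly at the ceiling is retained), and a gene is kept when at least
``gene_min_count`` counts occur in each of at least ``gene_min_cells``
cells (inclusive).
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("dmhseq")


@dataclasses.dataclass
class QCThresholds:
    """Filter thresholds; defaults are the pipeline's standard values."""

    min_umi: int = 500
    max_mito: float = 0.40
    gene_min_count: int = 2
    gene_min_cells: int = 5

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) < 0:
                raise ValueError(f"{field.name} must be non-negative")


def mito_genes(gene_ids: Iterable[str], prefix: str = "mt-") -> set[str]:
    """Mitochondrial gene identifiers by the conventional ``mt-`` prefix."""
    return {g for g in gene_ids if str(g).startswith(prefix)}


def compute_cell_qc(
    m: CountMatrix,
    mito_gene_ids: Iterable[str] | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-cell QC table: total UMIs, mitochondrial fraction, pass flag.

    The mitochondrial fraction is mito UMIs / total UMIs, defined as 0 for a
    zero-total cell (which necessarily fails).  ``m`` is not modified.
    """
    if m.n_genes == 0 or m.n_columns == 0:
        raise ValueError("cannot compute QC on an empty matrix")
    thresholds = thresholds or QCThresholds()
    if mito_gene_ids is None:
        mito_gene_ids = mito_genes(m.gene_ids)
    mito_gene_ids = set(mito_gene_ids)
    missing = mito_gene_ids - set(m.gene_ids)
    if missing:
        logger.warning("mito genes not in matrix: %s", sorted(missing))
    present = sorted(mito_gene_ids & set(m.gene_ids))

    totals = m.column_totals()
    if present:
        mito_counts = np.asarray(
            m.values[m.gene_index(present)].sum(axis=0)
        ).ravel()
    else:
        mito_counts = np.zeros_like(totals, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    passed = (totals >= thresholds.min_umi) & (frac <= thresholds.max_mito)
    passed &= totals > 0
    return pd.DataFrame(
        {"total_umis": totals.astype(int), "mito_fraction": frac, "passed": passed},
        index=pd.Index(m.column_ids, name="column_id"),
    )


def filter_cells(
    m: CountMatrix, qc: pd.DataFrame, thresholds: QCThresholds | None = None
) -> CountMatrix:
    """Drop cells below the UMI floor or above the mitochondrial ceiling."""
    thresholds = thresholds or QCThresholds()
    if len(qc) != m.n_columns or not np.array_equal(
        qc.index.to_numpy(dtype=object), m.column_ids
    ):
        raise ValueError("QC table is not aligned with the matrix columns")
    low_umi = qc["total_umis"].to_numpy() < thresholds.min_umi
    high_mito = qc["mito_fraction"].to_numpy() > thresholds.max_mito
    keep = ~(low_umi | high_mito)
    logger.info(
        "cell QC: %d low-UMI, %d high-mito, %d of %d retained",
        int(low_umi.sum()), int(high_mito.sum()), int(keep.sum()), m.n_columns,
    )
    if not keep.any():
        raise ValueError(
            "all cells removed by QC; review min_umi/max_mito thresholds"
        )
    return m.subset_columns(keep)


def filter_genes(
    m: CountMatrix, thresholds: QCThresholds | None = None
) -> CountMatrix:
    """Keep genes with >= gene_min_count counts in >= gene_min_cells cells."""
    thresholds = thresholds or QCThresholds()
    expressing = np.asarray(
        (m.values >= thresholds.gene_min_count).sum(axis=1)
    ).ravel()
    keep = expressing >= thresholds.gene_min_cells
    logger.info("gene QC: %d of %d genes retained", int(keep.sum()), m.n_genes)
    if not keep.any():
        raise ValueError("no genes retained; review gene filter thresholds")
    return m.subset_genes(keep)
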