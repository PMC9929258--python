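"""Median-total normalization and binned-dispersion variable-gene selection.

Each cell is scaled by its total transcript count, multiplied by the median
total across cells, and log2-transformed after adding a pseudocount:

    v[g, c] = log2(count[g, c] / total[c] * median_total + pseudocount)

Highly variable genes are ranked on the linearized normalized scale: the
per-gene dispersion (variance / mean) is standardized within equal-frequency
mean-expression bins against the bin's median dispersion (robust z using the
median absolute deviation), and the top ``n_top`` genes by bin-scaled
dispersion are selected.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("dmhseq")


@dataclasses.dataclass
class NormMatrix:
    """Log2-scale normalized expression (genes x cells) with provenance."""

    values: np.ndarray
    gene_ids: np.ndarray
    column_ids: np.ndarray
    column_labels: pd.DataFrame
    pseudocount: float
    median_total: float

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.column_ids)

    def linear(self) -> np.ndarray:
        """Linear-scale normalized expression, 2**v - pseudocount."""
        return np.power(2.0, self.values) - self.pseudocount

    def subset_columns(self, keep: np.ndarray) -> "NormMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return NormMatrix(
            self.values[:, keep],
            self.gene_ids,
            self.column_ids[keep],
            self.column_labels.iloc[keep],
            self.pseudocount,
            self.median_total,
        )


@dataclasses.dataclass
class HVGRecord:
    """Per-gene variability statistics and the selection decision."""

    gene_id: str
    mean: float
    dispersion: float
    bin: int
    scaled_dispersion: float
    selected: bool


def median_scale_normalize(m: CountMatrix, pseudocount: float = 1.0) -> NormMatrix:
    """Normalize to the median cell total and log2-transform.

    After linearization every cell's per-gene values sum to the median total
    (scaling conserves each cell's mass).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    totals = m.column_totals().astype(float)
    if (totals <= 0).any():
        raise ValueError(
            "zero-total cell encountered; apply cell QC before normalization"
        )
    median_total = float(np.median(totals))
    scaled = m.values.multiply(median_total / totals[None, :]).toarray()
    values = np.log2(scaled + pseudocount)
    return NormMatrix(
        values,
        m.gene_ids.copy(),
        m.column_ids.copy(),
        m.column_labels.copy(),
        pseudocount,
        median_total,
    )


def select_hvg(
    nm: NormMatrix, n_top: int = 1000, n_bins: int = 50
) -> list[HVGRecord]:
    """Select the most variable genes by bin-standardized dispersion.

    Genes are ordered by linear-scale mean (ties broken by gene id) and cut
    into ``n_bins`` equal-frequency bins; within each bin the dispersion is
    centered on the bin median and scaled by the bin MAD.  A bin with MAD 0
    contributes scaled dispersion 0 (logged).  Ties in the final ranking are
    broken lexicographically by gene id.
    """
    G = nm.n_genes
    if G < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes, have {G}")
    linear = nm.linear()
    mean = linear.mean(axis=1)
    var = linear.var(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    # equal-frequency binning on (mean, gene_id); permutation-invariant
    order = np.lexsort((nm.gene_ids.astype(str), mean))
    bins = np.empty(G, dtype=int)
    bins[order] = np.arange(G) * n_bins // G

    scaled = np.zeros(G)
    for b in range(n_bins):
        members = bins == b
        d = dispersion[members]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        if mad == 0:
            logger.info("HVG bin %d has zero dispersion MAD; scaled to 0", b)
            scaled[members] = 0.0
        else:
            scaled[members] = (d - med) / mad

    rank_order = np.lexsort((nm.gene_ids.astype(str), -scaled))
    selected = np.zeros(G, dtype=bool)
    selected[rank_order[: min(n_top, G)]] = True

    return [
        HVGRecord(
            gene_id=str(nm.gene_ids[i]),
            mean=float(mean[i]),
            dispersion=float(dispersion[i]),
            bin=int(bins[i]),
            scaled_dispersion=float(scaled[i]),
            selected=bool(selected[i]),
        )
        for i in range(G)
    ]


def hvg_frame(records: list[HVGRecord]) -> pd.DataFrame:
    """HVG records as a DataFrame (the TSV-facing representation)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def selected_gene_ids(records: list[HVGRecord]) -> list[str]:
    return [r.gene_id for r in records if r.selected]
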