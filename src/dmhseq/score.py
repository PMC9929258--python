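"""Gene-set scoring, score correlation, and over-representation tests.

A pathway score is the unweighted mean normalized expression of a set's
genes per unit (cell, or cluster as the mean of its cells' scores).  Two
score vectors are compared by Pearson correlation (Spearman behind a flag).
Over-representation of a query gene list in named sets uses the upper-tail
hypergeometric test with BH adjustment across sets.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr, spearmanr

from .cluster import ClusterLabels
from .dge import bh_adjust
from .normalize import NormMatrix

logger = logging.getLogger("dmhseq")


@dataclasses.dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read named sets from a two-column TSV (set_name, gene_id)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"set_name", "gene_id"} <= set(frame.columns):
        raise ValueError("gene set file needs set_name and gene_id columns")
    return [
        GeneSet(name, frozenset(group["gene_id"]))
        for name, group in frame.groupby("set_name", sort=True)
    ]


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    rows = [(s.name, g) for s in sets for g in sorted(s.genes)]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def pathway_score(
    nm: NormMatrix,
    gene_set: GeneSet,
    unit: str = "cell",
    labels: ClusterLabels | None = None,
) -> pd.Series:
    """Mean normalized expression of the set's genes per cell or cluster."""
    present = [g for g in sorted(gene_set.genes) if g in set(nm.gene_ids)]
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in matrix")
    dropped = len(gene_set.genes) - len(present)
    if dropped:
        logger.warning("set %s: %d genes absent from matrix",
                       gene_set.name, dropped)
    pos = {g: i for i, g in enumerate(nm.gene_ids)}
    rows = np.array([pos[g] for g in present])
    per_cell = nm.values[rows].mean(axis=0)
    if unit == "cell":
        return pd.Series(per_cell, index=nm.column_ids, name=gene_set.name)
    if unit == "cluster":
        if labels is None:
            raise ValueError("cluster unit requires cluster labels")
        if not np.array_equal(labels.column_ids, nm.column_ids):
            raise ValueError("labels are not aligned with the matrix")
        vals = [
            float(per_cell[labels.labels == c].mean())
            for c in range(labels.n_clusters)
        ]
        return pd.Series(vals, index=range(labels.n_clusters),
                         name=gene_set.name)
    raise ValueError("unit must be 'cell' or 'cluster'")


def score_correlation(
    a: Sequence[float], b: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between two paired score vectors: (r, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least 3 paired units")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate score vector (zero variance)")
    if method == "pearson":
        res = pearsonr(a, b)
    elif method == "spearman":
        res = spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


def hypergeom_enrichment(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Query genes outside the universe are dropped with a warning; set genes
    are intersected with the universe.  P-values are BH-adjusted across the
    supplied sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside universe dropped", len(outside))
        query &= universe

    rows = []
    for s in sets:
        members = s.genes & universe
        overlap = len(query & members)
        # P(X >= overlap) with M=|universe|, n=|set|, N=|query|
        p = float(hypergeom.sf(overlap - 1, len(universe), len(members),
                               len(query)))
        rows.append(
            {
                "set_name": s.name,
                "universe_size": len(universe),
                "set_size": len(members),
                "query_size": len(query),
                "overlap": overlap,
                "p_value": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
    return frame
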