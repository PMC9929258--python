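"""2-D embedding and density-based clustering of cells.

The selected variable genes are standardized (zero mean, unit variance per
gene) and embedded with Barnes-Hut t-SNE.  Clusters are then found in the
2-D map by a deterministic density procedure: core points (those with at
least ``min_samples`` neighbours within ``eps``) are linked into connected
components, and every remaining point is assigned to the nearest cluster
centroid so that all cells carry a label.  The procedure is invariant to
cell order up to label renaming; labels are renumbered by descending
cluster size.

When ``eps`` is not given it is set to a quantile of the distribution of
``min_samples``-th nearest-neighbour distances, which adapts the density
scale to the map without manual tuning.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .normalize import NormMatrix, HVGRecord, select_hvg, selected_gene_ids

logger = logging.getLogger("dmhseq")


@dataclasses.dataclass
class Embedding2D:
    """t-SNE coordinates with the parameters that produced them."""

    coords: np.ndarray  # (n_cells, 2)
    column_ids: np.ndarray
    perplexity: float
    seed: int


@dataclasses.dataclass
class ClusterLabels:
    """Per-cell cluster assignment; ids contiguous from 0."""

    labels: np.ndarray
    column_ids: np.ndarray
    round: str  # "all-cells" or "neurons-only"
    params: dict

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def standardized_hvg_matrix(nm: NormMatrix, hvg: list[HVGRecord]) -> np.ndarray:
    """Cells x selected-genes matrix, each gene zero-mean unit-variance."""
    genes = selected_gene_ids(hvg)
    if not genes:
        raise ValueError("no genes selected")
    idx = {g: i for i, g in enumerate(nm.gene_ids)}
    rows = np.array([idx[g] for g in genes])
    X = nm.values[rows].T.astype(np.float64).copy()
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    return X


def embed(
    nm: NormMatrix,
    hvg: list[HVGRecord],
    perplexity: float = 30.0,
    seed: int = 0,
) -> Embedding2D:
    """Barnes-Hut t-SNE of the standardized variable-gene expression."""
    n = nm.n_cells
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity}; lower perplexity"
        )
    X = standardized_hvg_matrix(nm, hvg)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="barnes_hut",
        init="pca",
        random_state=seed,
    )
    coords = np.asarray(tsne.fit_transform(X), dtype=np.float64)
    return Embedding2D(coords, nm.column_ids.copy(), float(perplexity), int(seed))


def _adaptive_eps(coords: np.ndarray, min_samples: int, quantile: float) -> float:
    k = min(min_samples, len(coords) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return float(np.quantile(dist[:, -1], quantile))


def cluster_embedding(
    e: Embedding2D,
    eps: float | None = None,
    min_samples: int = 10,
    eps_quantile: float = 0.90,
    round: str = "all-cells",
) -> ClusterLabels:
    """Deterministic density clustering in the 2-D map.

    Core points within ``eps`` of each other are merged; non-core points are
    assigned to the nearest cluster centroid so every cell is labeled.
    """
    coords = e.coords
    n = len(coords)
    if n == 0:
        raise ValueError("empty embedding")
    if np.allclose(coords, coords[0]):
        logger.warning("degenerate embedding (all points identical); one cluster")
        return ClusterLabels(
            np.zeros(n, dtype=int), e.column_ids.copy(), round,
            {"eps": eps, "min_samples": min_samples},
        )
    if eps is None:
        eps = _adaptive_eps(coords, min_samples, eps_quantile)

    nn = NearestNeighbors(radius=eps).fit(coords)
    graph = nn.radius_neighbors_graph(coords, mode="connectivity")
    # neighbour count includes the point itself
    core = np.asarray(graph.sum(axis=1)).ravel() >= min_samples
    if not core.any():
        logger.warning("no dense region at eps=%.3g; single cluster", eps)
        return ClusterLabels(
            np.zeros(n, dtype=int), e.column_ids.copy(), round,
            {"eps": eps, "min_samples": min_samples},
        )
    core_idx = np.flatnonzero(core)
    sub = graph[core_idx][:, core_idx]
    n_comp, comp = connected_components(sp.csr_matrix(sub), directed=False)

    labels = np.full(n, -1, dtype=int)
    labels[core_idx] = comp
    centroids = np.vstack(
        [coords[core_idx[comp == c]].mean(axis=0) for c in range(n_comp)]
    )
    loose = labels < 0
    if loose.any():
        d = np.linalg.norm(coords[loose, None, :] - centroids[None, :, :], axis=2)
        labels[loose] = d.argmin(axis=1)

    # renumber by descending size, ties by centroid coordinates
    sizes = np.bincount(labels, minlength=n_comp)
    order = sorted(
        range(n_comp),
        key=lambda c: (-sizes[c], centroids[c, 0], centroids[c, 1]),
    )
    remap = np.empty(n_comp, dtype=int)
    remap[order] = np.arange(n_comp)
    labels = remap[labels]
    logger.info("density clustering: %d clusters at eps=%.3g", n_comp, eps)
    return ClusterLabels(
        labels, e.column_ids.copy(), round,
        {"eps": float(eps), "min_samples": int(min_samples)},
    )


def iterative_subcluster(
    nm: NormMatrix,
    labels: ClusterLabels,
    subset: np.ndarray | Callable[[ClusterLabels], np.ndarray],
    *,
    n_top: int = 1000,
    n_bins: int = 50,
    perplexity: float = 30.0,
    eps: float | None = None,
    min_samples: int = 10,
    seed: int = 0,
    round: str = "neurons-only",
) -> tuple[list[HVGRecord], Embedding2D, ClusterLabels]:
    """Re-run variable-gene selection, embedding and clustering on a subset.

    ``subset`` is a boolean mask over cells or a predicate applied to the
    current labels.  Selecting all cells reproduces a fresh full run with
    the same seed.
    """
    mask = subset(labels) if callable(subset) else np.asarray(subset, dtype=bool)
    if mask.shape != (nm.n_cells,):
        raise ValueError("subset mask does not match the cell count")
    n_sub = int(mask.sum())
    if n_sub == 0:
        raise ValueError("subset predicate selects no cells")
    if n_sub <= 3 * perplexity:
        raise ValueError(
            f"subset of {n_sub} cells is too small for perplexity {perplexity}"
        )
    sub_nm = nm.subset_columns(mask)
    hvg = select_hvg(sub_nm, n_top=min(n_top, sub_nm.n_genes), n_bins=n_bins)
    e = embed(sub_nm, hvg, perplexity=perplexity, seed=seed)
    cl = cluster_embedding(e, eps=eps, min_samples=min_samples, round=round)
    return hvg, e, cl
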