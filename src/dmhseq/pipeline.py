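"""End-to-end single-cell pipeline: QC -> normalize -> HVG -> embed ->
cluster -> annotate -> neurons-only re-clustering -> dichotomy.

``run_pipeline`` wires the module operations together in the fixed order
the analysis prescribes and returns a :class:`PipelineResult` holding every
intermediate product plus a per-cell annotation table.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import classify, cluster, normalize, qc
from .classify import ClusterProfile, MarkerPanel
from .cluster import ClusterLabels, Embedding2D
from .io import CountMatrix
from .normalize import HVGRecord, NormMatrix


@dataclasses.dataclass
class PipelineResult:
    """All products of one pipeline run."""

    cell_qc: pd.DataFrame
    filtered: CountMatrix
    norm: NormMatrix
    hvg: list[HVGRecord]
    embedding: Embedding2D
    clusters: ClusterLabels
    profiles: list[ClusterProfile]
    neuron_cells: np.ndarray  # boolean over filtered cells
    neuron_hvg: list[HVGRecord] | None
    neuron_embedding: Embedding2D | None
    neuron_clusters: ClusterLabels | None
    neuron_profiles: list[ClusterProfile] | None
    cell_annotations: pd.DataFrame
    params: dict

    def final_partition(self) -> np.ndarray:
        """One label per retained cell: round-1 cluster for non-neurons,
        round-2 neuron subcluster (offset) for neurons."""
        labels = self.clusters.labels.copy()
        if self.neuron_clusters is not None:
            offset = self.clusters.n_clusters
            labels[self.neuron_cells] = offset + self.neuron_clusters.labels
        return labels


def run_pipeline(
    m: CountMatrix,
    *,
    mito_gene_ids=None,
    panel: MarkerPanel | None = None,
    thresholds: qc.QCThresholds | None = None,
    pseudocount: float = 1.0,
    n_top: int = 1000,
    n_bins: int = 50,
    perplexity: float = 30.0,
    eps: float | None = None,
    min_samples: int = 10,
    seed: int = 0,
) -> PipelineResult:
    panel = panel or MarkerPanel()
    thresholds = thresholds or qc.QCThresholds()

    cell_qc = qc.compute_cell_qc(m, mito_gene_ids, thresholds)
    filtered = qc.filter_cells(m, cell_qc, thresholds)
    filtered = qc.filter_genes(filtered, thresholds)

    nm = normalize.median_scale_normalize(filtered, pseudocount)
    hvg = normalize.select_hvg(nm, n_top=min(n_top, nm.n_genes), n_bins=n_bins)
    embedding = cluster.embed(nm, hvg, perplexity=perplexity, seed=seed)
    clusters = cluster.cluster_embedding(
        embedding, eps=eps, min_samples=min_samples, round="all-cells"
    )

    profiles = classify.aggregate_cluster_medians(nm, clusters, panel)
    profiles = classify.classify_neuron_clusters(profiles, seed=seed)
    profiles = classify.annotate_nonneuronal(profiles, panel)
    neuron_ids = {p.cluster_id for p in profiles if p.neuron}
    neuron_cells = np.isin(clusters.labels, sorted(neuron_ids))

    neuron_hvg = neuron_embedding = neuron_clusters = None
    neuron_profiles = None
    if neuron_cells.sum() > 3 * perplexity:
        neuron_hvg, neuron_embedding, neuron_clusters = cluster.iterative_subcluster(
            nm, clusters, neuron_cells,
            n_top=n_top, n_bins=min(n_bins, nm.n_genes),
            perplexity=perplexity, eps=eps, min_samples=min_samples,
            seed=seed, round="neurons-only",
        )
        sub_nm = nm.subset_columns(neuron_cells)
        neuron_profiles = classify.aggregate_cluster_medians(
            sub_nm, neuron_clusters, panel
        )
        neuron_profiles = classify.classify_neurotransmitter(neuron_profiles, panel)

    annotations = _cell_annotation_table(
        nm, clusters, profiles, neuron_cells, neuron_clusters, neuron_profiles
    )
    params = {
        "seed": seed, "n_top": n_top, "n_bins": n_bins,
        "perplexity": perplexity, "eps": eps, "min_samples": min_samples,
        "pseudocount": pseudocount,
        "thresholds": dataclasses.asdict(thresholds),
    }
    return PipelineResult(
        cell_qc, filtered, nm, hvg, embedding, clusters, profiles,
        neuron_cells, neuron_hvg, neuron_embedding, neuron_clusters,
        neuron_profiles, annotations, params,
    )


def _cell_annotation_table(
    nm: NormMatrix,
    clusters: ClusterLabels,
    profiles: list[ClusterProfile],
    neuron_cells: np.ndarray,
    neuron_clusters: ClusterLabels | None,
    neuron_profiles: list[ClusterProfile] | None,
) -> pd.DataFrame:
    by_id = {p.cluster_id: p for p in profiles}
    neuron = np.array([bool(by_id[c].neuron) for c in clusters.labels])
    cell_type = np.array(
        [by_id[c].cell_type or "" for c in clusters.labels], dtype=object
    )
    sub = np.full(nm.n_cells, -1, dtype=int)
    nt = np.array([""] * nm.n_cells, dtype=object)
    if neuron_clusters is not None and neuron_profiles is not None:
        sub[neuron_cells] = neuron_clusters.labels
        nt_by_id = {p.cluster_id: p.nt_class or "" for p in neuron_profiles}
        nt[neuron_cells] = [nt_by_id[c] for c in neuron_clusters.labels]
    return pd.DataFrame(
        {
            "cluster": clusters.labels,
            "neuron": neuron,
            "cell_type": cell_type,
            "neuron_cluster": sub,
            "nt_class": nt,
            "condition": nm.column_labels["condition"].to_numpy(),
            "sample": nm.column_labels["sample"].to_numpy(),
        },
        index=pd.Index(nm.column_ids, name="cell_id"),
    )
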