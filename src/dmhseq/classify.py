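"""Marker-based cluster annotation.

Three stages mirror the annotation scheme of the pipeline:

1. neuron vs non-neuron — the medians of the neuron markers (Snap25, Syp,
   Tubb3, Elavl2) are aggregated per cluster and a two-component Gaussian
   mixture splits clusters into high (neuronal) and low (non-neuronal)
   score groups; every cell inherits its cluster's call;
2. GABAergic vs glutamatergic — a neuron cluster is GABAergic when its
   median Slc32a1 exceeds its median Slc17a6 and glutamatergic for the
   reverse; an exact tie is left unclassified;
3. non-neuronal cell types — argmax over canonical type-marker medians
   (Agt astrocytes, Flt1 endothelial, Cx3cr1 microglia, Opalin
   oligodendrocytes, Pdgfra OPC, Vtn pericytes, Acta2 vascular smooth
   muscle), with the top-minus-runner-up margin reported.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .cluster import ClusterLabels
from .normalize import NormMatrix

logger = logging.getLogger("dmhseq")


def _default_type_markers() -> dict[str, str]:
    return {
        "astrocytes": "Agt",
        "endothelial": "Flt1",
        "microglia": "Cx3cr1",
        "oligodendrocytes": "Opalin",
        "opc": "Pdgfra",
        "pericytes": "Vtn",
        "vsm": "Acta2",
    }


@dataclasses.dataclass
class MarkerPanel:
    """Canonical marker genes driving the annotation."""

    neuron_markers: tuple[str, ...] = ("Snap25", "Syp", "Tubb3", "Elavl2")
    gaba_gene: str = "Slc32a1"
    glut_gene: str = "Slc17a6"
    type_markers: dict[str, str] = dataclasses.field(
        default_factory=_default_type_markers
    )

    def all_genes(self) -> list[str]:
        genes = list(self.neuron_markers) + [self.gaba_gene, self.glut_gene]
        genes += list(self.type_markers.values())
        if len(set(genes)) != len(genes):
            raise ValueError("marker panel genes must be distinct")
        return genes


@dataclasses.dataclass
class ClusterProfile:
    """Per-cluster marker medians and the annotation decisions."""

    cluster_id: int
    n_cells: int
    marker_medians: dict[str, float]
    neuron_score: float
    gmm_posterior_high: float | None = None
    neuron: bool | None = None
    nt_class: str | None = None  # GABAergic / glutamatergic / unclassified
    cell_type: str | None = None
    margin: float | None = None


def aggregate_cluster_medians(
    nm: NormMatrix, labels: ClusterLabels, panel: MarkerPanel | None = None
) -> list[ClusterProfile]:
    """Median normalized expression of each panel gene per cluster.

    The aggregated neuron score is the mean of the neuron-marker medians.
    Panel genes absent from the matrix are dropped with a warning.
    """
    panel = panel or MarkerPanel()
    if not np.array_equal(labels.column_ids, nm.column_ids):
        raise ValueError("cluster labels are not aligned with the matrix")
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    wanted = panel.all_genes()
    missing = [g for g in wanted if g not in gene_pos]
    if missing:
        logger.warning("panel genes missing from matrix: %s", missing)
    present = [g for g in wanted if g in gene_pos]

    profiles = []
    for c in range(labels.n_clusters):
        members = labels.labels == c
        assert members.any(), f"cluster {c} has no cells"
        medians = {
            g: float(np.median(nm.values[gene_pos[g], members])) for g in present
        }
        neuron_meds = [medians[g] for g in panel.neuron_markers if g in medians]
        score = float(np.mean(neuron_meds)) if neuron_meds else float("nan")
        profiles.append(
            ClusterProfile(
                cluster_id=c,
                n_cells=int(members.sum()),
                marker_medians=medians,
                neuron_score=score,
            )
        )
    return profiles


def classify_neuron_clusters(
    profiles: list[ClusterProfile], seed: int = 0
) -> list[ClusterProfile]:
    """Split clusters into neuronal (high score) and non-neuronal (low).

    A two-component 1-D Gaussian mixture (EM, k-means initialization, fixed
    seed, variance floor 1e-6) is fitted to the aggregated neuron scores;
    the component with the larger mean is "high" and a cluster is neuronal
    when its posterior for that component exceeds 0.5.
    """
    scores = np.array([p.neuron_score for p in profiles])
    if len(profiles) < 2 or np.allclose(scores, scores[0]):
        raise ValueError("unclassifiable: degenerate score distribution")
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        reg_covar=1e-6,
        n_init=5,
        init_params="kmeans",
        random_state=seed,
    )
    gmm.fit(scores[:, None])
    high = int(np.argmax(gmm.means_.ravel()))
    posterior = gmm.predict_proba(scores[:, None])[:, high]
    for p, post in zip(profiles, posterior):
        p.gmm_posterior_high = float(post)
        p.neuron = bool(post > 0.5)
    return profiles


def classify_neurotransmitter(
    profiles: list[ClusterProfile], panel: MarkerPanel | None = None
) -> list[ClusterProfile]:
    """GABAergic/glutamatergic dichotomy on neuron clusters.

    Strict comparison of the Slc32a1 and Slc17a6 medians; an exact tie
    leaves the cluster unclassified (logged).  Operates on clusters flagged
    neuronal, or on all clusters when no neuron calls are present (the
    neurons-only re-clustering round).
    """
    panel = panel or MarkerPanel()
    targets = [p for p in profiles if p.neuron is not False]
    for p in targets:
        if panel.gaba_gene not in p.marker_medians or (
            panel.glut_gene not in p.marker_medians
        ):
            raise ValueError(
                f"cluster {p.cluster_id}: {panel.gaba_gene}/{panel.glut_gene} "
                "medians unavailable"
            )
        gaba = p.marker_medians[panel.gaba_gene]
        glut = p.marker_medians[panel.glut_gene]
        if gaba > glut:
            p.nt_class = "GABAergic"
        elif glut > gaba:
            p.nt_class = "glutamatergic"
        else:
            p.nt_class = "unclassified"
            logger.info("cluster %d: %s = %s tie; unclassified",
                        p.cluster_id, panel.gaba_gene, panel.glut_gene)
    return profiles


def annotate_nonneuronal(
    profiles: list[ClusterProfile], panel: MarkerPanel | None = None
) -> list[ClusterProfile]:
    """Name non-neuron clusters by the maximal canonical-marker median."""
    panel = panel or MarkerPanel()
    for p in profiles:
        if p.neuron:
            p.cell_type = "neurons"
            continue
        scored = [
            (p.marker_medians[g], t)
            for t, g in panel.type_markers.items()
            if g in p.marker_medians
        ]
        if not scored:
            logger.warning("cluster %d: no type markers present", p.cluster_id)
            continue
        scored.sort(key=lambda x: (-x[0], x[1]))
        top_val = scored[0][0]
        runner = scored[1][0] if len(scored) > 1 else float("-inf")
        p.margin = float(top_val - runner)
        p.cell_type = "ambiguous" if p.margin == 0 else scored[0][1]
    return profiles


def profiles_frame(profiles: list[ClusterProfile]) -> pd.DataFrame:
    """Annotation table (the TSV-facing representation)."""
    rows = []
    for p in profiles:
        row = {
            "cluster_id": p.cluster_id,
            "n_cells": p.n_cells,
            "neuron_score": p.neuron_score,
            "gmm_posterior_high": p.gmm_posterior_high,
            "neuron": p.neuron,
            "nt_class": p.nt_class,
            "cell_type": p.cell_type,
            "margin": p.margin,
        }
        row.update({f"median_{g}": v for g, v in p.marker_medians.items()})
        rows.append(row)
    return pd.DataFrame(rows)
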