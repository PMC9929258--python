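"""Recovery metrics against generator ground truth.

Used by the test suite and the acceptance script to score how well the
pipeline recovers the simulated cell classes, the neuron/non-neuron calls,
the GABAergic/glutamatergic dichotomy, and the non-neuronal annotations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .pipeline import PipelineResult
from .synth import GroundTruth

_NT_BY_SUBCLASS = {"neurons_gaba": "GABAergic", "neurons_glut": "glutamatergic"}


def _truth_for_retained(result: PipelineResult, truth: GroundTruth) -> pd.DataFrame:
    cells = truth.cells.set_index("cell_id")
    return cells.loc[list(result.norm.column_ids)]


def final_partition_ari(result: PipelineResult, truth: GroundTruth) -> float:
    """ARI of the pipeline's final cell partition vs the finest truth labels."""
    t = _truth_for_retained(result, truth)
    return float(
        adjusted_rand_score(t["subclass"].to_numpy(), result.final_partition())
    )


def _majority(values: np.ndarray) -> str:
    vals, counts = np.unique(values.astype(str), return_counts=True)
    return str(vals[np.argmax(counts)])


def neuron_call_accuracy(result: PipelineResult, truth: GroundTruth) -> float:
    """Fraction of round-1 clusters whose neuron call matches the majority
    truth class of their member cells."""
    t = _truth_for_retained(result, truth)
    is_neuron_truth = (t["cell_class"] == "neurons").to_numpy()
    correct = 0
    for p in result.profiles:
        members = result.clusters.labels == p.cluster_id
        expected = is_neuron_truth[members].mean() > 0.5
        correct += p.neuron == expected
    return correct / len(result.profiles)


def nt_call_accuracy(result: PipelineResult, truth: GroundTruth) -> float:
    """Fraction of neuron subclusters with the majority-truth dichotomy call."""
    if result.neuron_clusters is None or result.neuron_profiles is None:
        raise ValueError("pipeline produced no neuron re-clustering")
    t = _truth_for_retained(result, truth)
    sub_truth = t.loc[result.neuron_cells, "subclass"].to_numpy()
    correct = 0
    for p in result.neuron_profiles:
        members = result.neuron_clusters.labels == p.cluster_id
        expected = _NT_BY_SUBCLASS.get(_majority(sub_truth[members]), "")
        correct += p.nt_class == expected
    return correct / len(result.neuron_profiles)


def annotation_accuracy(result: PipelineResult, truth: GroundTruth) -> float:
    """Fraction of non-neuron clusters annotated as their majority truth class."""
    t = _truth_for_retained(result, truth)
    cls_truth = t["cell_class"].to_numpy()
    nonneuron = [p for p in result.profiles if not p.neuron]
    if not nonneuron:
        raise ValueError("no non-neuron clusters to score")
    correct = 0
    for p in nonneuron:
        members = result.clusters.labels == p.cluster_id
        correct += p.cell_type == _majority(cls_truth[members])
    return correct / len(nonneuron)


def neuron_cell_fraction_error(result: PipelineResult, truth: GroundTruth) -> float:
    """Classified neuron cell fraction minus the true neuron fraction."""
    t = _truth_for_retained(result, truth)
    true_frac = (t["cell_class"] == "neurons").mean()
    called_frac = result.cell_annotations["neuron"].mean()
    return float(called_frac - true_frac)
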