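import numpy as np
import pandas as pd
import pytest

import _oracles
from dmhseq import (
    GeneratorConfig,
    MarkerPanel,
    aggregate_cluster_medians,
    annotate_nonneuronal,
    classify_neuron_clusters,
    classify_neurotransmitter,
    run_pipeline,
    simulate_counts,
)
from dmhseq.classify import ClusterProfile
from dmhseq.cluster import ClusterLabels
from dmhseq.normalize import NormMatrix


def _norm_matrix(values, gene_ids):
    values = np.asarray(values, float)
    cols = np.array([f"c{j}" for j in range(values.shape[1])], object)
    labels = pd.DataFrame(
        {"sample": "s", "condition": "A"}, index=cols
    )
    return NormMatrix(values, np.array(gene_ids, object), cols, labels, 1.0, 100.0)


def _labels(assignments):
    arr = np.asarray(assignments)
    ids = np.array([f"c{j}" for j in range(len(arr))], object)
    return ClusterLabels(arr, ids, "all-cells", {})


def _profile(cluster_id, medians, neuron=None):
    score = float(np.mean([medians.get(g, 0.0)
                           for g in MarkerPanel().neuron_markers]))
    return ClusterProfile(cluster_id, 10, medians, score, neuron=neuron)


def test_cluster_medians_match_sorting_oracle():
    rng = np.random.default_rng(0)
    panel = MarkerPanel()
    genes = panel.all_genes()
    values = rng.normal(2.0, 1.0, size=(len(genes), 30))
    nm = _norm_matrix(values, genes)
    labels = _labels(rng.integers(0, 3, 30))
    profiles = aggregate_cluster_medians(nm, labels, panel)
    for p in profiles:
        members = np.flatnonzero(labels.labels == p.cluster_id)
        for gi, g in enumerate(genes):
            vals = sorted(values[gi, members])
            n = len(vals)
            med = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert p.marker_medians[g] == pytest.approx(med)
    # aggregated score is the mean of the neuron-marker medians
    p0 = profiles[0]
    assert p0.neuron_score == pytest.approx(
        np.mean([p0.marker_medians[g] for g in panel.neuron_markers])
    )


def test_median_of_odd_cluster():
    nm = _norm_matrix([[0.0, 1.0, 9.0]], ["Snap25"])
    profiles = aggregate_cluster_medians(nm, _labels([0, 0, 0]),
                                         MarkerPanel(type_markers={}))
    assert profiles[0].marker_medians["Snap25"] == 1.0


def test_gmm_separates_high_and_low_scores():
    scores = [5.1, 4.8, 4.9, 0.1, 0.2]
    profiles = [
        _profile(i, {g: s for g in MarkerPanel().neuron_markers})
        for i, s in enumerate(scores)
    ]
    out = classify_neuron_clusters(profiles, seed=0)
    assert [p.neuron for p in out] == [True, True, True, False, False]
    for p in out:
        post = p.gmm_posterior_high if p.neuron else 1 - p.gmm_posterior_high
        assert post > 0.99


def test_gmm_matches_exhaustive_split_oracle():
    rng = np.random.default_rng(1)
    scores = np.concatenate([rng.normal(5, 0.3, 6), rng.normal(0.5, 0.2, 4)])
    profiles = [
        _profile(i, {g: s for g in MarkerPanel().neuron_markers})
        for i, s in enumerate(scores)
    ]
    out = classify_neuron_clusters(profiles, seed=0)
    expected = _oracles.gmm_two_group_split_loop(list(scores))
    assert [p.neuron for p in out] == expected


def test_degenerate_scores_rejected():
    profiles = [
        _profile(i, {g: 2.0 for g in MarkerPanel().neuron_markers})
        for i in range(3)
    ]
    with pytest.raises(ValueError, match="degenerate"):
        classify_neuron_clusters(profiles, seed=0)
    with pytest.raises(ValueError, match="degenerate"):
        classify_neuron_clusters(profiles[:1], seed=0)


def test_neuron_calls_invariant_to_cluster_order():
    scores = [5.0, 0.3, 4.6, 0.1, 4.9]
    profiles = [
        _profile(i, {g: s for g in MarkerPanel().neuron_markers})
        for i, s in enumerate(scores)
    ]
    calls = [p.neuron for p in classify_neuron_clusters(list(profiles), seed=0)]
    shuffled = [profiles[i] for i in [3, 0, 4, 1, 2]]
    calls_shuffled = {
        p.cluster_id: p.neuron
        for p in classify_neuron_clusters(shuffled, seed=0)
    }
    assert calls == [calls_shuffled[i] for i in range(5)]


@pytest.mark.parametrize(
    "gaba, glut, expected",
    [
        (2.0, 0.5, "GABAergic"),
        (0.0, 3.1, "glutamatergic"),
        (0.0, 0.0, "unclassified"),
        (1.5, 1.5, "unclassified"),
    ],
)
def test_neurotransmitter_dichotomy(gaba, glut, expected):
    p = _profile(0, {"Slc32a1": gaba, "Slc17a6": glut}, neuron=True)
    out = classify_neurotransmitter([p])
    assert out[0].nt_class == expected


def test_dichotomy_requires_both_genes():
    p = _profile(0, {"Slc32a1": 1.0}, neuron=True)
    with pytest.raises(ValueError, match="Slc17a6"):
        classify_neurotransmitter([p])


def test_nonneuronal_annotation_argmax_and_ties():
    markers = {g: 0.0 for g in MarkerPanel().type_markers.values()}
    astro = dict(markers, Agt=4.0)
    p = _profile(0, astro, neuron=False)
    assert annotate_nonneuronal([p])[0].cell_type == "astrocytes"
    tied = dict(markers, Agt=3.0, Flt1=3.0)
    q = _profile(1, tied, neuron=False)
    out = annotate_nonneuronal([q])[0]
    assert out.cell_type == "ambiguous"
    assert out.margin == 0.0
    neuron = _profile(2, markers, neuron=True)
    assert annotate_nonneuronal([neuron])[0].cell_type == "neurons"


def test_pipeline_annotates_mixture_perfectly():
    """On a clean six-type mixture every non-neuron cluster is annotated
    with its true class and the neuron fraction is recovered."""
    cfg = GeneratorConfig(
        n_genes=600,
        n_cells_per_condition=400,
        cell_class_proportions={
            "neurons": 0.4, "astrocytes": 0.15, "microglia": 0.15,
            "endothelial": 0.1, "oligodendrocytes": 0.1, "opc": 0.1,
        },
        seed=21,
    )
    m, t = simulate_counts(cfg)
    res = run_pipeline(m, seed=21)
    truth = t.cells.set_index("cell_id").loc[list(res.norm.column_ids)]
    for p in res.profiles:
        members = res.clusters.labels == p.cluster_id
        true_cls = truth.loc[members, "cell_class"].mode()[0]
        if p.neuron:
            assert true_cls == "neurons"
        else:
            assert p.cell_type == true_cls
    f_true = (truth["cell_class"] == "neurons").mean()
    f_called = res.cell_annotations["neuron"].mean()
    assert abs(f_called - f_true) <= 0.03
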