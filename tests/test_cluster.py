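import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from dmhseq import (
    GeneratorConfig,
    cluster_embedding,
    embed,
    filter_cells,
    filter_genes,
    compute_cell_qc,
    iterative_subcluster,
    median_scale_normalize,
    select_hvg,
    simulate_counts,
)
from dmhseq.cluster import Embedding2D


def _prepared(cfg):
    m, t = simulate_counts(cfg)
    qc = compute_cell_qc(m)
    f = filter_genes(filter_cells(m, qc))
    nm = median_scale_normalize(f)
    truth = t.cells.set_index("cell_id").loc[list(nm.column_ids)]
    return nm, truth


def _two_class_cfg(seed=0, n=300):
    return GeneratorConfig(
        n_genes=400,
        n_cells_per_condition=n,
        cell_class_proportions={"astrocytes": 0.5, "microglia": 0.5},
        condition_effects={},
        effect_gene_sets={},
        class_activity_sigma=0.0,
        seed=seed,
    )


def _blob_cfg(seed=0, n=200):
    return GeneratorConfig(
        n_genes=400,
        n_cells_per_condition=n,
        cell_class_proportions={"astrocytes": 1.0},
        condition_effects={},
        effect_gene_sets={},
        class_activity_sigma=0.0,
        seed=seed,
    )


def test_embedding_is_deterministic_for_fixed_seed():
    nm, _ = _prepared(_blob_cfg(seed=1, n=120))
    hvg = select_hvg(nm, n_top=100, n_bins=10)
    e1 = embed(nm, hvg, perplexity=20, seed=5)
    e2 = embed(nm, hvg, perplexity=20, seed=5)
    assert np.array_equal(e1.coords, e2.coords)
    assert np.isfinite(e1.coords).all()


def test_marker_separated_classes_are_far_apart_in_embedding():
    nm, truth = _prepared(_two_class_cfg(seed=2))
    hvg = select_hvg(nm, n_top=200, n_bins=20)
    e = embed(nm, hvg, perplexity=30, seed=0)
    classes = truth["cell_class"].to_numpy()
    a = e.coords[classes == "astrocytes"]
    b = e.coords[classes == "microglia"]
    intra = np.mean([
        np.linalg.norm(a - a.mean(0), axis=1).mean(),
        np.linalg.norm(b - b.mean(0), axis=1).mean(),
    ])
    inter = np.linalg.norm(a.mean(0) - b.mean(0))
    assert inter > intra


def test_homogeneous_blob_has_no_real_two_way_split():
    """The best 2-way split of a homogeneous blob scores far below the
    silhouette of truly separated classes (an isotropic cloud's optimal
    bisection sits near 0.35 by construction, well under the ~0.7 of
    marker-separated data)."""
    nm, _ = _prepared(_blob_cfg(seed=3))
    hvg = select_hvg(nm, n_top=200, n_bins=20)
    e = embed(nm, hvg, perplexity=30, seed=0)
    split = KMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(e.coords)
    blob_sil = silhouette_score(e.coords, split)

    nm2, truth2 = _prepared(_two_class_cfg(seed=3, n=200))
    hvg2 = select_hvg(nm2, n_top=200, n_bins=20)
    e2 = embed(nm2, hvg2, perplexity=30, seed=0)
    split2 = KMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(e2.coords)
    class_sil = silhouette_score(e2.coords, split2)

    assert blob_sil < 0.45
    assert class_sil > 0.55
    assert blob_sil < class_sil - 0.2


def test_density_clustering_recovers_separated_classes():
    cfg = GeneratorConfig(
        n_genes=400,
        n_cells_per_condition=400,
        cell_class_proportions={
            "astrocytes": 0.25, "microglia": 0.25,
            "endothelial": 0.25, "oligodendrocytes": 0.25,
        },
        condition_effects={}, effect_gene_sets={}, class_activity_sigma=0.0,
        seed=4,
    )
    nm, truth = _prepared(cfg)
    hvg = select_hvg(nm, n_top=200, n_bins=20)
    e = embed(nm, hvg, perplexity=30, seed=0)
    labels = cluster_embedding(e)
    ari = adjusted_rand_score(truth["cell_class"].to_numpy(), labels.labels)
    assert ari >= 0.9
    assert labels.labels.min() == 0
    assert len(labels.labels) == nm.n_cells


def test_single_blob_yields_one_cluster():
    nm, _ = _prepared(_blob_cfg(seed=5))
    hvg = select_hvg(nm, n_top=200, n_bins=20)
    e = embed(nm, hvg, perplexity=30, seed=0)
    labels = cluster_embedding(e)
    assert labels.n_clusters == 1


def test_clustering_invariant_to_point_order():
    rng = np.random.default_rng(6)
    pts = np.vstack([
        rng.normal([0, 0], 0.4, size=(80, 2)),
        rng.normal([8, 8], 0.4, size=(80, 2)),
        rng.normal([-8, 8], 0.4, size=(60, 2)),
    ])
    ids = np.array([f"c{i}" for i in range(len(pts))], dtype=object)
    e = Embedding2D(pts, ids, 30.0, 0)
    la = cluster_embedding(e, min_samples=5)
    perm = rng.permutation(len(pts))
    ep = Embedding2D(pts[perm], ids[perm], 30.0, 0)
    lb = cluster_embedding(ep, min_samples=5)
    assert adjusted_rand_score(la.labels[perm], lb.labels) == 1.0


def test_degenerate_embedding_gives_single_cluster():
    pts = np.zeros((50, 2))
    ids = np.array([f"c{i}" for i in range(50)], dtype=object)
    labels = cluster_embedding(Embedding2D(pts, ids, 30.0, 0))
    assert labels.n_clusters == 1


def test_subcluster_of_all_cells_equals_fresh_run():
    nm, _ = _prepared(_two_class_cfg(seed=7, n=150))
    hvg = select_hvg(nm, n_top=150, n_bins=15)
    e = embed(nm, hvg, perplexity=20, seed=9)
    full = cluster_embedding(e)
    _, e2, sub = iterative_subcluster(
        nm, full, np.ones(nm.n_cells, bool),
        n_top=150, n_bins=15, perplexity=20, seed=9,
    )
    assert np.array_equal(e.coords, e2.coords)
    assert adjusted_rand_score(full.labels, sub.labels) == 1.0
    assert sub.round == "neurons-only"


def test_subcluster_splits_neuron_subtypes():
    cfg = GeneratorConfig(
        n_genes=400,
        n_cells_per_condition=300,
        cell_class_proportions={"neurons": 1.0},
        condition_effects={}, effect_gene_sets={}, class_activity_sigma=0.0,
        seed=8,
    )
    nm, truth = _prepared(cfg)
    hvg = select_hvg(nm, n_top=200, n_bins=20)
    e = embed(nm, hvg, perplexity=30, seed=0)
    full = cluster_embedding(e)
    _, _, sub = iterative_subcluster(
        nm, full, np.ones(nm.n_cells, bool),
        n_top=200, n_bins=20, perplexity=30, seed=0,
    )
    assert sub.n_clusters >= 2
    ari = adjusted_rand_score(truth["nt_class"].to_numpy(), sub.labels)
    assert ari >= 0.9


def test_empty_subset_rejected():
    nm, _ = _prepared(_blob_cfg(seed=9, n=100))
    hvg = select_hvg(nm, n_top=100, n_bins=10)
    e = embed(nm, hvg, perplexity=20, seed=0)
    labels = cluster_embedding(e)
    with pytest.raises(ValueError, match="no cells"):
        iterative_subcluster(nm, labels, np.zeros(nm.n_cells, bool))
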