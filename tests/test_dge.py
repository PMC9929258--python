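import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

import _oracles
from dmhseq import (
    DGEConfig,
    GeneratorConfig,
    NegativeBinomialDE,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    sc_group_test,
    simulate_counts,
    size_factors_median_of_ratios,
)
from conftest import make_count_matrix


# ------------------------------------------------------------- size factors
def test_identical_samples_have_unit_factors():
    counts = np.array([[10, 10], [3, 3], [7, 7]])
    assert np.allclose(size_factors_median_of_ratios(counts), 1.0)


def test_fourfold_sample_splits_geometrically():
    counts = np.array([[4, 16], [10, 40], [3, 12]])
    assert np.allclose(size_factors_median_of_ratios(counts), [0.5, 2.0])


@pytest.mark.parametrize("seed", range(5))
def test_size_factors_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(20.0, size=(40, 6)) + 1
    assert np.allclose(
        size_factors_median_of_ratios(counts),
        _oracles.size_factors_loop(counts),
    )


def test_size_factors_need_a_ubiquitous_gene():
    counts = np.array([[1, 0], [0, 1]])
    with pytest.raises(ValueError, match="expressed in all"):
        size_factors_median_of_ratios(counts)


def test_size_factors_recover_true_multipliers():
    """On null bulk data the estimates track the generating multipliers."""
    from dmhseq import simulate_bulk

    cfg = GeneratorConfig(
        n_genes=500, condition_effects={}, effect_gene_sets={},
        class_activity_sigma=0.0, libsize_lognormal=(0.0, 0.3), seed=12,
    )
    b, t = simulate_bulk(cfg, n_replicates=5)
    sf = size_factors_median_of_ratios(b)
    lib = t.cells["lib_factor"].to_numpy()
    lib = lib / np.exp(np.log(lib).mean())
    assert np.allclose(sf, lib, rtol=0.05)


# -------------------------------------------------------------- dispersion
def test_dispersion_estimates_bracket_truth():
    rng = np.random.default_rng(3)
    G, n = 500, 20
    mu = rng.lognormal(1.0, 1.0, G)
    groups = np.array(["A"] * 10 + ["B"] * 10)
    y_pois = rng.poisson(mu[:, None], size=(G, n))
    assert np.nanmedian(estimate_dispersion(y_pois, np.ones(n), groups)) <= 0.01
    r = 1 / 0.4
    y_nb = rng.negative_binomial(r, r / (r + mu[:, None]), size=(G, n))
    med = np.nanmedian(estimate_dispersion(y_nb, np.ones(n), groups))
    assert 0.2 <= med <= 0.6


def test_constant_zero_gene_flagged_untestable():
    counts = np.vstack([np.zeros(10, int), np.full(10, 5)])
    groups = np.array(["A"] * 5 + ["B"] * 5)
    phi = estimate_dispersion(counts, np.ones(10), groups)
    assert np.isnan(phi[0]) and np.isfinite(phi[1])
    res = NegativeBinomialDE(counts, groups, size_factors=np.ones(10),
                             config=DGEConfig(min_total_count=1)).fit()
    assert res.frame.loc[0, "untestable"]
    assert np.isnan(res.frame.loc[0, "p_value"])
    assert np.isnan(res.frame.loc[0, "p_adjusted"])


# ----------------------------------------------------------------- NB test
def test_wald_fit_matches_statsmodels_glm():
    """Per-gene estimates agree with an independent NB GLM fit."""
    rng = np.random.default_rng(4)
    G, n = 15, 40
    mu = rng.lognormal(1.5, 0.5, G)
    s = rng.lognormal(0, 0.2, n)
    grp = np.array(["A"] * 20 + ["B"] * 20)
    fold = np.where(np.arange(G) % 2, 2.0, 1.0)
    muM = mu[:, None] * s[None, :]
    muM[:, 20:] *= fold[:, None]
    phi = 0.1
    r = 1 / phi
    y = rng.negative_binomial(r, r / (r + muM), size=(G, n))
    res = NegativeBinomialDE(
        y, grp, size_factors=s, dispersions=np.full(G, phi)
    ).fit()
    X = np.column_stack([np.ones(n), (grp == "B").astype(float)])
    for i in range(G):
        ref = sm.GLM(
            y[i], X, family=sm.families.NegativeBinomial(alpha=phi),
            offset=np.log(s),
        ).fit()
        assert res.frame.loc[i, "log2_fold_change"] == pytest.approx(
            ref.params[1] / np.log(2), abs=1e-5
        )
        assert res.frame.loc[i, "p_value"] == pytest.approx(
            ref.pvalues[1], abs=1e-5
        )


def test_planted_effect_detected_in_small_bulk_design():
    """log2FC = 1 with tiny dispersion is significant at n = 5 per group."""
    rng = np.random.default_rng(5)
    mu = np.full(30, 100.0)
    muM = np.tile(mu[:, None], (1, 10))
    muM[0, 5:] *= 2.0
    phi = 0.05
    r = 1 / phi
    y = rng.negative_binomial(r, r / (r + muM), size=(30, 10))
    m = make_count_matrix(y, conditions=["A"] * 5 + ["B"] * 5)
    res = NegativeBinomialDE.from_count_matrix(m, contrast=("A", "B")).fit()
    assert res.frame.loc[0, "p_value"] < 0.05
    # n = 5/group puts ~0.22 sampling SE on the log2 fold estimate
    assert res.frame.loc[0, "log2_fold_change"] == pytest.approx(1.0, abs=0.6)


def test_summary_reports_contrast_and_counts():
    rng = np.random.default_rng(6)
    y = rng.poisson(20.0, size=(20, 10))
    m = make_count_matrix(y, conditions=["A"] * 5 + ["B"] * 5)
    res = NegativeBinomialDE.from_count_matrix(m).fit()
    text = res.summary()
    assert "B vs A" in text and "20" in text


# ---------------------------------------------------------------------- BH
def test_bh_stepup_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_adjust([0.7]) == pytest.approx([0.7])
    assert bh_adjust([]).size == 0


def test_bh_matches_definition_oracle():
    rng = np.random.default_rng(7)
    p = rng.random(1000)
    assert np.allclose(bh_adjust(p), _oracles.bh_adjust_loop(list(p)))


def test_bh_nan_passthrough():
    p = [0.01, np.nan, 0.04]
    out = bh_adjust(p)
    assert np.isnan(out[1])
    # NaN excluded from the number of tests (m = 2 here)
    assert np.allclose(out[[0, 2]], _oracles.bh_adjust_loop([0.01, 0.04]))


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_is_monotone_and_permutation_invariant(p):
    out = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(out[order]) >= -1e-12).all()
    perm = np.random.default_rng(0).permutation(len(p))
    out_perm = bh_adjust(np.asarray(p)[perm])
    assert np.allclose(out[perm], out_perm)
    assert (out >= np.asarray(p) - 1e-12).all()


# ------------------------------------------------------------- calling rule
def test_deg_calling_boundaries():
    frame = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "log2_fold_change": [0.58, 1.0, np.log2(1.5), -1.0],
            "p_adjusted": [0.01, 0.06, 0.05, 0.04],
        }
    )
    out = call_degs(frame)
    # 0.58 < log2(1.5) ~ 0.585 fails the fold rule despite small p
    assert out["is_deg"].tolist() == [False, False, True, True]


@pytest.mark.parametrize("seed", range(3))
def test_deg_calls_match_bruteforce_filter(seed):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(200)],
            "log2_fold_change": rng.normal(0, 1, 200),
            "p_adjusted": rng.random(200),
        }
    )
    out = call_degs(frame)
    expected = [
        abs(l) >= np.log2(1.5) and q <= 0.05
        for l, q in zip(frame["log2_fold_change"], frame["p_adjusted"])
    ]
    assert out["is_deg"].tolist() == expected


# ------------------------------------------------------------- single cell
def test_sc_test_finds_planted_effects_in_gaba_class():
    cfg = GeneratorConfig(n_cells_per_condition=550, seed=101)
    m, t = simulate_counts(cfg)
    res = sc_group_test(
        m, t.cells["nt_class"].to_numpy(), "GABAergic", contrast=("WT", "KO")
    )
    f = res.frame.set_index("gene_id")
    # fully ablated gene: negative sign, zero KO mean, called DEG
    assert f.loc["Prkar2b", "log2_fold_change"] == -np.inf
    assert f.loc["Prkar2b", "is_deg"]
    # up-shifted gene significant with a positive estimate
    assert f.loc["Prkar1a", "p_adjusted"] <= 0.05
    assert f.loc["Prkar1a", "log2_fold_change"] > 0


def test_sc_test_rejects_sparse_classes():
    cfg = GeneratorConfig(n_genes=400, n_cells_per_condition=30, seed=1)
    m, t = simulate_counts(cfg)
    with pytest.raises(ValueError, match="pericytes"):
        sc_group_test(m, t.cells["cell_class"].to_numpy(), "pericytes")


def test_config_validation():
    with pytest.raises(ValueError, match="fold_threshold"):
        DGEConfig(fold_threshold=1.0)
    with pytest.raises(ValueError, match="alpha"):
        DGEConfig(alpha=0.0)
    with pytest.raises(ValueError, match="test"):
        DGEConfig(test="exact")
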