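"""Synthetic genotype/phenotype generator and QC operations."""

import numpy as np
import pytest

from mtgwp.simdata import (
    MISSING,
    SimConfig,
    fourclass_to_binary,
    impute_marginal,
    liability_to_fourclass,
    maf_filter,
    simulate_genotypes,
    simulate_traits,
    split_data,
)


def _small_cfg(**kw):
    base = dict(n_samples=300, n_markers=60, n_traits=2, heritability=(0.5, 0.5),
                seed=3)
    base.update(kw)
    return SimConfig(**base)


def test_genotypes_additive_coding_range_and_shape():
    cfg = _small_cfg()
    G = simulate_genotypes(cfg)
    assert G.values.shape == (300, 60)
    assert set(np.unique(G.values)).issubset({0, 1, 2})
    assert G.max_dosage == 2


def test_genotypes_dominant_coding_is_binary():
    cfg = _small_cfg(coding="dominant_01")
    G = simulate_genotypes(cfg)
    assert set(np.unique(G.values)).issubset({0, 1})
    assert G.max_dosage == 1


def test_maf_within_configured_range():
    cfg = _small_cfg(n_samples=4000, maf_range=(0.1, 0.4), seed=5)
    G = simulate_genotypes(cfg)
    maf = G.maf()
    # sampling noise at n=4000 is ~0.008; allow 4 sigma
    assert maf.min() > 0.1 - 0.035
    assert maf.max() < 0.4 + 0.035


def test_adjacent_marker_ld_matches_target():
    cfg = _small_cfg(n_samples=6000, n_markers=100, ld_block_size=10,
                     ld_rho=0.5, seed=7)
    G = simulate_genotypes(cfg)
    X = G.values.astype(float)
    rs = []
    for j in range(0, 100):
        if (j % 10) == 9:
            continue  # block boundary
        rs.append(np.corrcoef(X[:, j], X[:, j + 1])[0, 1])
    assert abs(np.mean(rs) - 0.5) < 0.05


def test_markers_in_different_blocks_uncorrelated():
    cfg = _small_cfg(n_samples=6000, n_markers=40, ld_block_size=10,
                     ld_rho=0.8, seed=11)
    G = simulate_genotypes(cfg)
    X = G.values.astype(float)
    r = np.corrcoef(X[:, 5], X[:, 25])[0, 1]
    assert abs(r) < 0.05


def test_missing_rate_honored():
    cfg = _small_cfg(missing_rate=0.1, seed=2)
    G = simulate_genotypes(cfg)
    frac = (G.values == MISSING).mean()
    assert abs(frac - 0.1) < 0.02


def test_traits_are_standardized_and_reproducible():
    cfg = _small_cfg()
    G = simulate_genotypes(cfg)
    t1, truth1 = simulate_traits(G, cfg)
    t2, truth2 = simulate_traits(G, cfg)
    assert np.allclose(t1.values, t2.values)
    assert np.array_equal(truth1.all_causal, truth2.all_causal)
    assert np.allclose(t1.values.mean(0), 0.0, atol=1e-10)
    assert np.allclose(t1.values.std(0), 1.0, atol=1e-10)


def test_qtl_truth_counts():
    cfg = _small_cfg(n_qtl_shared=5, n_qtl_specific_per_trait=3)
    G = simulate_genotypes(cfg)
    _, truth = simulate_traits(G, cfg)
    assert truth.all_causal.size == 5 + 3 * 2


def test_zero_heritability_trait_independent_of_genotype():
    cfg = _small_cfg(n_samples=2000, heritability=(0.0, 0.5), seed=9)
    G = simulate_genotypes(cfg)
    traits, truth = simulate_traits(G, cfg)
    X = G.values.astype(float)
    causal = truth.all_causal
    r = np.corrcoef(X[:, causal].sum(1), traits.values[:, 0])[0, 1]
    assert abs(r) < 0.06


def test_full_heritability_trait_noiseless():
    cfg = _small_cfg(n_samples=500, heritability=(1.0, 1.0), seed=13)
    G = simulate_genotypes(cfg)
    traits, truth = simulate_traits(G, cfg)
    X = G.values.astype(float)
    # trait must be an exact linear function of the causal markers
    Z = X[:, truth.all_causal]
    Z1 = np.column_stack([Z, np.ones(len(Z))])
    resid = traits.values[:, 0] - Z1 @ np.linalg.lstsq(Z1, traits.values[:, 0],
                                                       rcond=None)[0]
    assert np.abs(resid).max() < 1e-8


def test_maf_filter_removes_rare_markers():
    cfg = _small_cfg(n_samples=1000, maf_range=(0.01, 0.5), seed=17)
    G = simulate_genotypes(cfg)
    G2, removed = maf_filter(G, threshold=0.1)
    assert np.all(G2.maf() >= 0.1)
    assert G2.values.shape[1] + len(removed) == G.values.shape[1]
    assert set(G2.marker_ids) | set(removed) == set(G.marker_ids)


def test_impute_marginal_fills_all_missing_with_valid_dosages():
    cfg = _small_cfg(missing_rate=0.15, seed=19)
    G = simulate_genotypes(cfg)
    G2 = impute_marginal(G, seed=0)
    assert not np.any(G2.values == MISSING)
    assert set(np.unique(G2.values)).issubset({0, 1, 2})
    observed = G.values != MISSING
    assert np.array_equal(G2.values[observed], G.values[observed])


def test_liability_thresholding_roundtrip():
    rng = np.random.default_rng(0)
    Y = rng.normal(size=(400, 2))
    four = liability_to_fourclass(Y)
    assert set(np.unique(four.values)).issubset({0, 1, 2, 3})
    B = fourclass_to_binary(four.values)
    # class index encodes the two binary thresholds
    assert np.array_equal(B[:, 0] * 2 + B[:, 1], four.values)
    assert np.array_equal(B, (Y > 0).astype(int))


def test_split_sizes_and_disjointness():
    split = split_data(10, seed=0)
    assert len(split.train_idx) == 7
    assert len(split.val_idx) == 1
    assert len(split.test_idx) == 2
    allidx = np.concatenate([split.train_idx, split.val_idx, split.test_idx])
    assert sorted(allidx.tolist()) == list(range(10))


def test_split_deterministic_given_seed():
    s1 = split_data(100, seed=4)
    s2 = split_data(100, seed=4)
    s3 = split_data(100, seed=5)
    assert np.array_equal(s1.train_idx, s2.train_idx)
    assert not np.array_equal(s1.train_idx, s3.train_idx)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_samples=0)
    with pytest.raises(ValueError):
        _small_cfg(heritability=(1.5, 0.5))
    with pytest.raises(ValueError):
        _small_cfg(maf_range=(0.4, 0.1))
    with pytest.raises(ValueError):
        _small_cfg(n_qtl_shared=10_000)
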