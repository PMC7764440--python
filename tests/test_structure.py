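"""Heterozygosity, F_ST estimators, PCA, IBD and GRM."""

import numpy as np
import pytest

from rohscan import (
    MISSING,
    SimConfig,
    fst_outlier_scan,
    heterozygosity,
    ibd_and_grm,
    pairwise_fst,
    pca,
    simulate_populations,
)

from conftest import make_genotypes


def two_pop_matrix(col_a, col_b):
    """Stack explicit per-population genotype columns into one matrix."""
    calls = np.array(col_a + col_b, dtype=np.int8)
    pops = ["A"] * len(col_a) + ["B"] * len(col_b)
    return make_genotypes(calls, populations=pops)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def test_heterozygosity_hand_fixture():
    # one population: marker 1 monomorphic (He = Ho = 0 contribution)
    calls = np.array([[1, 0], [1, 0], [0, 0], [2, 0]], dtype=np.int8)
    out = heterozygosity(make_genotypes(calls))
    p = 4 / 8
    expect_he = (2 * p * (1 - p) + 0.0) / 2
    assert out.iloc[0]["He"] == pytest.approx(expect_he)
    assert out.iloc[0]["Ho"] == pytest.approx((2 / 4 + 0.0) / 2)


def test_heterozygosity_matches_hwe_simulation():
    rng = np.random.default_rng(8)
    calls = rng.binomial(2, 0.5, size=(300, 2000)).astype(np.int8)
    out = heterozygosity(make_genotypes(calls))
    assert out.iloc[0]["He"] == pytest.approx(0.5, abs=0.01)
    assert out.iloc[0]["Ho"] == pytest.approx(0.5, abs=0.01)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def test_wright_hand_example():
    """p_A = 0.2, p_B = 0.8 with equal sizes: (0.5 - 0.32) / 0.5 = 0.36."""
    gm = two_pop_matrix(
        [[1], [1], [0], [0], [0]],  # p = 0.2
        [[1], [1], [2], [2], [2]],  # p = 0.8
    )
    res = pairwise_fst(gm, "A", "B", estimator="wright", n_boot=0)
    assert res.per_marker_fst[0] == pytest.approx(0.36)
    assert res.fst_overall == pytest.approx(0.36)


def test_identical_frequencies_give_zero():
    gm = two_pop_matrix([[0], [1], [2]], [[0], [1], [2]])
    res = pairwise_fst(gm, "A", "B", estimator="wright", n_boot=0)
    assert res.fst_overall == pytest.approx(0.0)


def test_fixed_difference_gives_one():
    gm = two_pop_matrix([[0], [0], [0]], [[2], [2], [2]])
    res = pairwise_fst(gm, "A", "B", estimator="wright", n_boot=0)
    assert res.per_marker_fst[0] == pytest.approx(1.0)


def test_monomorphic_marker_is_undefined_not_outlier():
    gm = two_pop_matrix([[0, 0], [0, 1]], [[0, 2], [0, 1]])  # marker 0 fixed everywhere
    res = pairwise_fst(gm, "A", "B", estimator="wright", n_boot=0)
    assert np.isnan(res.per_marker_fst[0])
    assert 0 not in fst_outlier_scan(res, threshold=-1.0)


def test_wright_per_marker_in_unit_interval():
    gm, _, _ = simulate_populations(
        SimConfig(seed=71, n_populations=2, n_per_population=(40, 40),
                  n_chromosomes=2, markers_per_chromosome=500, fst=0.1, missing_rate=0.02)
    )
    res = pairwise_fst(gm, "pop1", "pop2", estimator="wright", n_boot=0)
    vals = res.per_marker_fst[np.isfinite(res.per_marker_fst)]
    assert np.all((vals >= 0) & (vals <= 1))


def test_weir_cockerham_and_hudson_recover_divergence():
    gm, _, _ = simulate_populations(
        SimConfig(seed=72, n_populations=2, n_per_population=(150, 150),
                  n_chromosomes=5, markers_per_chromosome=1200, fst=0.1, missing_rate=0.0)
    )
    for est in ("weir_cockerham", "hudson"):
        res = pairwise_fst(gm, "pop1", "pop2", estimator=est, n_boot=0)
        assert res.fst_overall == pytest.approx(0.1, abs=0.02), est


def test_bootstrap_ci_reproducible_and_brackets_estimate():
    gm, _, _ = simulate_populations(
        SimConfig(seed=73, n_populations=2, n_per_population=(50, 50),
                  n_chromosomes=2, markers_per_chromosome=400, fst=0.05, missing_rate=0.0)
    )
    r1 = pairwise_fst(gm, "pop1", "pop2", n_boot=200, seed=9)
    r2 = pairwise_fst(gm, "pop1", "pop2", n_boot=200, seed=9)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
    assert r1.ci_low <= r1.fst_overall <= r1.ci_high


def test_outlier_scan_thresholds():
    gm = two_pop_matrix(
        [[0, 0, 1], [0, 0, 1], [0, 0, 0]],
        [[2, 0, 1], [2, 0, 1], [2, 0, 2]],
    )
    res = pairwise_fst(gm, "A", "B", estimator="wright", n_boot=0)
    assert list(fst_outlier_scan(res, 0.5)) == [0]  # the fixed difference
    assert list(fst_outlier_scan(res, 0.0)) == [0, 2]  # all defined, positive markers
    assert list(fst_outlier_scan(res, 1.0)) == []  # strict comparison


def test_unknown_estimator_rejected():
    gm = two_pop_matrix([[0], [1]], [[2], [1]])
    with pytest.raises(ValueError, match="estimator"):
        pairwise_fst(gm, "A", "B", estimator="nei", n_boot=0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_separates_diverged_populations():
    gm, _, _ = simulate_populations(
        SimConfig(seed=74, n_populations=2, n_per_population=(40, 40),
                  n_chromosomes=3, markers_per_chromosome=600, fst=0.15, missing_rate=0.01)
    )
    res = pca(gm, n_components=4)
    pc1 = res.scores["PC1"].to_numpy()
    a = pc1[np.array(gm.populations) == "pop1"]
    b = pc1[np.array(gm.populations) == "pop2"]
    between = (a.mean() - b.mean()) ** 2
    within = a.var() + b.var()
    assert between > within
    assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # descending
    assert np.all(res.eigenvalues >= -1e-9)


def test_duplicated_sample_has_coincident_scores():
    rng = np.random.default_rng(3)
    calls = rng.binomial(2, rng.uniform(0.1, 0.9, 200), size=(20, 200)).astype(np.int8)
    calls[1] = calls[0]
    res = pca(make_genotypes(calls), n_components=3)
    s = res.scores[[f"PC{i}" for i in (1, 2, 3)]].to_numpy()
    np.testing.assert_allclose(s[0], s[1], atol=1e-8)


def test_zero_variance_markers_dropped_with_warning():
    calls = np.array([[0, 1], [0, 1], [0, 0], [0, 2]], dtype=np.int8)  # marker 0 fixed
    with pytest.warns(UserWarning, match="zero-variance"):
        res = pca(make_genotypes(calls), n_components=1)
    assert len(res.eigenvalues) == 1


# ---------------------------------------------------------------------------
# IBD / GRM
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def unstructured_cohort():
    return simulate_populations(
        SimConfig(seed=75, n_populations=1, n_per_population=(60,), n_chromosomes=4,
                  markers_per_chromosome=1000, fst=0.0, missing_rate=0.0)
    )


def test_duplicate_sample_flagged(unstructured_cohort):
    gm, _, _ = unstructured_cohort
    calls = np.vstack([gm.calls, gm.calls[0]])
    gm2 = make_genotypes(calls, populations=["P"] * (gm.n_samples + 1))
    rel = ibd_and_grm(gm2)
    pair = rel.ibd[(rel.ibd["sample_a"] == "s0") & (rel.ibd["sample_b"] == f"s{gm.n_samples}")]
    assert float(pair["pi_hat"].iloc[0]) > 0.95
    assert bool(pair["duplicate"].iloc[0])


def test_unrelated_pairs_near_zero(unstructured_cohort):
    gm, _, _ = unstructured_cohort
    rel = ibd_and_grm(gm)
    assert rel.ibd["pi_hat"].median() < 0.05


def test_grm_symmetric_with_unit_diagonal(unstructured_cohort):
    gm, _, _ = unstructured_cohort
    rel = ibd_and_grm(gm)
    np.testing.assert_allclose(rel.grm, rel.grm.T, atol=1e-12)
    assert np.mean(np.diag(rel.grm)) == pytest.approx(1.0, abs=0.05)
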