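import itertools

import numpy as np
import pytest
from scipy import stats

import eegconn as e
from eegconn.permstats import (
    PowerSpec, binwise_permutation, cohens_d, mann_whitney, pearson,
    standard_tests, t_test, t_test_power, anova_two_way,
)


def test_exact_permutation_matches_enumeration():
    """4+4 exact p equals independent exhaustive enumeration of C(8,4)."""
    a = np.array([[5.1], [6.2], [5.8], [6.0]])
    b = np.array([[1.1], [0.9], [1.5], [1.2]])
    res = binwise_permutation(a, b, exact=True)
    pooled = np.concatenate([a, b]).ravel()
    obs = a.mean() - b.mean()
    count = 0
    total = 0
    for combo in itertools.combinations(range(8), 4):
        rest = [i for i in range(8) if i not in combo]
        diff = pooled[list(combo)].mean() - pooled[rest].mean()
        count += diff >= obs - 1e-12
        total += 1
    assert total == 70
    assert res.p_values[0] == pytest.approx(count / 70)
    assert res.p_values[0] == pytest.approx(1 / 70)  # complete separation


def test_identical_groups_no_significant_bins():
    rng = np.random.default_rng(0)
    g = rng.standard_normal((6, 20))
    res = binwise_permutation(g, g.copy(), n_perm=500, seed=1)
    assert not res.significant_bins.any()
    assert res.clusters == []


def test_seed_determinism():
    rng = np.random.default_rng(1)
    a = rng.standard_normal((8, 30))
    b = rng.standard_normal((8, 30)) + 0.8
    r1 = binwise_permutation(a, b, n_perm=300, seed=7)
    r2 = binwise_permutation(a, b, n_perm=300, seed=7)
    assert np.array_equal(r1.p_values, r2.p_values)
    assert r1.clusters == r2.clusters


def test_affine_invariance_of_p_values():
    """p-hat is unchanged by a common affine map of both groups."""
    rng = np.random.default_rng(2)
    a = rng.standard_normal((6, 10))
    b = rng.standard_normal((6, 10)) + 0.5
    r1 = binwise_permutation(a, b, n_perm=200, seed=3)
    r2 = binwise_permutation(3.7 * a + 11, 3.7 * b + 11, n_perm=200, seed=3)
    # identical up to floating-point tie-breaking (one permutation
    # reproducing the observed labelling can fall on either side of >=)
    assert np.allclose(r1.p_values, r2.p_values, atol=2 / 201)


def test_cluster_detection_and_corrected_p():
    rng = np.random.default_rng(3)
    n_bins = 40
    a = rng.standard_normal((10, n_bins))
    b = rng.standard_normal((10, n_bins))
    b[:, 10:16] += 3.0  # strong contiguous effect, A < B
    res = binwise_permutation(a, b, n_perm=1000, seed=4)
    assert res.clusters
    main = max(res.clusters, key=lambda c: c.mass)
    assert main.direction == -1
    assert main.start_bin >= 9 and main.end_bin <= 16
    assert main.corrected_p <= 0.05
    # corrected p never beats the best per-bin p
    in_cluster = res.p_values[main.start_bin:main.end_bin + 1]
    best_bin_p = min(min(in_cluster), min(1 - in_cluster))
    assert main.corrected_p >= best_bin_p - 1e-12


def test_bin_count_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        binwise_permutation(np.zeros((3, 4)), np.zeros((3, 5)))


def test_t_test_df_and_identity():
    rng = np.random.default_rng(4)
    a = rng.standard_normal(12)
    b = rng.standard_normal(12)
    out = t_test(a, b)
    assert out["df"] == 22
    same = t_test(a, a)
    assert same["t"] == pytest.approx(0.0)
    assert same["p"] == pytest.approx(1.0)


def test_mann_whitney_matches_rank_enumeration():
    """U equals the count of (a, b) pairs with a > b (+ half-ties)."""
    a = [3.1, 4.5, 2.2, 6.6]
    b = [1.0, 2.9, 4.4]
    u_brute = sum(
        1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
    )
    assert mann_whitney(a, b)["U"] == pytest.approx(u_brute)


def test_mann_whitney_exact_p_small_samples():
    """Two-sided exact p matches enumeration over all rank assignments."""
    a = [9.0, 7.0, 5.5]
    b = [1.0, 2.0, 3.0]
    out = mann_whitney(a, b)
    pooled = a + b
    n_a = len(a)
    u_obs = sum(1.0 for x in a for y in b if x > y)
    more_extreme = 0
    total = 0
    for combo in itertools.combinations(range(6), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(6) if i not in combo]
        u = sum(1.0 for x in ga for y in gb if x > y)
        # two-sided: as or more extreme in either direction
        if abs(u - 4.5) >= abs(u_obs - 4.5) - 1e-12:
            more_extreme += 1
        total += 1
    assert out["p"] == pytest.approx(more_extreme / total)


def test_pearson_and_zero_variance():
    x = np.arange(10.0)
    out = pearson(x, 2 * x + 1)
    assert out["r"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="variance"):
        pearson(x, np.ones(10))


def test_anova_two_way_recovers_factor_effect():
    rng = np.random.default_rng(5)
    geno = ["ctrl"] * 12 + ["mut"] * 12
    modality = (["a"] * 6 + ["b"] * 6) * 2
    y = rng.standard_normal(24)
    y[12:] += 4.0
    out = anova_two_way(y, geno, modality)
    assert out["C(a)"]["p"] < 0.001
    assert out["C(b)"]["p"] > 0.05
    assert out["C(a)"]["df"] == 1


def test_cohens_d_values():
    assert cohens_d(PowerSpec(75.0, 55.0, 15.8, 12)) == pytest.approx(
        1.27, abs=0.005
    )
    assert cohens_d(PowerSpec(5.0, 5.0, 2.0, 12)) == 0.0
    assert cohens_d(PowerSpec(1.0, 0.0, 1.0, 12)) == 1.0


def test_power_at_paper_design():
    spec = PowerSpec(75.0, 55.0, 15.8, 12)
    assert t_test_power(spec) >= 0.803


def test_power_null_equals_alpha():
    spec = PowerSpec(1.0, 1.0, 1.0, 12)
    assert t_test_power(spec) == pytest.approx(0.05, abs=1e-9)


def test_power_matches_monte_carlo():
    """Noncentral-t power agrees with simulated experiments to ~0.005."""
    spec = PowerSpec(75.0, 55.0, 15.8, 12)
    analytic = t_test_power(spec)
    rng = np.random.default_rng(6)
    n_sim = 100_000
    a = rng.normal(75.0, 15.8, (n_sim, 12))
    b = rng.normal(55.0, 15.8, (n_sim, 12))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt((va + vb) / 2)
    tstat = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2 / 12))
    crit = stats.t.ppf(0.975, 22)
    mc = np.mean(np.abs(tstat) > crit)
    assert analytic == pytest.approx(mc, abs=0.005)


def test_standard_tests_bundle():
    rng = np.random.default_rng(7)
    a = rng.standard_normal(12)
    b = rng.standard_normal(12) + 1
    out = standard_tests(a, b)
    assert {"t_test", "mann_whitney", "pearson"} <= set(out)
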