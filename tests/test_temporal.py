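from itertools import combinations

import numpy as np
import pytest

from exoflow import (
    deviance_p_value,
    estimate_rates,
    holm_bonferroni,
    lr_test_seed_vs_seedling,
    randomization_test,
)
from exoflow.frequencies import component_matrix
from exoflow.likelihood import _grid_logliks, _grid_weights

from conftest import cross_offspring


def test_randomization_identical_samples(disjoint_freqs):
    native, exotic = disjoint_freqs
    s1 = cross_offspring({"NN": 8, "PN": 2}, label="a")
    s2 = cross_offspring({"NN": 8, "PN": 2}, label="b")
    results = randomization_test(s1, s2, native, exotic, B=49, seed=1)
    for r in results:
        assert r.observed_diff == pytest.approx(0.0, abs=1e-9)
        assert r.p_raw == 1.0


def test_randomization_rejects_seed_stage(disjoint_freqs):
    native, exotic = disjoint_freqs
    s1 = cross_offspring({"NN": 5}, label="a", stage="seed")
    s2 = cross_offspring({"NN": 5}, label="b")
    with pytest.raises(ValueError, match="not justified"):
        randomization_test(s1, s2, native, exotic, B=9)


def test_randomization_exhaustive_enumeration(disjoint_freqs):
    """n=2+2 toy: p equals the exhaustive two-sided tail over all C(4,2)
    partitions, recomputed here by direct enumeration."""
    native, exotic = disjoint_freqs
    s1 = cross_offspring({"NN": 2}, label="a")
    s2 = cross_offspring({"PN": 2}, label="b")
    results = randomization_test(s1, s2, native, exotic, exhaustive=True)
    r_mm = next(r for r in results if r.parameter == "m_m")

    # independent oracle: estimate each side of every partition
    pooled = s1.genotypes + s2.genotypes
    from exoflow.markers import SampleTable
    def mm(genos, tag):
        t = SampleTable(tag, list(genos), stage="seedling")
        return estimate_rates(t, "seedling", native, exotic, compute_ci=False).rates.m_m
    diffs = []
    for left in combinations(range(4), 2):
        right = [i for i in range(4) if i not in left]
        ids = 0
        diffs.append(mm([pooled[i] for i in left], "l") - mm([pooled[i] for i in right], "r"))
    obs = mm(s1.genotypes, "s1") - mm(s2.genotypes, "s2")
    p_oracle = sum(abs(d) >= abs(obs) - 1e-12 for d in diffs) / len(diffs)
    assert r_mm.p_raw == pytest.approx(p_oracle)
    assert r_mm.n_permutations == 6


def test_randomization_label_order_invariance(disjoint_freqs):
    native, exotic = disjoint_freqs
    s1 = cross_offspring({"NN": 3, "PN": 1}, label="a")
    s2 = cross_offspring({"NN": 2, "PN": 2}, label="b")
    p12 = {r.parameter: r.p_raw
           for r in randomization_test(s1, s2, native, exotic, exhaustive=True)}
    p21 = {r.parameter: r.p_raw
           for r in randomization_test(s2, s1, native, exotic, exhaustive=True)}
    assert p12 == p21


def test_lr_test_nested_optimum_d_zero(disjoint_freqs):
    """Seedling multiset equal to the seed multiset with m_z = m_f = 0:
    the shared-rate optimum is attained, D = 0, p = 1."""
    native, exotic = disjoint_freqs
    seed_s = cross_offspring({"NN": 7, "PN": 3}, label="seeds", stage="seed")
    seedling = cross_offspring({"NN": 7, "PN": 3}, label="R1", stage="seedling")
    r = lr_test_seed_vs_seedling(seed_s, seedling, native, exotic)
    assert r.deviance == pytest.approx(0.0, abs=1e-6)
    assert r.p_raw == pytest.approx(1.0, abs=1e-4)


def test_deviance_chi2_quantile():
    assert deviance_p_value(3.841458820694124) == pytest.approx(0.050, abs=1e-6)
    assert deviance_p_value(0.0) == 1.0
    with pytest.raises(ValueError):
        deviance_p_value(-1.0)


def test_lr_test_grid_oracle(disjoint_freqs):
    """Deviance matches two independent fine-grid maximizations."""
    native, exotic = disjoint_freqs
    seed_s = cross_offspring({"NN": 30, "PN": 10}, label="seeds", stage="seed")
    seedling = cross_offspring({"NN": 36, "PN": 3, "PP": 1}, label="R1")
    r = lr_test_seed_vs_seedling(seed_s, seedling, native, exotic)

    counts_S, P_S = component_matrix(seed_s, native, exotic)
    counts_R, P_R = component_matrix(seedling, native, exotic)
    grid = np.arange(0.0, 1.0 + 1e-9, 0.001)

    def ll_seed_vec(m):
        W = np.column_stack([m, np.zeros_like(m), np.zeros_like(m), 1 - m])
        return _grid_logliks(counts_S, P_S, W)

    W3 = _grid_weights("seedling", step=0.02)
    ll_R_grid = _grid_logliks(counts_R, P_R, W3)
    ll_B_oracle = ll_seed_vec(grid).max() + ll_R_grid.max()
    # shared model: maximize over grid m_m with the best (m_z, m_f) per m_m
    ll_A_oracle = -np.inf
    for m in np.arange(0.0, 1.0 + 1e-9, 0.005):
        mask = np.abs(W3[:, 0] - m) < 1e-9
        if not mask.any():
            continue
        ll_A_oracle = max(
            ll_A_oracle,
            ll_R_grid[mask].max() + float(ll_seed_vec(np.array([m]))[0]),
        )
    D_oracle = -2 * (ll_A_oracle - ll_B_oracle)
    assert r.deviance == pytest.approx(D_oracle, abs=0.05)
    assert r.deviance >= D_oracle - 1e-6  # exact optimizers beat the grids


def test_deviance_scaling_law(disjoint_freqs):
    """Duplicating both samples' genotype counts k-fold scales D by k."""
    native, exotic = disjoint_freqs
    d = []
    for k in (1, 2):
        seed_s = cross_offspring({"NN": 30 * k, "PN": 10 * k}, label="s", stage="seed")
        seedling = cross_offspring({"NN": 38 * k, "PN": 2 * k}, label="r")
        d.append(lr_test_seed_vs_seedling(seed_s, seedling, native, exotic).deviance)
    assert d[1] == pytest.approx(2 * d[0], rel=1e-4)


def test_holm_textbook_cases():
    assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])
    assert holm_bonferroni([0.3]) == pytest.approx([0.3])
    assert holm_bonferroni([]) == []


def test_holm_matches_direct_definition():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=6)
    adjusted = holm_bonferroni(list(p))
    # brute-force step-down definition with cumulative-max monotonicity
    order = np.argsort(p)
    m = len(p)
    stepped = [(m - k) * p[order[k]] for k in range(m)]
    mono = np.minimum(1.0, np.maximum.accumulate(stepped))
    expected = np.empty(m)
    expected[order] = mono
    assert adjusted == pytest.approx(list(expected))
    assert all(a >= r for a, r in zip(adjusted, p))  # never decreases
    assert all(a <= min(1.0, m * r) + 1e-12 for a, r in zip(adjusted, p))  # <= Bonferroni
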