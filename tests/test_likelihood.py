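import math

import numpy as np
import pytest

from exoflow import (
    CrossTypeRates,
    FrequencyTable,
    estimate_rates,
    loglik_seed,
    loglik_seedling,
    profile_ci,
    relative_male_rate,
)
from exoflow.frequencies import component_matrix
from exoflow.likelihood import _grid_logliks, _grid_weights

from conftest import cross_offspring, random_instance


def test_loglik_constant_under_identical_panels(overlap_freqs):
    native, _ = overlap_freqs
    sample = cross_offspring({"NN": 5, "PN": 5})
    # replace haplotype/allele support so all genotypes live in one table
    native2 = FrequencyTable("p", {"H1": 0.5, "H2": 0.5},
                             {"L1": {"A": 0.5, "B": 0.5}})
    l1 = loglik_seedling(CrossTypeRates(0.1, 0.2, 0.3), sample, native2, native2)
    l2 = loglik_seedling(CrossTypeRates(0.7, 0.0, 0.1), sample, native2, native2)
    assert l1 == pytest.approx(l2, abs=1e-10)


def test_loglik_seedling_hand_value(disjoint_freqs):
    """6 native-type + 4 male-immigrant-type offspring, disjoint panels.

    Each genotype has probability 1 under its own cross type and 0 under
    the others, so l(0.4,0,0) = ln(0.6^6 * 0.4^4)."""
    native, exotic = disjoint_freqs
    sample = cross_offspring({"NN": 6, "PN": 4})
    ll = loglik_seedling(CrossTypeRates(0.4, 0.0, 0.0), sample, native, exotic)
    assert ll == pytest.approx(6 * math.log(0.6) + 4 * math.log(0.4))


def test_loglik_zero_support_is_minus_inf(disjoint_freqs):
    native, exotic = disjoint_freqs
    sample = cross_offspring({"NN": 6, "PN": 4})
    assert loglik_seedling(CrossTypeRates(0.0, 0.0, 0.0), sample, native, exotic) == -math.inf


def test_loglik_seed_hand_value(disjoint_freqs):
    native, exotic = disjoint_freqs
    sample = cross_offspring({"PN": 3, "NN": 7}, stage="seed")
    ll = loglik_seed(0.3, sample, native, exotic)
    assert ll == pytest.approx(3 * math.log(0.3) + 7 * math.log(0.7))
    ll0 = loglik_seed(0.0, cross_offspring({"NN": 5}, stage="seed"), native, exotic)
    assert ll0 == pytest.approx(0.0)  # all seeds NN-supported with Pr_NN = 1


def test_rates_off_simplex_rejected():
    with pytest.raises(ValueError, match="simplex"):
        CrossTypeRates(0.6, 0.3, 0.3)
    with pytest.raises(ValueError):
        CrossTypeRates(-0.1)
    with pytest.raises(ValueError, match="seed"):
        CrossTypeRates(0.1, 0.2, 0.0, stage="seed")


def test_estimate_rates_closed_form(disjoint_freqs):
    """Unambiguous assignment: the MLE is the multinomial proportion."""
    native, exotic = disjoint_freqs
    sample = cross_offspring({"NN": 60, "PN": 40})
    est = estimate_rates(sample, "seedling", native, exotic, compute_ci=False)
    assert est.rates.m_m == pytest.approx(0.400, abs=1e-9)
    assert est.rates.m_z == pytest.approx(0.0, abs=1e-9)
    assert est.rates.m_f == pytest.approx(0.0, abs=1e-9)
    assert est.identifiable


def test_estimate_rates_all_native_boundary(disjoint_freqs):
    native, exotic = disjoint_freqs
    sample = cross_offspring({"NN": 50})
    est = estimate_rates(sample, "seedling", native, exotic, compute_ci=True)
    assert (est.rates.m_m, est.rates.m_z, est.rates.m_f) == (0.0, 0.0, 0.0)
    assert est.ci_m_m[0] == 0.0  # boundary estimate clips the lower endpoint


def test_estimate_matches_grid_oracle(overlap_freqs):
    native, exotic = overlap_freqs
    rng = np.random.default_rng(7)
    sample, nat, exo = random_instance(rng, n_loci=2, n_off=60)
    counts, P = component_matrix(sample, nat, exo)
    est = estimate_rates(sample, "seedling", nat, exo, compute_ci=False)
    W = _grid_weights("seedling", step=0.01)
    grid_ll = _grid_logliks(counts, P, W)
    k = int(np.argmax(grid_ll))
    assert est.loglik >= grid_ll[k] - 1e-9
    assert np.allclose(est.rates.as_weights()[:3], W[k][:3], atol=0.01)


def test_unidentifiable_panels_flagged():
    table = FrequencyTable("p", {"H1": 0.5, "H2": 0.5}, {"L1": {"A": 0.5, "B": 0.5}})
    sample = cross_offspring({"NN": 10, "PN": 10})
    est = estimate_rates(sample, "seedling", table, table)
    assert not est.identifiable
    assert est.ci_m_m == (0.0, 1.0)
    assert est.ci_m_z == (0.0, 1.0)


def test_profile_ci_matches_binomial_oracle(disjoint_freqs):
    """Disjoint panels, n=100, m_hat=0.4: the profile interval equals the
    1-D binomial profile-likelihood interval computed by direct scan."""
    native, exotic = disjoint_freqs
    sample = cross_offspring({"NN": 60, "PN": 40})
    lo, hi = profile_ci(sample, "seedling", native, exotic, "m_m")
    # independent 1-D oracle
    grid = np.linspace(1e-6, 1 - 1e-6, 200001)
    ll = 40 * np.log(grid) + 60 * np.log1p(-grid)
    inside = grid[2 * (ll.max() - ll) <= 3.841458820694124]
    assert lo == pytest.approx(inside.min(), abs=5e-4)
    assert hi == pytest.approx(inside.max(), abs=5e-4)
    assert lo <= 0.4 <= hi


def test_profile_ci_flat_likelihood():
    table = FrequencyTable("p", {"H1": 1.0}, {"L1": {"A": 1.0}})
    sample = cross_offspring({"NN": 5})
    assert profile_ci(sample, "seedling", table, table, "m_m") == (0.0, 1.0)


def test_seed_stage_estimation(disjoint_freqs):
    native, exotic = disjoint_freqs
    sample = cross_offspring({"PN": 30, "NN": 70}, stage="seed")
    est = estimate_rates(sample, "seed", native, exotic)
    assert est.rates.m_m == pytest.approx(0.300, abs=1e-9)
    assert est.rates.m_z == est.rates.m_f == 0.0
    assert est.ci_m_m[0] < 0.3 < est.ci_m_m[1]


def test_relative_male_rate():
    assert relative_male_rate(CrossTypeRates(0.1, 0.05, 0.05)) == pytest.approx(1 / 9)
    assert relative_male_rate(CrossTypeRates(0.2, 0.0, 0.0)) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        relative_male_rate(CrossTypeRates(0.0, 0.5, 0.5))


def test_likelihood_invariant_under_allele_relabeling(overlap_freqs):
    native, exotic = overlap_freqs
    rng = np.random.default_rng(11)
    sample, nat, exo = random_instance(rng, n_loci=2, n_off=40)
    est1 = estimate_rates(sample, "seedling", nat, exo, compute_ci=False)

    relabel = lambda a: f"z{a}"
    def relabel_table(t):
        return FrequencyTable(
            t.population,
            {relabel(h): f for h, f in t.cp_freqs.items()},
            {l: {relabel(a): f for a, f in d.items()} for l, d in t.nuclear_freqs.items()},
        )
    from exoflow import MultilocusGenotype, SampleTable
    genos = [
        MultilocusGenotype(
            g.individual_id,
            None if g.cp_haplotype is None else relabel(g.cp_haplotype),
            {l: None if p is None else (relabel(p[0]), relabel(p[1]))
             for l, p in g.nuclear_genotypes.items()},
        )
        for g in sample.genotypes
    ]
    sample2 = SampleTable(sample.label, genos, stage=sample.stage)
    est2 = estimate_rates(sample2, "seedling", relabel_table(nat), relabel_table(exo),
                          compute_ci=False)
    assert est1.loglik == pytest.approx(est2.loglik, abs=1e-8)
    assert est1.rates.m_m == pytest.approx(est2.rates.m_m, abs=1e-6)
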