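import math
import numpy as np
import pytest

from exoflow import (
    SampleTable,
    diversity_summary,
    fst_amova,
    hwe_exact_test,
    jost_dest,
    null_allele_em,
    permutation_significance,
)

from conftest import make_genotype


def one_locus_sample(pairs, label="s", cps=None):
    genos = []
    for i, p in enumerate(pairs):
        cp = None if cps is None else cps[i]
        genos.append(make_genotype(f"{label}{i}", cp=cp, L1=p))
    return SampleTable(label, genos)


def test_diversity_hand_values():
    """One locus, genotypes {A/B, A/B, A/A, B/B}: H_o = 0.5,
    H_e = (2n/(2n-1))(1 - sum p^2) = (8/7)*0.5, F_IS = 1 - H_o/H_e."""
    s = one_locus_sample([("A", "B"), ("A", "B"), ("A", "A"), ("B", "B")])
    d = diversity_summary(s)
    assert d.H_o == pytest.approx(0.5)
    assert d.H_e == pytest.approx((8 / 7) * 0.5)
    assert d.F_IS == pytest.approx(1 - 0.5 / ((8 / 7) * 0.5))
    assert d.na == 2


def test_effective_haplotype_number():
    """Counts (5, 3, 2), N=10: nh_e = 1 / [ (5*4 + 3*2 + 2*1) / 90 ] = 90/28."""
    cps = ["H1"] * 5 + ["H2"] * 3 + ["H3"] * 2
    s = one_locus_sample([("A", "A")] * 10, cps=cps)
    d = diversity_summary(s)
    assert d.nh == 3
    assert d.nh_e == pytest.approx(90 / 28)


def test_monomorphic_sample():
    s = one_locus_sample([("A", "A")] * 6, cps=["H1"] * 6)
    d = diversity_summary(s)
    assert d.H_o == 0.0 and d.H_e == 0.0
    assert d.F_IS == 0.0  # undefined ratio defaults to 0
    assert d.na == d.na_e == 1.0
    assert d.nh == 1 and d.nh_e == 1.0


def _hwe_enumerate_p(nAA, nAB, nBB):
    """Exact conditional p for a 2-allele locus by complete enumeration."""
    n = nAA + nAB + nBB
    nA = 2 * nAA + nAB
    def logw(het):
        aa, bb = (nA - het) // 2, (2 * n - nA - het) // 2
        return (het * math.log(2)
                - math.lgamma(aa + 1) - math.lgamma(het + 1) - math.lgamma(bb + 1))
    hets = [h for h in range(min(nA, 2 * n - nA) + 1) if (nA - h) % 2 == 0]
    weights = {h: math.exp(logw(h)) for h in hets}
    total = sum(weights.values())
    obs = weights[nAB]
    return sum(w for w in weights.values() if w <= obs * (1 + 1e-12)) / total


def test_hwe_matches_enumeration():
    """(AA:1, AB:8, BB:1) — heterozygote excess; Monte-Carlo p within 3 MC
    standard errors of the complete-enumeration exact p."""
    pairs = [("A", "A")] + [("A", "B")] * 8 + [("B", "B")]
    steps = 40_000
    p_mc = hwe_exact_test(pairs, steps=steps, dememorization=4_000, seed=2)
    p_exact = _hwe_enumerate_p(1, 8, 1)
    se = math.sqrt(p_exact * (1 - p_exact) / steps) * 3  # ignores autocorrelation
    assert abs(p_mc - p_exact) < max(3 * se, 0.02)


def test_hwe_perfect_proportions():
    pairs = [("A", "A")] * 25 + [("A", "B")] * 50 + [("B", "B")] * 25
    p = hwe_exact_test(pairs, steps=20_000, dememorization=2_000, seed=3)
    assert p > 0.5


def test_hwe_monomorphic():
    with pytest.warns(UserWarning, match="monomorphic"):
        assert hwe_exact_test([("A", "A")] * 10) == 1.0


def test_hwe_deterministic_given_seed():
    pairs = [("A", "A")] * 6 + [("A", "B")] * 6 + [("B", "B")] * 4
    p1 = hwe_exact_test(pairs, steps=5_000, dememorization=500, seed=7)
    p2 = hwe_exact_test(pairs, steps=5_000, dememorization=500, seed=7)
    assert p1 == p2


def test_null_allele_em_hw_data():
    """Data simulated in exact HW proportions: both estimates near zero."""
    rng = np.random.default_rng(0)
    p = np.array([0.5, 0.3, 0.2])
    draws = rng.choice(3, size=(500, 2), p=p)
    pairs = [tuple(sorted((str(a), str(b)))) for a, b in draws]
    f_null, F = null_allele_em(pairs)
    assert f_null < 0.01
    assert abs(F) < 0.02


def test_null_allele_em_recovery():
    """True null allele at 0.1, no inbreeding: mean estimate within 0.03.

    Null-null homozygotes must enter as blanks: conditioned on amplified
    genotypes alone, the null-allele and inbreeding explanations of
    homozygote excess are exactly confounded at a single locus.
    """
    rng = np.random.default_rng(1)
    p_vis = np.array([0.5, 0.25, 0.1, 0.05])
    estimates = []
    for _ in range(10):
        freqs = np.array([*p_vis, 0.1])
        null = len(freqs) - 1
        pairs = []
        for a, b in rng.choice(len(freqs), size=(500, 2), p=freqs):
            if a == null and b == null:
                pairs.append(None)  # null homozygote scores as a blank
            elif a == null or b == null:
                vis = str(min(a, b))
                pairs.append((vis, vis))  # null heterozygote looks homozygous
            else:
                pairs.append(tuple(sorted((str(a), str(b)))))
        estimates.append(null_allele_em(pairs)[0])
    assert abs(np.mean(estimates) - 0.1) < 0.03


def test_null_allele_em_all_heterozygotes():
    pairs = [("A", "B")] * 20
    f_null, _ = null_allele_em(pairs)
    assert f_null == pytest.approx(0.0, abs=1e-6)


def test_fst_fixed_difference():
    a = one_locus_sample([("A", "A")] * 10, label="a", cps=["H1"] * 10)
    b = one_locus_sample([("B", "B")] * 10, label="b", cps=["H2"] * 10)
    assert fst_amova(a, b, "nuclear") == pytest.approx(1.0)
    assert fst_amova(a, b, "cp") == pytest.approx(1.0)
    assert jost_dest(a, b, "nuclear") == pytest.approx(1.0)
    assert jost_dest(a, b, "cp") == pytest.approx(1.0)


def test_fst_identical_samples():
    # the unbiased estimator carries O(1/N) noise around zero, so use n=100
    pairs = ([("A", "B")] * 5 + [("A", "A")] * 3 + [("B", "B")] * 2) * 10
    a = one_locus_sample(pairs, label="a")
    b = one_locus_sample(pairs, label="b")
    assert abs(fst_amova(a, b, "nuclear")) <= 0.01
    assert abs(jost_dest(a, b, "nuclear")) < 0.02


def test_fst_hand_amova():
    """1 locus, 2 pops of 2 diploids: symbolic sums-of-squares decomposition.

    Pop a copies: A,A,A,B; pop b copies: B,B,B,B (N=8, K=2).
    SS_total = (64 - (3^2 + 5^2)) / 16 = 30/16; SS_within = (16-10)/8 + 0.
    """
    a = one_locus_sample([("A", "A"), ("A", "B")], label="a")
    b = one_locus_sample([("B", "B"), ("B", "B")], label="b")
    ss_t = (64 - (9 + 25)) / 16
    ss_w = (16 - (9 + 1)) / 8
    ms_a, ms_w = (ss_t - ss_w) / 1, ss_w / 6
    n0 = (8 - (16 + 16) / 8) / 1
    sig_a = (ms_a - ms_w) / n0
    expected = sig_a / (sig_a + ms_w)
    assert fst_amova(a, b, "nuclear") == pytest.approx(expected, abs=1e-12)


def test_dest_limit_closed_form():
    """p = (0.9, 0.1) vs (0.1, 0.9) at large n approaches the uncorrected
    two-population closed form D = 2 (Ht - Hs) / (1 - Hs)."""
    n = 4000
    a = one_locus_sample([("A", "A")] * int(0.81 * n) + [("A", "B")] * int(0.18 * n)
                         + [("B", "B")] * int(0.01 * n), label="a")
    b = one_locus_sample([("B", "B")] * int(0.81 * n) + [("A", "B")] * int(0.18 * n)
                         + [("A", "A")] * int(0.01 * n), label="b")
    hs = 1 - (0.81 + 0.01)
    ht = 1 - 2 * 0.25
    expected = 2 * (ht - hs) / (1 - hs)
    assert jost_dest(a, b, "nuclear") == pytest.approx(expected, abs=0.01)


def test_permutation_significance():
    rng = np.random.default_rng(2)
    pairs = [tuple(sorted(rng.choice(["A", "B"], 2))) for _ in range(30)]
    a = one_locus_sample(pairs[:15], label="a")
    b = one_locus_sample(pairs[15:], label="b")
    # same generating process: large p
    p_same = permutation_significance("F_ST", a, b, "nuclear", n_perm=99, seed=4)
    assert p_same >= 0.05
    # fixed differences: observed statistic is the maximum over partitions
    c = one_locus_sample([("A", "A")] * 10, label="c")
    d = one_locus_sample([("B", "B")] * 10, label="d")
    p_fixed = permutation_significance("F_ST", c, d, "nuclear", n_perm=99, seed=4)
    assert p_fixed == pytest.approx(1 / 100)
    # label-order symmetry
    p_swap = permutation_significance("F_ST", d, c, "nuclear", n_perm=99, seed=4)
    assert p_fixed == p_swap
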