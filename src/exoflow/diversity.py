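"""Genetic diversity and differentiation summaries.

Per-sample diversity: observed/expected (unbiased) heterozygosity and F_IS
for nuclear loci, observed and effective numbers of chloroplast haplotypes
and nuclear alleles, plus an EM decomposition of homozygote excess into
null-allele frequency and inbreeding.  Between-sample differentiation:
two-level AMOVA F_ST and Jost's bias-corrected D_est for either marker
class, with permutation significance.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .markers import SampleTable

Pair = tuple[str, str]


@dataclass
class DiversitySummary:
    label: str
    n: int
    nh: int
    nh_e: float
    na: float
    na_e: float
    H_o: float
    H_e: float
    F_IS: float
    F_IS_prime: float
    f_null: float


@dataclass
class DifferentiationResult:
    pair: str
    marker_class: str  # "cp" | "nuclear"
    F_ST: float
    D_est: float
    p_F_ST: Optional[float] = None
    p_D_est: Optional[float] = None
    n_permutations: Optional[int] = None


# ------------------------------------------------------------- diversity ---

def _effective_number(counts: Sequence[int]) -> float:
    """Reciprocal of the unbiased homozygosity sum c(c-1)/(N(N-1)).

    With every category a singleton the estimator hits zero; the effective
    number is then capped at N (it cannot exceed the number of copies).
    """
    N = sum(counts)
    if N < 2:
        return float("nan")
    hom = sum(c * (c - 1) for c in counts) / (N * (N - 1))
    if hom <= 0:
        return float(N)
    return min(float(N), 1.0 / hom)


def diversity_summary(sample: SampleTable) -> DiversitySummary:
    """Diversity statistics for one sample (both marker classes)."""
    if sample.n == 0:
        raise ValueError("empty sample")
    haps = [g.cp_haplotype for g in sample.genotypes if g.cp_haplotype is not None]
    hap_counts = list(Counter(haps).values())
    nh = len(hap_counts)
    nh_e = _effective_number(hap_counts) if hap_counts else float("nan")

    loci = sample.loci()
    ho_l, he_l, na_l, nae_l = [], [], [], []
    locus_data: list[list[Optional[Pair]]] = []
    for locus in loci:
        with_blanks = [g.nuclear_genotypes.get(locus) for g in sample.genotypes]
        pairs = [p for p in with_blanks if p is not None]
        if 2 * len(pairs) < 2:
            warnings.warn(f"locus {locus!r}: fewer than 2 called copies; excluded")
            continue
        n_ind = len(pairs)
        allele_counts = Counter(a for p in pairs for a in p)
        tot = 2 * n_ind
        p2 = sum((c / tot) ** 2 for c in allele_counts.values())
        ho_l.append(sum(1 for a, b in pairs if a != b) / n_ind)
        he_l.append((tot / (tot - 1)) * (1.0 - p2))
        na_l.append(len(allele_counts))
        nae_l.append(_effective_number(list(allele_counts.values())))
        locus_data.append(with_blanks)

    H_o = float(np.mean(ho_l)) if ho_l else float("nan")
    H_e = float(np.mean(he_l)) if he_l else float("nan")
    F_IS = 0.0 if not he_l or H_e == 0 else 1.0 - H_o / H_e
    f_null, F_prime = joint_null_inbreeding(locus_data) if locus_data else (float("nan"),) * 2
    return DiversitySummary(
        label=sample.label, n=sample.n, nh=nh, nh_e=nh_e,
        na=float(np.mean(na_l)) if na_l else float("nan"),
        na_e=float(np.mean(nae_l)) if nae_l else float("nan"),
        H_o=H_o, H_e=H_e, F_IS=float(F_IS),
        F_IS_prime=float(F_prime), f_null=float(f_null),
    )


# -------------------------------------------------- null alleles and F_IS ---

def _null_em(
    loci_data: list[list[Optional[Pair]]], tol: float = 1e-8, max_iter: int = 200_000
) -> tuple[list[float], float]:
    """EM under an inbreeding + null-allele model with a shared F.

    Latent structure per individual and locus: an autozygosity indicator
    (probability F) and the true genotype.  Apparent homozygotes mix
    allozygous true homozygotes, autozygous homozygotes and visible/null
    heterozygotes; blank genotypes (None) are candidate null-null
    homozygotes.  The blank class is what separates null alleles from
    inbreeding — conditioned on amplified genotypes alone the two
    explanations of homozygote excess are exactly confounded at a single
    locus.  Technical amplification failures are not modelled separately,
    so null frequencies are upper bounds when dropout is present.
    """
    # class-count sufficient statistics per locus; E-steps only differ
    # across homozygote classes and the blank class, so each EM iteration
    # is O(#alleles) regardless of sample size
    per_locus = []
    n_total = 0
    for pairs in loci_data:
        hom: Counter = Counter()
        het_draws: Counter = Counter()
        blanks = 0
        for p in pairs:
            if p is None:
                blanks += 1
            elif p[0] == p[1]:
                hom[p[0]] += 1
            else:
                het_draws[p[0]] += 1
                het_draws[p[1]] += 1
        alleles = sorted(set(hom) | set(het_draws))
        if not alleles:
            raise ValueError("locus has no amplified genotypes")
        per_locus.append((
            alleles,
            np.array([hom[a] for a in alleles], dtype=float),
            np.array([het_draws[a] for a in alleles], dtype=float),
            blanks,
        ))
        n_total += len(pairs)
    # q[l][:k] visible allele frequencies, q[l][k] null frequency
    q = [np.full(len(a) + 1, 1.0 / (len(a) + 1)) for a, *_ in per_locus]
    F = 0.05
    for _ in range(max_iter):
        auto_sum = 0.0
        new_q = []
        max_delta = 0.0
        for (alleles, homc, hetd, blanks), ql in zip(per_locus, q):
            k = len(alleles)
            r = ql[k]
            w_allo = (1.0 - F) * ql[:k] ** 2
            w_auto = F * ql[:k]
            w_null = (1.0 - F) * 2.0 * ql[:k] * r
            z = np.maximum(w_allo + w_auto + w_null, 1e-300)
            r_allo, r_auto, r_null = w_allo / z, w_auto / z, w_null / z
            draws = hetd + homc * (2.0 * r_allo + r_auto + r_null)
            null_draws = float(homc @ r_null)
            auto_sum += float(homc @ r_auto)
            if blanks:  # blank: null-null, allozygous or autozygous
                zb = (1.0 - F) * r * r + F * r
                b_auto = (F * r / zb) if zb > 0 else 0.0
                null_draws += blanks * (2.0 * (1.0 - b_auto) + b_auto)
                auto_sum += blanks * b_auto
            nq = np.append(draws, null_draws)
            nq /= nq.sum()
            max_delta = max(max_delta, float(np.abs(nq - ql).max()))
            new_q.append(nq)
        new_F = min(1.0 - 1e-12, max(0.0, auto_sum / n_total)) if n_total else 0.0
        max_delta = max(max_delta, abs(new_F - F))
        q, F = new_q, new_F
        if max_delta < tol:
            break
    else:
        raise RuntimeError(f"null-allele EM did not converge in {max_iter} iterations")
    return [float(ql[-1]) for ql in q], F


def null_allele_em(locus_genotypes: list[Optional[Pair]]) -> tuple[float, float]:
    """Jointly estimate null-allele frequency and inbreeding at one locus.

    ``None`` entries are unamplified individuals, treated as candidate
    null-null homozygotes.
    """
    if not locus_genotypes:
        raise ValueError("no genotypes")
    nulls, F = _null_em([locus_genotypes])
    return nulls[0], F


def joint_null_inbreeding(loci_data: list[list[Optional[Pair]]]) -> tuple[float, float]:
    """Mean null frequency across loci and the shared inbreeding coefficient."""
    nulls, F = _null_em(loci_data)
    return float(np.mean(nulls)), F


# ------------------------------------------------------------- HWE test ----

def _log_table_weight(counts: dict[Pair, int]) -> float:
    """log of the conditional table probability up to the allele-count constant."""
    h = sum(c for (a, b), c in counts.items() if a != b)
    return h * math.log(2.0) - sum(math.lgamma(c + 1) for c in counts.values())


def hwe_exact_test(
    locus_genotypes: list[Pair],
    steps: int = 100_000,
    dememorization: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions.

    Markov chain on genotype tables with the observed allele counts using
    allele-switch proposals; the p-value is the chain fraction of tables no
    more probable than the observed one (probability-ordering criterion).
    Deterministic given ``seed``.
    """
    genos = [tuple(sorted(g)) for g in locus_genotypes]
    alleles = sorted({a for g in genos for a in g})
    if len(alleles) < 2:
        warnings.warn("monomorphic locus: HWE p-value is 1 by convention")
        return 1.0
    counts: Counter = Counter(genos)
    state = list(genos)
    logw_obs = _log_table_weight(counts)
    logw = logw_obs
    rng = np.random.default_rng(seed)
    n = len(state)
    below = 0
    pick = rng.integers(0, n, size=2 * (steps + dememorization))
    flip = rng.random(size=steps + dememorization)
    accept_u = rng.random(size=steps + dememorization)

    def _flips(g1, g2):
        (a, b), (c, d) = g1, g2
        return (
            (tuple(sorted((a, d))), tuple(sorted((c, b)))),
            (tuple(sorted((a, c))), tuple(sorted((b, d)))),
        )

    ln2 = math.log(2.0)
    for t in range(steps + dememorization):
        i, j = pick[2 * t], pick[2 * t + 1]
        if i != j:
            old = (state[i], state[j])
            props = _flips(*old)
            new = props[0] if flip[t] < 0.5 else props[1]
            if new != old:
                # chain over labeled individuals: target 2^H per labeled
                # state, plus a Hastings term for coincident flip proposals
                d_het = sum(g[0] != g[1] for g in new) - sum(
                    g[0] != g[1] for g in old
                )
                old_sw, new_sw = (old[1], old[0]), (new[1], new[0])
                fwd = sum(p == new for p in props) + sum(
                    p == new_sw for p in _flips(*old_sw)
                )
                rev = sum(p == old for p in _flips(*new)) + sum(
                    p == old_sw for p in _flips(*new_sw)
                )
                log_alpha = (
                    -math.inf if rev == 0
                    else d_het * ln2 + math.log(rev) - math.log(fwd)
                )
                if math.log(accept_u[t] + 1e-300) < log_alpha:
                    # update the table statistic used for probability ordering
                    for g in old:
                        logw -= ln2 if g[0] != g[1] else 0.0
                        logw += math.log(counts[g])
                        counts[g] -= 1
                    for g in new:
                        counts[g] += 1
                        logw += ln2 if g[0] != g[1] else 0.0
                        logw -= math.log(counts[g])
                    state[i], state[j] = new
        if t >= dememorization and logw <= logw_obs + 1e-9:
            below += 1
    return below / steps


# ------------------------------------------------------- differentiation ---

def _copy_counts(sample: SampleTable, marker_class: str) -> dict[str, Counter]:
    """Category counts of gene copies per locus ('cp_hap' for haplotypes)."""
    if marker_class == "cp":
        return {"cp_hap": Counter(
            g.cp_haplotype for g in sample.genotypes if g.cp_haplotype is not None
        )}
    out: dict[str, Counter] = {}
    for locus in sample.loci():
        c: Counter = Counter()
        for g in sample.genotypes:
            pair = g.nuclear_genotypes.get(locus)
            if pair is not None:
                c.update(pair)
        out[locus] = c
    return out


def fst_amova(a: SampleTable, b: SampleTable, marker_class: str = "nuclear") -> float:
    """Two-level AMOVA F_ST (among/within samples, identity metric).

    Variance components are summed across loci before forming the ratio.
    Diploid nuclear data enter as gene copies; chloroplast haplotypes are
    haploid.
    """
    ca, cb = _copy_counts(a, marker_class), _copy_counts(b, marker_class)
    shared = [l for l in ca if l in cb and (len((ca[l] + cb[l])) > 1)]
    if not shared:
        raise ValueError("no shared polymorphic locus between the two samples")
    sig_a = sig_w = 0.0
    for locus in shared:
        pops = [ca[locus], cb[locus]]
        Nk = [sum(c.values()) for c in pops]
        if min(Nk) == 0:
            continue
        N = sum(Nk)
        total = pops[0] + pops[1]
        ss_t = (N * N - sum(v * v for v in total.values())) / (2.0 * N)
        ss_w = sum(
            (nk * nk - sum(v * v for v in c.values())) / (2.0 * nk)
            for c, nk in zip(pops, Nk)
        )
        ss_a = ss_t - ss_w
        df_a, df_w = 1, N - 2
        if df_w <= 0:
            continue
        ms_a, ms_w = ss_a / df_a, ss_w / df_w
        n0 = (N - sum(nk * nk for nk in Nk) / N) / df_a
        sig_a += (ms_a - ms_w) / n0
        sig_w += ms_w
    denom = sig_a + sig_w
    if denom == 0:
        return 0.0
    return sig_a / denom


def jost_dest(a: SampleTable, b: SampleTable, marker_class: str = "nuclear") -> float:
    """Jost's D_est for two samples, bias-corrected for sample size.

    Per locus, D = (k/(k-1)) (H_T - H_S)/(1 - H_S) with k = 2 samples,
    using the harmonic-mean-size-corrected within-sample gene diversity
    H_S = (n~/(n~-1)) (1 - mean_k sum p_k^2) and the matching total
    diversity H_T = 1 - sum pbar^2 + H_S/(2 n~ k), n~ counted in gene
    copies.  The multilocus value is the arithmetic mean over loci.
    """
    ca, cb = _copy_counts(a, marker_class), _copy_counts(b, marker_class)
    shared = [l for l in ca if l in cb]
    vals = []
    for locus in shared:
        pops = [ca[locus], cb[locus]]
        Nk = [sum(c.values()) for c in pops]
        if min(Nk) < 2:
            continue
        n_tilde = 2.0 / (1.0 / Nk[0] + 1.0 / Nk[1])
        cats = set(pops[0]) | set(pops[1])
        p = [{x: c[x] / nk for x in cats} for c, nk in zip(pops, Nk)]
        mean_p2 = np.mean([sum(v * v for v in pk.values()) for pk in p])
        Hs = (n_tilde / (n_tilde - 1.0)) * (1.0 - mean_p2)
        pbar = {x: 0.5 * (p[0][x] + p[1][x]) for x in cats}
        Ht = 1.0 - sum(v * v for v in pbar.values()) + Hs / (2.0 * n_tilde * 2.0)
        if Hs >= 1.0:
            warnings.warn(f"locus {locus!r}: H_S estimate is 1; locus skipped")
            continue
        vals.append(2.0 * (Ht - Hs) / (1.0 - Hs))
    if not vals:
        raise ValueError("no usable locus for D_est")
    return float(np.mean(vals))


_STATS = {"F_ST": fst_amova, "D_est": jost_dest}


def permutation_significance(
    statistic: str,
    a: SampleTable,
    b: SampleTable,
    marker_class: str = "nuclear",
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for a differentiation statistic.

    Whole multilocus genotypes are permuted between the two samples;
    p = (r+1)/(n_perm+1) with r the count of permuted statistics >= observed.
    """
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fn = _STATS[statistic]
    obs = fn(a, b, marker_class)
    pooled = a.genotypes + b.genotypes
    na = a.n
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        ga = SampleTable("pa", [pooled[i] for i in perm[:na]])
        gb = SampleTable("pb", [pooled[i] for i in perm[na:]])
        try:
            stat = fn(ga, gb, marker_class)
        except ValueError:
            continue
        if stat >= obs - 1e-12:
            r += 1
    return (r + 1) / (n_perm + 1)


def differentiation(
    a: SampleTable,
    b: SampleTable,
    marker_class: str = "nuclear",
    n_perm: int = 10_000,
    seed: int = 0,
) -> DifferentiationResult:
    """F_ST and D_est with permutation significance for one sample pair."""
    return DifferentiationResult(
        pair=f"{a.label} - {b.label}",
        marker_class=marker_class,
        F_ST=fst_amova(a, b, marker_class),
        D_est=jost_dest(a, b, marker_class),
        p_F_ST=permutation_significance("F_ST", a, b, marker_class, n_perm, seed),
        p_D_est=permutation_significance("D_est", a, b, marker_class, n_perm, seed + 1),
        n_permutations=n_perm,
    )
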