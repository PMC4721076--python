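"""Two-sample tests for temporal change in exotic introgression.

Sequential offspring samples from the same recruitment cohort are compared
to test the null hypothesis that the proportion of exotic immigrants stays
constant over time (i.e., no differential early survival of cross types).

* seedling vs seedling — a nonparametric randomization test: the pooled
  n1+n2 seedlings are reallocated at random into two samples of the
  original sizes, gene-flow rates are re-estimated on each side, and the
  observed per-parameter difference is referred to the null distribution of
  differences.
* seed vs seedling — the two samples follow different models (the seed
  mixture has no zygotic/female components), so random reallocation is not
  justified; a likelihood-ratio test of a shared male gametic rate against
  stage-specific rates is used instead, with deviance referred to
  chi-square with one degree of freedom.

Raw p-values across a battery of comparisons are adjusted with the
Holm-Bonferroni step-down correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .frequencies import FrequencyTable, component_matrix
from .likelihood import (
    _estimate_from_matrix,
    _mixture_loglik,
    em_batch,
    maximize_weights,
)
from .markers import SampleTable

_PARAMS = ("m_m", "m_z", "m_f")


@dataclass
class TestResult:
    comparison: str
    parameter: str
    observed_diff: float
    p_raw: float
    method: str  # "randomization" | "likelihood_ratio"
    p_adjusted: Optional[float] = None
    n_permutations: Optional[int] = None
    deviance: Optional[float] = None
    loglik_shared: Optional[float] = None
    loglik_free: Optional[float] = None
    seed: Optional[int] = None
    boundary_warning: bool = False


def _rates_vector(counts, P, stage="seedling") -> np.ndarray:
    est = _estimate_from_matrix(counts, P, stage, compute_ci=False, fast=True)
    return np.array([est.rates.m_m, est.rates.m_z, est.rates.m_f])


def randomization_test(
    sample1: SampleTable,
    sample2: SampleTable,
    native: FrequencyTable,
    exotic: FrequencyTable,
    B: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[TestResult]:
    """Randomization test of equal gene-flow rates in two seedling samples.

    Two-sided p per parameter with the (r+1)/(B+1) convention, the observed
    allocation counting as one replicate.  ``exhaustive=True`` enumerates
    every partition of the pooled sample instead of sampling ``B`` of them
    (only sensible for tiny samples).
    """
    for s in (sample1, sample2):
        if s.stage == "seed":
            raise ValueError(
                f"sample {s.label!r} is a pre-dispersal seed sample: random "
                "reallocation is not justified across stages; use "
                "lr_test_seed_vs_seedling instead"
            )
    if B < 1 and not exhaustive:
        raise ValueError("B must be >= 1")
    n1, n2 = sample1.n, sample2.n
    # per-individual component rows are stage-independent; compute once
    _, P1 = component_matrix(sample1, native, exotic, collapse=False)
    _, P2 = component_matrix(sample2, native, exotic, collapse=False)
    pooled = np.vstack([P1, P2])
    ones1, ones2 = np.ones(n1), np.ones(n2)

    obs = _rates_vector(ones1, P1) - _rates_vector(ones2, P2)

    if exhaustive:
        sides = [np.array(left) for left in combinations(range(n1 + n2), n1)]
        S = np.zeros((len(sides), n1 + n2))
        for r, li in enumerate(sides):
            S[r, li] = 1.0
    else:
        rng = np.random.default_rng(seed)
        S = np.zeros((B, n1 + n2))
        for r in range(B):
            S[r, rng.permutation(n1 + n2)[:n1]] = 1.0
    # re-estimate both sides of every replicate with one batched EM each
    W1 = em_batch(pooled, S)
    W2 = em_batch(pooled, 1.0 - S)
    diffs = W1[:, :3] - W2[:, :3]
    exceed = (np.abs(diffs) >= np.abs(obs) - 1e-12).sum(axis=0)
    if exhaustive:
        # the observed partition is one of the enumerated ones
        p = exceed / S.shape[0]
        n_perm = S.shape[0]
    else:
        p = (exceed + 1) / (B + 1)
        n_perm = B

    comparison = f"{sample1.label} vs {sample2.label}"
    return [
        TestResult(
            comparison=comparison,
            parameter=_PARAMS[k],
            observed_diff=float(obs[k]),
            p_raw=float(min(1.0, p[k])),
            method="randomization",
            n_permutations=n_perm,
            seed=None if exhaustive else seed,
        )
        for k in range(3)
    ]


def lr_test_seed_vs_seedling(
    seed_sample: SampleTable,
    seedling_sample: SampleTable,
    native: FrequencyTable,
    exotic: FrequencyTable,
) -> TestResult:
    """Likelihood-ratio test of equal male gametic rate in a seed/seedling pair.

    Model A shares m_m across the two samples (the seedling sample keeps
    free m_z, m_f); model B adds a stage-specific male rate.  The deviance
    D = -2 ln(L_A / L_B) is referred to chi-square with 1 df.
    """
    counts_S, P_S = component_matrix(seed_sample, native, exotic)
    counts_R, P_R = component_matrix(seedling_sample, native, exotic)

    def seed_ll(m: float) -> float:
        return _mixture_loglik(np.array([m, 0.0, 0.0, 1.0 - m]), counts_S, P_S)

    def joint_profile(m: float) -> float:
        _, ll_R = maximize_weights(counts_R, P_R, fixed={0: m}, fast=True)
        return ll_R + seed_ll(m)

    # free model: the joint likelihood factorizes over the two samples
    w_R, ll_R_free = maximize_weights(counts_R, P_R)
    w_S, ll_S_free = maximize_weights(counts_S, P_S, fixed={1: 0.0, 2: 0.0})
    ll_B = ll_R_free + ll_S_free

    # shared model: 1-D concave profile over the common m_m
    grid = np.linspace(0.0, 1.0, 101)
    vals = np.array([joint_profile(m) for m in grid])
    if not np.isfinite(vals).any():
        raise RuntimeError("shared-rate likelihood has no support; check panels")
    k = int(np.nanargmax(np.where(np.isfinite(vals), vals, -np.inf)))
    lo, hi = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    res = minimize_scalar(
        lambda m: -joint_profile(m), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7},
    )
    ll_A = max(float(-res.fun), float(vals[k]))

    D = max(0.0, -2.0 * (ll_A - ll_B))
    p = float(chi2.sf(D, df=1))
    boundary = bool(
        min(w_S[0], w_R[0]) < 1e-9 or w_R[1] < 1e-9 or w_R[2] < 1e-9
    )
    return TestResult(
        comparison=f"{seed_sample.label} vs {seedling_sample.label}",
        parameter="m_m",
        observed_diff=float(w_S[0] - w_R[0]),
        p_raw=p,
        method="likelihood_ratio",
        deviance=D,
        loglik_shared=ll_A,
        loglik_free=ll_B,
        boundary_warning=boundary,
    )


def deviance_p_value(D: float) -> float:
    """Upper-tail chi-square(1 df) p-value for a deviance statistic."""
    if D < -1e-8:
        raise ValueError("deviance must be non-negative")
    return float(chi2.sf(max(0.0, D), df=1))


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values, in input order."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0.0 <= x <= 1.0 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def adjust_results(results: list[TestResult]) -> list[TestResult]:
    """Fill ``p_adjusted`` across one family of test results (in place)."""
    adj = holm_bonferroni([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results
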