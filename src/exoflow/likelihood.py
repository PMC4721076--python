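"""Maximum-likelihood estimation of exotic gene-flow components.

The offspring sample is modelled as a finite mixture over the four parental
cross types.  For a seedling sample the mixture weights are the male
gametic rate m_m (native mother x exotic father), the zygotic rate m_z
(both parents exotic), the female gametic rate m_f (exotic mother x native
father) and the native residual 1 - m_m - m_z - m_f.  The log-likelihood

    l(m) = sum_G n_G * ln[ m_m Pr_PN(G) + m_z Pr_PP(G) + m_f Pr_NP(G)
                           + (1 - m_m - m_z - m_f) Pr_NN(G) ]

is concave in the weight vector (log of an affine function), so the global
maximizer on the simplex is found reliably; we combine a coarse grid scan,
a multi-start expectation-maximization pass that supports clamped
coordinates (used for profiling), and a constrained quasi-Newton polish.

Seed samples collected before dispersal necessarily have native mothers, so
m_z and m_f are structurally zero and only m_m is estimated.

Confidence intervals are profile-likelihood intervals: the set of parameter
values whose profiled deviance from the maximum stays below the 95%
chi-square(1 df) quantile 3.841, with endpoints located by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .frequencies import FrequencyTable, component_matrix
from .markers import SampleTable

CHI2_1_95 = 3.841458820694124  # chi-square 1 df, 95% quantile
_PARAM_NAMES = ("m_m", "m_z", "m_f")


@dataclass
class CrossTypeRates:
    """Gene-flow rate vector on the 3-simplex (plus the native residual)."""

    m_m: float
    m_z: float = 0.0
    m_f: float = 0.0
    stage: str = "seedling"

    def __post_init__(self):
        for name in _PARAM_NAMES:
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.m_m + self.m_z + self.m_f > 1 + 1e-9:
            raise ValueError("rates exceed the simplex: m_m + m_z + m_f > 1")
        if self.stage not in ("seed", "seedling"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "seed" and (self.m_z != 0.0 or self.m_f != 0.0):
            raise ValueError("seed-stage samples have m_z = m_f = 0 structurally")

    def as_weights(self) -> np.ndarray:
        """Mixture weights in component order (PN, PP, NP, NN)."""
        return np.array([self.m_m, self.m_z, self.m_f,
                         1.0 - self.m_m - self.m_z - self.m_f])


@dataclass
class GeneFlowEstimate:
    rates: CrossTypeRates
    loglik: float
    ci_m_m: Optional[tuple[float, float]] = None
    ci_m_z: Optional[tuple[float, float]] = None
    ci_m_f: Optional[tuple[float, float]] = None
    m_m_relative: Optional[float] = None
    identifiable: bool = True


def _mixture_loglik(w: np.ndarray, counts: np.ndarray, P: np.ndarray) -> float:
    mix = P @ w
    if np.any(mix <= 0.0):
        return -math.inf
    return float(counts @ np.log(mix))


def loglik_seedling(
    rates: CrossTypeRates,
    sample: SampleTable,
    native: FrequencyTable,
    exotic: FrequencyTable,
) -> float:
    """Seedling-sample log-likelihood at the given rates (-inf on zero support)."""
    if sample.n == 0:
        raise ValueError("empty sample")
    counts, P = component_matrix(sample, native, exotic)
    return _mixture_loglik(rates.as_weights(), counts, P)


def loglik_seed(
    m_m: float,
    sample: SampleTable,
    native: FrequencyTable,
    exotic: FrequencyTable,
) -> float:
    """Pre-dispersal seed-sample log-likelihood: mixture of PN and NN only."""
    rates = CrossTypeRates(m_m=m_m, stage="seed")
    if sample.n == 0:
        raise ValueError("empty sample")
    counts, P = component_matrix(sample, native, exotic)
    return _mixture_loglik(rates.as_weights(), counts, P)


# ---------------------------------------------------------------- solver ---

def _em_fixed(
    counts: np.ndarray,
    P: np.ndarray,
    w0: np.ndarray,
    fixed: dict[int, float],
    tol: float = 1e-12,
    max_iter: int = 4000,
) -> np.ndarray:
    """EM for mixture weights with some coordinates clamped.

    The M-step renormalizes the free expected counts to the free budget,
    which keeps the monotone-ascent property of EM on the restricted face.
    """
    free = np.array([i not in fixed for i in range(P.shape[1])])
    budget = 1.0 - sum(fixed.values())
    w = w0.copy()
    for i, v in fixed.items():
        w[i] = v
    if budget <= 0:
        w[free] = 0.0
        return w
    # keep the start interior on the free face
    w[free] = np.maximum(w[free], 1e-9)
    w[free] *= budget / w[free].sum()
    for _ in range(max_iter):
        mix = P @ w
        if np.any(mix <= 0.0):
            break
        E = ((counts / mix)[:, None] * P * w).sum(axis=0)
        s = E[free].sum()
        if s <= 0:
            w[free] = budget / free.sum()
            break
        new_free = budget * E[free] / s
        delta = np.abs(new_free - w[free]).max()
        w[free] = new_free
        if delta < tol:
            break
    return w


def _polish(counts, P, w_start, fixed) -> np.ndarray:
    """SLSQP refinement; lands exactly on boundary zeros EM only approaches."""
    free_idx = [i for i in range(P.shape[1]) if i not in fixed]
    budget = 1.0 - sum(fixed.values())
    if not free_idx or budget <= 0:
        return w_start

    def build(x):
        w = w_start.copy()
        for i, v in fixed.items():
            w[i] = v
        w[free_idx] = x
        return w

    def neg_ll(x):
        mix = P @ build(x)
        bad = mix <= 0.0
        if np.any(bad & (counts > 0)):
            return 1e300
        mix = np.where(bad, 1.0, mix)
        return -float(counts @ np.log(mix))

    res = minimize(
        neg_ll,
        w_start[free_idx],
        method="SLSQP",
        bounds=[(0.0, budget)] * len(free_idx),
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - budget}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    w = build(np.clip(res.x, 0.0, budget))
    # renormalize the free block exactly
    s = w[free_idx].sum()
    if s > 0:
        w[free_idx] *= budget / s
    return w


def _snap_boundary(counts, P, w, fixed, eps=1e-7) -> np.ndarray:
    """Set near-zero free weights exactly to zero when that does not hurt."""
    w = w.copy()
    free_idx = [i for i in range(P.shape[1]) if i not in fixed]
    small = [i for i in free_idx if 0 < w[i] < eps]
    if not small:
        return w
    trial = w.copy()
    trial[small] = 0.0
    budget = 1.0 - sum(fixed.values())
    s = trial[free_idx].sum()
    if s > 0:
        trial[free_idx] *= budget / s
    if _mixture_loglik(trial, counts, P) >= _mixture_loglik(w, counts, P) - 1e-9:
        return trial
    return w


def _fixed_starts(fixed: dict[int, float]) -> list[np.ndarray]:
    """Vertices, centroid and edge midpoints of the 4-simplex (blended inward)."""
    pts = [np.eye(4)[i] for i in range(4)]
    pts.append(np.full(4, 0.25))
    for i in range(4):
        for j in range(i + 1, 4):
            p = np.zeros(4)
            p[i] = p[j] = 0.5
            pts.append(p)
    return [0.9 * p + 0.1 * np.full(4, 0.25) for p in pts]


def maximize_weights(
    counts: np.ndarray,
    P: np.ndarray,
    fixed: Optional[dict[int, float]] = None,
    fast: bool = False,
) -> tuple[np.ndarray, float]:
    """Global maximizer of the mixture log-likelihood over the (clamped) simplex.

    ``fast=True`` trades the multi-start sweep for a single EM run from the
    centroid plus one polish — used inside randomization replicates, where
    concavity guarantees the same optimum.
    """
    fixed = dict(fixed or {})
    starts = [np.full(4, 0.25)] if fast else _fixed_starts(fixed)
    best_w, best_ll = None, -math.inf
    for w0 in starts:
        w = _em_fixed(counts, P, w0, fixed, max_iter=300 if fast else 4000)
        w = _polish(counts, P, w, fixed)
        w = _snap_boundary(counts, P, w, fixed)
        ll = _mixture_loglik(w, counts, P)
        if (
            best_w is None
            or ll > best_ll + 1e-9
            or (ll > best_ll - 1e-9 and tuple(w[:3]) < tuple(best_w[:3]))
        ):
            best_w, best_ll = w, ll
    assert best_w is not None
    return best_w, best_ll


def em_batch(
    P: np.ndarray,
    S: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-11,
) -> np.ndarray:
    """Batched EM: one mixture fit per row of the membership matrix ``S``.

    ``P`` holds per-individual component probabilities (n x 4); ``S`` is a
    (B x n) 0/1 matrix selecting the individuals of each replicate sample.
    All replicates share the same component matrix, so every EM iteration
    for the whole batch is two dense matrix products.  Concavity of each
    replicate's log-likelihood makes the uniform start sufficient.
    """
    B = S.shape[0]
    W = np.full((B, 4), 0.25)
    for _ in range(max_iter):
        M = W @ P.T  # (B, n) mixture density per individual
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(S > 0, S / M, 0.0)
        E = (R @ P) * W
        s = E.sum(axis=1, keepdims=True)
        W_new = E / np.where(s > 0, s, 1.0)
        delta = np.abs(W_new - W).max()
        W = W_new
        if delta < tol:
            break
    # land boundary components exactly on zero
    W[W < 1e-8] = 0.0
    W /= W.sum(axis=1, keepdims=True)
    return W


def _grid_weights(stage: str, step: float = 0.1) -> np.ndarray:
    """Coarse simplex grid in weight space (1-D for seed stage)."""
    vals = np.arange(0.0, 1.0 + step / 2, step)
    if stage == "seed":
        return np.array([[m, 0.0, 0.0, 1.0 - m] for m in vals])
    pts = []
    for a in vals:
        for b in vals:
            for c in vals:
                if a + b + c <= 1.0 + 1e-12:
                    pts.append([a, b, c, max(0.0, 1.0 - a - b - c)])
    return np.array(pts)


def _grid_logliks(counts, P, W) -> np.ndarray:
    mix = W @ P.T  # (grid, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(mix > 0, np.log(np.where(mix > 0, mix, 1.0)), -np.inf) @ counts
    return ll


def estimate_rates(
    sample: SampleTable,
    stage: str,
    native: FrequencyTable,
    exotic: FrequencyTable,
    compute_ci: bool = True,
    level: float = 0.95,
    fast: bool = False,
) -> GeneFlowEstimate:
    """Maximum-likelihood gene-flow rates with profile-likelihood intervals.

    ``stage='seed'`` restricts the model to the pre-dispersal mixture (m_m
    only); ``stage='seedling'`` estimates all three components.  Degenerate
    reference panels (indistinguishable populations) yield a flat
    likelihood; the estimate is then flagged ``identifiable=False`` with
    intervals spanning [0, 1] rather than raising.
    """
    if sample.n == 0:
        raise ValueError("empty offspring sample")
    counts, P = component_matrix(sample, native, exotic)
    return _estimate_from_matrix(counts, P, stage, compute_ci, level, fast)


def _estimate_from_matrix(
    counts, P, stage, compute_ci=True, level=0.95, fast=False
) -> GeneFlowEstimate:
    structural = {1: 0.0, 2: 0.0} if stage == "seed" else {}
    probe = _grid_logliks(counts, P, _grid_weights(stage))
    finite = probe[np.isfinite(probe)]
    if finite.size and (finite.max() - finite.min()) < 1e-8:
        rates = CrossTypeRates(0.0, 0.0, 0.0, stage=stage)
        full = (0.0, 1.0)
        return GeneFlowEstimate(
            rates, float(finite.max()), full, full, full,
            m_m_relative=None, identifiable=False,
        )
    w, ll = maximize_weights(counts, P, structural, fast=fast)
    rates = CrossTypeRates(
        m_m=float(w[0]), m_z=float(w[1]), m_f=float(w[2]), stage=stage
    )
    est = GeneFlowEstimate(rates, ll, identifiable=True)
    if stage == "seedling" and rates.m_z + rates.m_f < 1.0 - 1e-12:
        est.m_m_relative = relative_male_rate(rates)
    if compute_ci:
        # concavity: the clamped single-start EM reaches the same profile
        # optimum as the multi-start sweep, at a fraction of the cost
        est.ci_m_m = _profile_interval(counts, P, w, ll, 0, structural, level, True)
        if stage == "seedling":
            est.ci_m_z = _profile_interval(counts, P, w, ll, 1, structural, level, True)
            est.ci_m_f = _profile_interval(counts, P, w, ll, 2, structural, level, True)
    return est


def profile_ci(
    sample: SampleTable,
    stage: str,
    native: FrequencyTable,
    exotic: FrequencyTable,
    param: str,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% profile-likelihood interval for one gene-flow component."""
    if param not in _PARAM_NAMES:
        raise ValueError(f"param must be one of {_PARAM_NAMES}")
    if stage == "seed" and param != "m_m":
        raise ValueError("seed-stage model only has parameter m_m")
    counts, P = component_matrix(sample, native, exotic)
    structural = {1: 0.0, 2: 0.0} if stage == "seed" else {}
    probe = _grid_logliks(counts, P, _grid_weights(stage))
    finite = probe[np.isfinite(probe)]
    if finite.size and (finite.max() - finite.min()) < 1e-8:
        return (0.0, 1.0)
    w, ll = maximize_weights(counts, P, structural)
    return _profile_interval(counts, P, w, ll, _PARAM_NAMES.index(param), structural, level)


def _profile_interval(
    counts, P, w_hat, ll_max, idx, structural, level=0.95, fast=False, tol=1e-4
):
    from scipy.stats import chi2

    thr = chi2.ppf(level, df=1) if level != 0.95 else CHI2_1_95

    others_fixed = {i: v for i, v in structural.items() if i != idx}
    hi_bound = 1.0 - sum(others_fixed.values())

    def deviance(theta: float) -> float:
        fixed = dict(others_fixed)
        fixed[idx] = theta
        _, ll = maximize_weights(counts, P, fixed, fast=fast)
        return 2.0 * (ll_max - ll)

    mhat = float(w_hat[idx])

    def bisect(lo, hi, lo_in):
        # dev(lo side inside) <= thr < dev(outside); find the crossing
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if hi - lo < tol:
                break
            if (deviance(mid) <= thr) == lo_in:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lower = 0.0 if deviance(0.0) <= thr else bisect(0.0, mhat, lo_in=False)
    upper = hi_bound if deviance(hi_bound) <= thr else bisect(mhat, hi_bound, lo_in=True)
    return (max(0.0, min(lower, mhat)), min(1.0, max(upper, mhat)))


def relative_male_rate(rates: CrossTypeRates) -> float:
    """Post-dispersal male gametic rate: m_m / (1 - m_z - m_f).

    Rescales the seedling-stage m_m to the proportion of male gametic
    immigrants among offspring dispersed from local (native) mothers only,
    making it comparable with the pre-dispersal seed-stage estimate.
    """
    denom = 1.0 - rates.m_z - rates.m_f
    if denom <= 0:
        raise ValueError("m_z + m_f >= 1: relative male rate undefined")
    return rates.m_m / denom
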