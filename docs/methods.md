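# Methods

## Gene-flow mixture model

An offspring sampled under the native canopy is modelled as a draw from a
four-component mixture over parental cross types (father, mother):
PN (exotic father, native mother; weight m_m), PP (both exotic; m_z),
NP (exotic mother; m_f) and NN (both native; the residual). The genotypic
probability of a combined chloroplast–nuclear multilocus genotype under a
cross type is the product of

- the chloroplast haplotype frequency in the **father's** population —
  plastids are paternally inherited in *Pinus*; a `cp_inheritance:
  paternal|maternal` switch is exposed for reuse in maternally inheriting
  taxa;
- one single-locus diploid probability per nuclear locus: for unordered
  genotype {a, b} with maternal pool M and paternal pool F,
  `p_M(a)p_F(b) + p_M(b)p_F(a)` when a ≠ b and `p_M(a)p_F(a)` when a = b.

Assumptions: nuclear loci unlinked and in Hardy–Weinberg equilibrium within
each parental pool; reference panels representative of the effective parent
pools; at most one exotic source pool (admixture among several plantations
of different origin is out of scope). Missing data contribute a factor 1
(the locus is skipped); individuals missing the chloroplast haplotype enter
through their nuclear loci alone; individuals missing everything are
rejected at load.

Pre-dispersal seed samples are collected from native mother trees, so m_z
and m_f are structurally zero and the seed model is the two-component
mixture `m_m·Pr_PN + (1−m_m)·Pr_NN`. The seed model uses population
frequencies for the maternal gamete rather than conditioning on each known
mother's genotype — the simpler estimand that matches the seedling model;
mother-conditioned seed likelihoods are a non-goal.

### Reference frequencies

Plug-in sample frequencies from each adult panel over the **union** alphabet
of both panels plus all offspring samples. Categories unobserved in a panel
receive a small floor (default 1e-4, range [0, 0.01]) and the vector is
renormalized; this prevents a single offspring allele absent from a panel
from zeroing the whole likelihood, while barely perturbing observed
frequencies. Floor 0 is allowed (useful for exact toy computations) and
yields genuinely zero-support genotypes, with log-likelihood −∞ where a
required component has no mass.

### Optimization

The log-likelihood is a sum of logs of affine functions of the mixture
weights, hence concave on the simplex; the global maximizer is therefore a
local one. The solver stacks three layers — redundant given concavity, but
cheap and defensive against degenerate flat regions:

1. a coarse simplex grid scan (step 0.1) that also powers the
   identifiability probe;
2. expectation–maximization for mixture weights, extended with *clamped
   coordinates* (fixed weights keep the monotone-ascent property on the
   restricted face) so the same routine drives profile likelihoods;
3. an SLSQP polish that lands boundary estimates exactly on 0 (EM only
   approaches the boundary geometrically), followed by a snap-to-zero step
   accepted only when it does not lower the likelihood.

Multi-start points are the simplex vertices, centroid and edge midpoints
(blended 10% toward the centroid so EM starts interior); ties within 1e-9
log-likelihood are broken by the lexicographically smallest
(m_m, m_z, m_f). Permutation replicates use a single-start EM batched
across replicates as dense matrix products (concavity guarantees the same
optimum); a grid-oracle acceptance test verifies the maximizer against an
exhaustive 0.01-step scan on random instances.

When the two panels are (near-)identical the likelihood is flat; if the
probe grid's likelihood range falls below 1e-8 the estimate is flagged
`identifiable=False` with intervals [0, 1] instead of raising, so pipelines
survive degenerate scenarios.

### Profile-likelihood intervals

95% intervals are `{θ : 2[l_max − l_profile(θ)] ≤ 3.841}` (χ²₁ quantile),
profiling over the remaining components with the clamped solver. The profile
deviance is convex (concave likelihood), so each endpoint is found by
bisection to 1e-4, clipped to [0, 1]. Estimates at a boundary keep the
boundary endpoint exactly. The seedling-stage m_m is additionally reported
as m_m/(1 − m_z − m_f), the male-immigrant fraction among offspring of
local mothers, which is the quantity comparable with a seed-stage m_m.

## Temporal tests

Randomization test (seedling–seedling): the pooled n1+n2 genotypes are
reallocated B times (default 1000) into samples of the original sizes, rates
are re-estimated jointly on each side, and each parameter's two-sided
p-value is `(r+1)/(B+1)` counting the observed allocation — the convention
that keeps p in (0, 1]. All three parameters are re-estimated jointly per
replicate and per-parameter differences extracted. The test refuses
seed-stage samples: under the null of equal m_m, seeds and seedlings still
follow different models, so exchangeability fails.

Likelihood-ratio test (seed–seedling): model A maximizes the joint
likelihood with a shared m_m (seedling keeps free m_z, m_f); model B frees
the male rate per stage — its likelihood factorizes, so the free fit is two
independent fits. The shared fit profiles the seedling likelihood over
(m_z, m_f) at each m_m (clamped EM) and maximizes the 1-D concave profile
with a grid-bracketed bounded search. D = −2 ln(L_A/L_B) is referred to
χ²₁. When any component sits at 0 the asymptotic reference is only
approximate; results carry a `boundary_warning` flag rather than a silent
p-value. Bootstrap two-sample comparisons are deliberately absent (variance
underestimation for small samples).

Holm–Bonferroni adjustment wraps `statsmodels.stats.multitest`; the family
is one battery of comparisons per run (configurable by calling
`adjust_results` on any subset).

## Diversity and differentiation

- H_o: fraction heterozygous among called genotypes, averaged over loci.
- H_e: unbiased per-locus `(2n/(2n−1))(1 − Σp̂²)`, averaged; F_IS = 1 −
  H_o/H_e (0 when H_e = 0). Loci with fewer than two called copies are
  excluded with a warning.
- Effective numbers of alleles/haplotypes: reciprocal of the unbiased
  homozygosity `Σc(c−1)/(N(N−1))`. With all categories singletons the
  estimator is 0; the effective number is then capped at N, since it cannot
  exceed the number of copies.
- Exact Hardy–Weinberg test: Monte-Carlo Markov chain over genotype tables
  with fixed allele counts (allele-switch proposals between two random
  individuals). The chain runs on labelled individuals with stationary
  weight 2^H per labelled state, which marginalizes to the exact
  conditional table distribution; proposal-multiplicity Hastings factors
  handle coincident flips. p is the chain fraction of tables no more
  probable than the observed one. Defaults 1e5 steps / 1e4 dememorization
  (desk scale); longer chains (e.g. 1e7/1e6) are plain arguments.
- Null alleles vs inbreeding: EM under a model with a per-locus null allele
  and a shared inbreeding coefficient F (autozygosity as a latent
  indicator). Blank genotypes enter as candidate null–null homozygotes —
  necessary, not cosmetic: conditioned on amplified genotypes only, the
  single-locus null-allele model is *exactly* equivalent to inbreeding with
  F = 2r/(1+r), so the blank class carries the identifying information.
  Technical dropout is not modelled separately, making f(null) an upper
  bound when dropout is present. This EM approximates the estimand of the
  full Bayesian population-inbreeding MCMC treatment, which is not
  reimplemented. Convergence: max parameter change < 1e-8; iteration cap
  200,000 (the ridge near F = 0 converges slowly; iterations are O(#alleles)
  after class-count vectorization, so the cap costs milliseconds).
- F_ST: two-level AMOVA (among/within samples) on the identity metric over
  gene copies (haploid for cp haplotypes), variance components summed
  across loci before the ratio.
- Jost's D_est: per locus `(k/(k−1))(H_T − H_S)/(1 − H_S)` with k = 2,
  H_S = (ñ/(ñ−1))(1 − mean Σp²) over the harmonic-mean copy number ñ and
  H_T = 1 − Σp̄² + H_S/(2ñk); arithmetic mean over loci; a locus with
  H_S = 1 is skipped with a warning. The observed-heterozygosity
  small-sample term is omitted (the estimator treats gene copies, which
  also serves haploid data); it vanishes in the large-n limit check.
- Permutation significance: whole multilocus genotypes permuted between the
  two samples, one-sided `(r+1)/(n_perm+1)`, default 10,000 permutations.

## Synthetic-data generator

What it emulates: two parental pools diverged in nuclear allele frequencies
at F_ST ≈ 0.04–0.11 (the monitored field regime) with a largely private,
highly diverse plantation chloroplast pool; adult reference panels of
100–200 trees; offspring cohorts of tens to hundreds drawn as the
four-component cross-type mixture with paternal plastid inheritance; sparse
missing data; optional per-cross-type Bernoulli survival between sequential
stages.

Mechanism: per nuclear locus an ancestral frequency vector from a symmetric
Dirichlet, then each population from a Dirichlet centred on it with
concentration (1−F)/F — the F-model. This matches what the estimator
consumes (frequency divergence), not any demographic history; no linkage,
no spatial structure, no mutation model, no overlapping generations. Defaults:
10 nuclear loci × 8 alleles, divergence F = 0.1, 70% of 40 exotic
chloroplast haplotypes private, panels (150, 150), cohorts seeds n=400 at
m_m = 0.15 and seedlings at (0.15, 0.05, 0), missing rate 0.02. Passing
tests on these data demonstrate correctness of the estimator under its own
assumptions; they do not certify robustness to linked loci, genotyping
error, within-population structure or misspecified reference panels.

Hidden cross-type truth labels travel with simulated individuals for oracle
checks but are never read by estimation code. One master seed spawns
per-stage substreams, so every bundle is bit-reproducible.

## Problem sizes and numerical choices

Acceptance-scale studies use 200 replicates for recovery/coverage and 200
simulated pairs at B = 199 for randomization calibration — sizes chosen so
Monte-Carlo error is well inside the asserted tolerances. EM tolerance
1e-12 on weights; profile bisection 1e-4; frequency-sum validation 1e-12;
p-value conventions always include the observed statistic. Degenerate
inputs (empty samples, monomorphic loci, all-missing loci, identical
panels) raise informative errors or flagged results as documented above.

## Known limitations

- A single exotic source pool; admixed plantations of multiple origins are
  not modelled.
- Genotyping error and null alleles are not propagated into the gene-flow
  likelihood (null-allele handling lives in the diversity module only).
- The χ²₁ reference for the LR test and the profile cutoff are asymptotic
  and conservative/anticonservative at boundary estimates; flags are
  reported, corrections are not attempted.
- f(null) absorbs technical dropout.
- The randomization test assumes exchangeability of seedlings across the
  pooled samples under the null, which spatial or maternal-family structure
  could violate.
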