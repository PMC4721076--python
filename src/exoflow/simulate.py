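"""Synthetic reference panels and offspring cohorts.

The generator reproduces the statistical structure the estimator assumes: a
native relict stand and a surrounding exotic plantation that have diverged
in nuclear allele frequencies (an F-model / Dirichlet drift around a shared
ancestral frequency vector) and carry strongly divergent chloroplast
haplotype pools with a large fraction of plantation-private haplotypes.
Offspring cohorts are four-component mixtures of parental cross types, with
maternal and paternal nuclear gametes drawn from the respective population
pools and the chloroplast haplotype following the father (paternal plastid
inheritance).  Hidden cross-type labels travel with simulated individuals
for oracle checks but are never consumed by the estimators.

Defaults mirror the monitored field setting: ten nuclear microsatellites,
reference panels of 150 adults per population, nuclear divergence around
F_ST 0.1, ~70% plantation-private chloroplast haplotypes, a pre-dispersal
seed cohort of 400 with male gametic rate 0.15, and post-dispersal seedling
cohorts with rates (0.15, 0.05, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .frequencies import CROSS_TYPES, FrequencyTable
from .likelihood import CrossTypeRates
from .markers import MarkerPanel, MultilocusGenotype, SampleTable


@dataclass
class CohortSpec:
    label: str
    stage: str  # "seed" | "seedling"
    n: int
    rates: tuple[float, float, float]  # true (m_m, m_z, m_f)


@dataclass
class ScenarioConfig:
    n_nuclear_loci: int = 10
    alleles_per_locus: int = 8
    n_cp_haplotypes_native: int = 15
    n_cp_haplotypes_exotic: int = 40
    divergence: float = 0.1  # F-model drift, ~ expected nuclear F_ST
    private_cp_fraction: float = 0.7
    panel_sizes: tuple[int, int] = (150, 150)  # (n_N native, n_P exotic)
    cohorts: list[CohortSpec] = field(default_factory=lambda: [
        CohortSpec("seeds", "seed", 400, (0.15, 0.0, 0.0)),
        CohortSpec("R1", "seedling", 200, (0.15, 0.05, 0.0)),
        CohortSpec("R2", "seedling", 100, (0.15, 0.05, 0.0)),
    ])
    survival_differential: Optional[dict[str, float]] = None
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.divergence < 1:
            raise ValueError("divergence must lie in (0, 1)")
        if min(self.n_nuclear_loci, self.alleles_per_locus,
               self.n_cp_haplotypes_native, self.n_cp_haplotypes_exotic,
               *self.panel_sizes) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.private_cp_fraction <= 1:
            raise ValueError("private_cp_fraction must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for c in self.cohorts:
            CrossTypeRates(*c.rates, stage=c.stage)  # raises off-simplex
        if self.survival_differential is not None:
            if any(not 0 <= s <= 1 for s in self.survival_differential.values()):
                raise ValueError("survival values must lie in [0, 1]")


@dataclass
class ScenarioBundle:
    true_frequencies: tuple[FrequencyTable, FrequencyTable]  # (native, exotic)
    panels: tuple[SampleTable, SampleTable]
    cohorts: list[SampleTable]
    truth: ScenarioConfig
    marker_panel: MarkerPanel = None  # type: ignore[assignment]


def _locus_names(k: int) -> list[str]:
    return [f"nSSR{str(i + 1).zfill(2)}" for i in range(k)]


def simulate_reference_populations(
    config: ScenarioConfig, rng: Optional[np.random.Generator] = None
):
    """True population frequencies plus sampled adult reference panels.

    Nuclear frequencies follow the F-model: an ancestral vector per locus
    from a symmetric Dirichlet, then each population from a Dirichlet
    centred on it with concentration (1-F)/F — no demographic history, just
    the frequency divergence the estimator actually consumes.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    F = config.divergence
    conc = (1.0 - F) / F

    loci = _locus_names(config.n_nuclear_loci)
    alleles = [str(a + 1) for a in range(config.alleles_per_locus)]
    nat_nuc, exo_nuc = {}, {}
    for locus in loci:
        ancestral = rng.dirichlet(np.ones(config.alleles_per_locus))
        nat_nuc[locus] = dict(zip(alleles, rng.dirichlet(ancestral * conc)))
        exo_nuc[locus] = dict(zip(alleles, rng.dirichlet(ancestral * conc)))

    n_private = int(round(config.private_cp_fraction * config.n_cp_haplotypes_exotic))
    n_shared = config.n_cp_haplotypes_exotic - n_private
    native_haps = [f"H{str(i + 1).zfill(3)}" for i in range(config.n_cp_haplotypes_native)]
    shared = list(rng.choice(native_haps, size=min(n_shared, len(native_haps)), replace=False))
    private = [f"E{str(i + 1).zfill(3)}" for i in range(n_private)]
    exotic_haps = shared + private
    nat_cp = dict(zip(native_haps, rng.dirichlet(np.ones(len(native_haps)))))
    exo_cp = dict(zip(exotic_haps, rng.dirichlet(np.ones(len(exotic_haps)))))

    native = FrequencyTable("native", nat_cp, nat_nuc, floor=0.0)
    exotic = FrequencyTable("exotic", exo_cp, exo_nuc, floor=0.0)

    panels = (
        _sample_adults(native, config.panel_sizes[0], "native_adults",
                       config.missing_rate, rng),
        _sample_adults(exotic, config.panel_sizes[1], "exotic_adults",
                       config.missing_rate, rng),
    )
    return (native, exotic), panels


def _draw_many(rng, freqs: dict[str, float], size: int) -> list[str]:
    """Vectorized categorical draws (sorted category order for determinism)."""
    cats = sorted(freqs)
    p = np.array([freqs[c] for c in cats], dtype=float)
    cum = np.cumsum(p / p.sum())
    idx = np.searchsorted(cum, rng.random(size), side="right")
    return [cats[i] for i in np.minimum(idx, len(cats) - 1)]


def _mask_missing(geno: MultilocusGenotype, rate: float, rng) -> MultilocusGenotype:
    if rate <= 0:
        return geno
    cp = None if rng.random() < rate else geno.cp_haplotype
    nuclear = {l: (None if rng.random() < rate else g)
               for l, g in geno.nuclear_genotypes.items()}
    if cp is None and all(g is None for g in nuclear.values()):
        cp = geno.cp_haplotype  # never blank a whole individual
    return MultilocusGenotype(geno.individual_id, cp, nuclear)


def _sample_adults(freqs: FrequencyTable, n: int, label: str, missing_rate, rng) -> SampleTable:
    cps = _draw_many(rng, freqs.cp_freqs, n)
    locus_draws = {
        locus: (_draw_many(rng, p, n), _draw_many(rng, p, n))
        for locus, p in freqs.nuclear_freqs.items()
    }
    genos = []
    for i in range(n):
        nuclear = {locus: (a[i], b[i]) for locus, (a, b) in locus_draws.items()}
        g = MultilocusGenotype(f"{label}_{i + 1}", cps[i], nuclear)
        genos.append(_mask_missing(g, missing_rate, rng))
    return SampleTable(label, genos)


def simulate_offspring(
    native: FrequencyTable,
    exotic: FrequencyTable,
    rates: CrossTypeRates,
    n: int,
    stage: str = "seedling",
    label: str = "offspring",
    missing_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> SampleTable:
    """Draw a mixed-origin offspring cohort with hidden cross-type labels."""
    rng = rng or np.random.default_rng(seed)
    if stage == "seed" and (rates.m_z != 0 or rates.m_f != 0):
        raise ValueError("seed stage forces m_z = m_f = 0")
    weights = rates.as_weights()
    pops = {"N": native, "P": exotic}
    if n == 0:
        return SampleTable(label, [], stage=stage, cross_labels=[])
    draws = rng.choice(4, size=n, p=weights / weights.sum())
    labels = [CROSS_TYPES[c] for c in draws]
    # one vectorized gamete stream per (parent population, role)
    maternal: dict[str, dict[str, list[str]]] = {}
    paternal: dict[str, dict[str, list[str]]] = {}
    cp_draws: dict[str, list[str]] = {}
    loci = list(native.nuclear_freqs)
    for pop_code, freqs in pops.items():
        maternal[pop_code] = {l: _draw_many(rng, freqs.nuclear_freqs[l], n) for l in loci}
        paternal[pop_code] = {l: _draw_many(rng, freqs.nuclear_freqs[l], n) for l in loci}
        cp_draws[pop_code] = _draw_many(rng, freqs.cp_freqs, n)
    genos = []
    for i, cross in enumerate(labels):
        father, mother = cross[0], cross[1]  # codes are (father, mother)
        nuclear = {l: (maternal[mother][l][i], paternal[father][l][i]) for l in loci}
        g = MultilocusGenotype(f"{label}_{i + 1}", cp_draws[father][i], nuclear)
        genos.append(_mask_missing(g, missing_rate, rng))
    return SampleTable(label, genos, stage=stage, cross_labels=labels)


def apply_survival(
    sample: SampleTable,
    differential: dict[str, float],
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    label: Optional[str] = None,
) -> SampleTable:
    """Bernoulli thinning of a labelled cohort by per-cross-type survival."""
    if sample.cross_labels is None:
        raise ValueError("sample carries no cross-type labels (not simulated?)")
    if any(not 0 <= s <= 1 for s in differential.values()):
        raise ValueError("survival values must lie in [0, 1]")
    rng = rng or np.random.default_rng(seed)
    u = rng.random(sample.n)
    keep = [i for i in range(sample.n)
            if u[i] < differential.get(sample.cross_labels[i], 1.0)]
    return sample.subset(keep, label=label or f"{sample.label}_survived")


def simulate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Full reproducible bundle: true frequencies, panels and all cohorts.

    One master seed; per-stage substreams are spawned from it so each
    cohort is reproducible independently of the others.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(2 + len(config.cohorts))
    (true_freqs, panels) = simulate_reference_populations(
        config, rng=np.random.default_rng(streams[0])
    )
    native, exotic = true_freqs
    cohorts = []
    for spec, ss in zip(config.cohorts, streams[2:]):
        rng = np.random.default_rng(ss)
        rates = CrossTypeRates(*spec.rates, stage=spec.stage)
        cohort = simulate_offspring(
            native, exotic, rates, spec.n, stage=spec.stage, label=spec.label,
            missing_rate=config.missing_rate, rng=rng,
        )
        if config.survival_differential is not None and spec.stage == "seedling":
            cohort = apply_survival(
                cohort, config.survival_differential, rng=rng, label=spec.label
            )
        cohorts.append(cohort)
    marker_panel = MarkerPanel.union(
        panels[0].marker_panel(), panels[1].marker_panel(),
        *[c.marker_panel() for c in cohorts],
    )
    return ScenarioBundle(true_freqs, panels, cohorts, replace(config), marker_panel)
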