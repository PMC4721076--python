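"""Reference allele/haplotype frequencies and cross-type genotype probabilities.

An offspring sampled in the native stand has one of four parental origins
(mother, father): NN native x native, PN native mother x exotic (plantation)
father, PP both exotic, NP exotic mother x native father.  Given reference
allele frequencies for the two adult pools, the probability of an observed
combined chloroplast-nuclear multilocus genotype under each cross type is
the product of (i) the chloroplast-haplotype frequency in the *father's*
population (paternal plastid inheritance in pines) and (ii) one
single-locus diploid probability per nuclear locus, assuming unlinked loci
in Hardy-Weinberg equilibrium within each parental pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .markers import MarkerPanel, MultilocusGenotype, SampleTable

#: the four (father, mother) parental-origin codes, in mixture-weight order
#: (PN -> m_m, PP -> m_z, NP -> m_f, NN -> 1 - m_m - m_z - m_f)
CROSS_TYPES = ("PN", "PP", "NP", "NN")


@dataclass
class FrequencyTable:
    """Per-population chloroplast-haplotype and nuclear allele frequencies.

    Frequencies are plug-in sample proportions over a *union* alphabet;
    categories unobserved in this population receive a small ``floor``
    probability, after which each vector is renormalized to sum to one.
    """

    population: str
    cp_freqs: dict[str, float] = field(default_factory=dict)
    nuclear_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    floor: float = 0.0
    n_source: Optional[int] = None

    def validate(self) -> None:
        vectors = [self.cp_freqs] + list(self.nuclear_freqs.values())
        for vec in vectors:
            if vec and abs(sum(vec.values()) - 1.0) > 1e-12:
                raise ValueError(f"frequency vector does not sum to 1: {vec}")
            if self.floor > 0 and any(v <= 0 for v in vec.values()):
                raise ValueError("zero frequency despite positive floor")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": self.population, "marker": "cp_hap", "category": h, "frequency": f}
            for h, f in sorted(self.cp_freqs.items())
        ]
        for locus in sorted(self.nuclear_freqs):
            rows += [
                {"population": self.population, "marker": locus, "category": a, "frequency": f}
                for a, f in sorted(self.nuclear_freqs[locus].items())
            ]
        return pd.DataFrame(rows, columns=["population", "marker", "category", "frequency"])


def _floored(counts: dict[str, float], alphabet: set[str], floor: float) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no observed copies")
    freqs = {c: counts.get(c, 0.0) / total for c in alphabet}
    unobserved = [c for c in alphabet if freqs[c] == 0.0]
    if floor > 0 and unobserved:
        for c in unobserved:
            freqs[c] = floor
        z = 1.0 + floor * len(unobserved)
        freqs = {c: v / z for c, v in freqs.items()}
    return freqs


def estimate_frequencies(
    panel: SampleTable,
    union_alphabet: MarkerPanel,
    floor: float = 1e-4,
    population: Optional[str] = None,
) -> FrequencyTable:
    """Plug-in frequency estimates from an adult reference panel.

    The alphabet is the union of categories seen across both panels and the
    offspring (built by the caller with :meth:`MarkerPanel.union`), so that
    offspring genotypes carrying alleles absent from this panel still get a
    positive probability when ``floor > 0``.
    """
    if panel.n == 0:
        raise ValueError("empty reference panel")
    if not 0 <= floor <= 0.01:
        raise ValueError("floor must lie in [0, 0.01]")
    cp_counts: dict[str, float] = {}
    for g in panel.genotypes:
        if g.cp_haplotype is not None:
            cp_counts[g.cp_haplotype] = cp_counts.get(g.cp_haplotype, 0.0) + 1.0
    cp = (
        _floored(cp_counts, set(union_alphabet.haplotype_alphabet), floor)
        if union_alphabet.haplotype_alphabet
        else {}
    )
    nuclear: dict[str, dict[str, float]] = {}
    for locus in union_alphabet.nuclear_loci:
        counts: dict[str, float] = {}
        for g in panel.genotypes:
            pair = g.nuclear_genotypes.get(locus)
            if pair is not None:
                for a in pair:
                    counts[a] = counts.get(a, 0.0) + 1.0
        if not counts:
            raise ValueError(f"locus {locus!r}: all data missing in panel {panel.label!r}")
        nuclear[locus] = _floored(counts, set(union_alphabet.allele_alphabet[locus]), floor)
    table = FrequencyTable(
        population=population or panel.label,
        cp_freqs=cp,
        nuclear_freqs=nuclear,
        floor=floor,
        n_source=panel.n,
    )
    table.validate()
    return table


def _parent_tables(
    cross: str, native: FrequencyTable, exotic: FrequencyTable, cp_inheritance: str
) -> tuple[FrequencyTable, FrequencyTable, FrequencyTable]:
    """(mother, father, cp-carrier) frequency tables for a cross code.

    Code letters are ordered (father, mother): PN is an exotic (plantation)
    father crossed with a native mother — the male gametic immigration
    class — and NP the reverse.
    """
    father = native if cross[0] == "N" else exotic
    mother = native if cross[1] == "N" else exotic
    cp_carrier = father if cp_inheritance == "paternal" else mother
    return mother, father, cp_carrier


def genotype_prob(
    g: MultilocusGenotype,
    cross: str,
    native: FrequencyTable,
    exotic: FrequencyTable,
    cp_inheritance: str = "paternal",
) -> float:
    """Probability of a combined multilocus genotype under one cross type.

    Missing chloroplast haplotype or missing nuclear loci contribute a
    factor of 1 (the likelihood simply skips them).
    """
    if cross not in CROSS_TYPES:
        raise ValueError(f"unknown cross type {cross!r}")
    if cp_inheritance not in ("paternal", "maternal"):
        raise ValueError("cp_inheritance must be 'paternal' or 'maternal'")
    mother, father, cp_carrier = _parent_tables(cross, native, exotic, cp_inheritance)
    prob = 1.0
    if g.cp_haplotype is not None:
        try:
            prob *= cp_carrier.cp_freqs[g.cp_haplotype]
        except KeyError:
            raise KeyError(
                f"haplotype {g.cp_haplotype!r} absent from the union alphabet; "
                "rebuild frequency tables including the offspring"
            )
    for locus, pair in g.nuclear_genotypes.items():
        if pair is None:
            continue
        try:
            pm, pf = mother.nuclear_freqs[locus], father.nuclear_freqs[locus]
            a, b = pair
            if a == b:
                prob *= pm[a] * pf[a]
            else:
                prob *= pm[a] * pf[b] + pm[b] * pf[a]
        except KeyError as exc:
            raise KeyError(
                f"locus {locus!r} allele {exc.args[0]!r} absent from union alphabet; "
                "rebuild frequency tables including the offspring"
            ) from None
    return prob


def component_matrix(
    sample: SampleTable,
    native: FrequencyTable,
    exotic: FrequencyTable,
    cp_inheritance: str = "paternal",
    collapse: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-type probability matrix for a sample.

    Returns ``(counts, P)`` where ``P[k, c]`` is the probability of distinct
    genotype ``k`` under cross type ``CROSS_TYPES[c]`` and ``counts[k]`` its
    multiplicity.  With ``collapse=False`` one row per individual is
    returned (counts all one) — used by permutation machinery.
    """
    loci = sorted(native.nuclear_freqs)
    cache: dict[tuple, np.ndarray] = {}
    rows, counts = [], []
    if collapse:
        items = sample.genotype_counts(loci).items()
        keyed = {g.key(loci): g for g in sample.genotypes}
        for key, mult in items:
            g = keyed[key]
            row = np.array(
                [genotype_prob(g, c, native, exotic, cp_inheritance) for c in CROSS_TYPES]
            )
            rows.append(row)
            counts.append(mult)
    else:
        for g in sample.genotypes:
            key = g.key(loci)
            if key not in cache:
                cache[key] = np.array(
                    [genotype_prob(g, c, native, exotic, cp_inheritance) for c in CROSS_TYPES]
                )
            rows.append(cache[key])
            counts.append(1)
    return np.asarray(counts, dtype=float), np.vstack(rows)
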