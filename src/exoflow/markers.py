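"""Core marker and genotype containers.

Two marker classes are carried side by side: chloroplast microsatellite
(cpSSR) haplotypes, which are haploid and (in pines) paternally inherited,
and nuclear microsatellites (nSSRs), which are codominant diploid markers.
A multilocus genotype couples one categorical chloroplast haplotype with an
unordered diploid genotype per nuclear locus; either part may be missing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

MISSING_TOKENS = {"", "NA", "na", "0", "00", "000", "0000", "000000",
                  "nan", "NaN", "None", "<NA>"}

#: canonical missing sentinel on output
MISSING = "NA"


def normalize_allele(label) -> Optional[str]:
    """Canonicalize an allele/fragment label; return None for missing.

    Numeric labels lose leading zeros so GenePop's ``001`` equals ``1``.
    """
    if label is None:
        return None
    s = str(label).strip()
    if s in MISSING_TOKENS:
        return None
    try:
        return str(int(s))
    except ValueError:
        pass
    try:  # integral floats (e.g. pandas-coerced fragment sizes)
        f = float(s)
        if f == f and f.is_integer():
            return str(int(f))
    except ValueError:
        pass
    return s


def canonical_pair(a, b) -> Optional[tuple[str, str]]:
    """Sorted (unordered) diploid genotype; None if either allele missing."""
    na, nb = normalize_allele(a), normalize_allele(b)
    if na is None or nb is None:
        return None
    return tuple(sorted((na, nb), key=_allele_key))  # type: ignore[return-value]


def _allele_key(s: str):
    try:
        return (0, int(s), s)
    except ValueError:
        return (1, 0, s)


@dataclass
class MarkerPanel:
    """Declares loci, inheritance modes and observed allele alphabets."""

    nuclear_loci: list[str] = field(default_factory=list)
    cp_loci: list[str] = field(default_factory=list)
    allele_alphabet: dict[str, set[str]] = field(default_factory=dict)
    haplotype_alphabet: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if len(set(self.nuclear_loci)) != len(self.nuclear_loci):
            raise ValueError("duplicate nuclear locus names")
        if len(set(self.cp_loci)) != len(self.cp_loci):
            raise ValueError("duplicate cpSSR fragment names")
        for locus, alleles in self.allele_alphabet.items():
            if locus not in self.nuclear_loci:
                raise ValueError(f"alphabet declared for undeclared locus {locus!r}")
            if any(normalize_allele(a) is None for a in alleles):
                raise ValueError(f"missing-data sentinel in alphabet of {locus!r}")
        if any(h is None or str(h) in MISSING_TOKENS for h in self.haplotype_alphabet):
            raise ValueError("missing-data sentinel in haplotype alphabet")

    @staticmethod
    def union(*panels: "MarkerPanel") -> "MarkerPanel":
        """Union of alphabets over panels sharing (a superset of) loci."""
        nuclear: list[str] = []
        cp: list[str] = []
        alleles: dict[str, set[str]] = {}
        haps: set[str] = set()
        for p in panels:
            for loc in p.nuclear_loci:
                if loc not in nuclear:
                    nuclear.append(loc)
                alleles.setdefault(loc, set()).update(p.allele_alphabet.get(loc, set()))
            for loc in p.cp_loci:
                if loc not in cp:
                    cp.append(loc)
            haps.update(p.haplotype_alphabet)
        return MarkerPanel(nuclear, cp, alleles, haps)


@dataclass
class MultilocusGenotype:
    """One individual: cp haplotype plus per-locus diploid nuclear genotypes.

    ``nuclear_genotypes`` maps locus name to a canonical sorted allele pair,
    or None where the locus failed to amplify.
    """

    individual_id: str
    cp_haplotype: Optional[str]
    nuclear_genotypes: dict[str, Optional[tuple[str, str]]]

    def __post_init__(self):
        canon = {}
        for locus, g in self.nuclear_genotypes.items():
            canon[locus] = None if g is None else canonical_pair(*g)
        self.nuclear_genotypes = canon
        if self.cp_haplotype is not None and str(self.cp_haplotype) in MISSING_TOKENS:
            self.cp_haplotype = None

    @property
    def all_missing(self) -> bool:
        return self.cp_haplotype is None and all(
            g is None for g in self.nuclear_genotypes.values()
        )

    def key(self, loci: Iterable[str]) -> tuple:
        """Hashable canonical combined-genotype key over the given loci."""
        return (self.cp_haplotype, tuple(self.nuclear_genotypes.get(l) for l in loci))


@dataclass
class SampleTable:
    """A labelled sample of multilocus genotypes (a panel or a cohort)."""

    label: str
    genotypes: list[MultilocusGenotype]
    stage: Optional[str] = None  # "seed" | "seedling" | None (adult panel)
    cross_labels: Optional[list[str]] = None  # hidden simulation truth

    def __post_init__(self):
        ids = [g.individual_id for g in self.genotypes]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicated individual_id(s): {dup[:5]}")
        empties = [g.individual_id for g in self.genotypes if g.all_missing]
        if empties:
            raise ValueError(f"individuals missing all loci: {empties[:5]}")
        if self.cross_labels is not None and len(self.cross_labels) != len(self.genotypes):
            raise ValueError("cross_labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def loci(self) -> list[str]:
        seen: list[str] = []
        for g in self.genotypes:
            for l in g.nuclear_genotypes:
                if l not in seen:
                    seen.append(l)
        return seen

    def genotype_counts(self, loci: Optional[list[str]] = None) -> dict[tuple, int]:
        """Distinct combined chloroplast-nuclear genotypes with multiplicities."""
        loci = self.loci() if loci is None else loci
        counts: Counter = Counter(g.key(loci) for g in self.genotypes)
        assert sum(counts.values()) == self.n
        return dict(counts)

    def marker_panel(self) -> MarkerPanel:
        """Panel of alphabets observed in this sample."""
        panel = MarkerPanel(nuclear_loci=self.loci())
        for g in self.genotypes:
            if g.cp_haplotype is not None:
                panel.haplotype_alphabet.add(g.cp_haplotype)
            for locus, pair in g.nuclear_genotypes.items():
                if pair is not None:
                    panel.allele_alphabet.setdefault(locus, set()).update(pair)
        for locus in panel.nuclear_loci:
            panel.allele_alphabet.setdefault(locus, set())
        return panel

    def subset(self, indices: Iterable[int], label: Optional[str] = None) -> "SampleTable":
        idx = list(indices)
        return SampleTable(
            label=label or self.label,
            genotypes=[self.genotypes[i] for i in idx],
            stage=self.stage,
            cross_labels=None
            if self.cross_labels is None
            else [self.cross_labels[i] for i in idx],
        )
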