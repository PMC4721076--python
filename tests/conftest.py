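import numpy as np
import pytest

from exoflow import FrequencyTable, MultilocusGenotype, SampleTable


def make_genotype(ind_id, cp=None, **loci):
    """Shorthand: make_genotype('i1', cp='H1', L1=('A','B'), L2=None)."""
    return MultilocusGenotype(ind_id, cp, dict(loci))


@pytest.fixture
def disjoint_freqs():
    """Native fixed for allele A / haplotype H1, exotic for B / H2.

    Under these panels every offspring genotype identifies its cross type
    unambiguously, so the MLE reduces to multinomial counting.
    """
    native = FrequencyTable(
        "native",
        cp_freqs={"H1": 1.0, "H2": 0.0},
        nuclear_freqs={"L1": {"A": 1.0, "B": 0.0}},
    )
    exotic = FrequencyTable(
        "exotic",
        cp_freqs={"H1": 0.0, "H2": 1.0},
        nuclear_freqs={"L1": {"A": 0.0, "B": 1.0}},
    )
    return native, exotic


@pytest.fixture
def overlap_freqs():
    """Two-locus tables with overlapping allele frequencies."""
    native = FrequencyTable(
        "native",
        cp_freqs={"H1": 0.9, "H2": 0.1},
        nuclear_freqs={"L1": {"A": 0.8, "B": 0.2}, "L2": {"C": 0.6, "D": 0.4}},
    )
    exotic = FrequencyTable(
        "exotic",
        cp_freqs={"H1": 0.2, "H2": 0.8},
        nuclear_freqs={"L1": {"A": 0.1, "B": 0.9}, "L2": {"C": 0.3, "D": 0.7}},
    )
    return native, exotic


def cross_offspring(n_by_cross: dict[str, int], label="off", stage="seedling"):
    """Offspring sample under the disjoint panels: NN = A/A+H1, PN = A/B+H2, etc.

    Cross codes are (father, mother); the father contributes one allele and
    the chloroplast haplotype, the mother the other allele.
    """
    hap = {"N": "H1", "P": "H2"}
    allele = {"N": "A", "P": "B"}
    genos, labels = [], []
    i = 0
    for cross, count in n_by_cross.items():
        father, mother = cross[0], cross[1]
        for _ in range(count):
            i += 1
            pair = (allele[mother], allele[father])
            genos.append(make_genotype(f"{label}{i}", cp=hap[father], L1=pair))
            labels.append(cross)
    return SampleTable(label, genos, stage=stage, cross_labels=labels)


def random_instance(rng, n_loci=3, n_alleles=3, n_off=40):
    """A random small estimation instance for oracle-equivalence checks."""
    loci = [f"L{k}" for k in range(n_loci)]
    def table(pop):
        nuc = {}
        for l in loci:
            p = rng.dirichlet(np.ones(n_alleles))
            nuc[l] = {str(a): float(x) for a, x in enumerate(p)}
        cp = rng.dirichlet(np.ones(3))
        return FrequencyTable(pop, {f"H{j}": float(x) for j, x in enumerate(cp)}, nuc)
    native, exotic = table("native"), table("exotic")
    from exoflow import CrossTypeRates, simulate_offspring
    true = rng.dirichlet(np.ones(4) * 2.0)
    rates = CrossTypeRates(float(true[0]), float(true[1]), float(true[2]))
    sample = simulate_offspring(native, exotic, rates, n_off, rng=rng)
    return sample, native, exotic
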