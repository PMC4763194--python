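"""Tiny construction helpers shared across test modules."""

from __future__ import annotations

from hlamatch import Haplotype, HaplotypeFrequencyTable, LocusSet, UnphasedGenotype

FOUR_LOCI = LocusSet(("A", "B", "C", "DRB1"))
TWO_LOCI = LocusSet(("A", "B"))


def hap(*alleles: str) -> Haplotype:
    return Haplotype(tuple(alleles))


def geno(pairs, loci=FOUR_LOCI, **kw) -> UnphasedGenotype:
    """Genotype from a list of (a, b) pairs aligned with ``loci``."""
    return UnphasedGenotype(tuple(loci), tuple(pairs), **kw)


def table(freqs: dict, loci=FOUR_LOCI, population="pop") -> HaplotypeFrequencyTable:
    """Table from {allele-tuple: frequency}."""
    return HaplotypeFrequencyTable(
        loci, population, {Haplotype(tuple(k)): v for k, v in freqs.items()}
    )


def total_variation(t1: HaplotypeFrequencyTable, t2: HaplotypeFrequencyTable) -> float:
    support = sorted(set(t1.freqs) | set(t2.freqs), key=lambda h: h.alleles)
    return 0.5 * sum(abs(t1.get(h) - t2.get(h)) for h in support)
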