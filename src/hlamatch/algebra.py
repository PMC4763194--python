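"""Haplotype-frequency algebra: marginalization, HWE genotype probabilities,
and per-donor match probabilities at a given stringency.

Under Hardy-Weinberg equilibrium a donor's two haplotypes are independent
draws from the population table, so the probability of an unphased genotype
g is the sum of f(h1) f(h2) over unordered compatible pairs, doubled for
heterozygous pairs.  The probability that a random donor from population k
matches a patient within a mismatch budget is obtained by scanning the
population's full genotype-probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .em import enumerate_phase_decompositions, genotype_probability
from .genotypes import (
    Haplotype,
    LocusSet,
    MatchStringency,
    UnphasedGenotype,
    mismatch_count,
)
from .tables import HaplotypeFrequencyTable

DEFAULT_SUPPORT_CAP = 2_000_000


class SupportCapExceeded(RuntimeError):
    """Exact genotype enumeration would exceed the configured cap."""


def marginalize(
    table: HaplotypeFrequencyTable, drop_locus: str
) -> HaplotypeFrequencyTable:
    """Sum haplotype frequencies over one locus, preserving total mass.

    This is the mathematical counterpart of removing a locus from matching
    consideration: e.g. three-locus B/C/DRB1 frequencies are obtained from the
    four-locus table by summing over the A locus.
    """
    idx = table.locus_set.index(drop_locus)
    reduced_loci = table.locus_set.drop(drop_locus)
    freqs: dict[Haplotype, float] = {}
    for hap in table.sorted_haplotypes():
        reduced = hap.drop(idx)
        freqs[reduced] = freqs.get(reduced, 0.0) + table.freqs[hap]
    return HaplotypeFrequencyTable(reduced_loci, table.population, freqs)


def marginalize_to(
    table: HaplotypeFrequencyTable, considered_loci: Iterable[str]
) -> HaplotypeFrequencyTable:
    """Marginalize down to a locus subset (order follows the table's loci)."""
    keep = set(considered_loci)
    out = table
    for locus in tuple(table.locus_set):
        if locus not in keep:
            out = marginalize(out, locus)
    return out


def hwe_genotype_prob(
    table: HaplotypeFrequencyTable,
    g: UnphasedGenotype,
    considered_loci: Iterable[str] | None = None,
) -> float:
    """P(g) under HWE, marginalizing the table to the considered loci first.

    Genotypes outside the table's support have probability 0.
    """
    loci = (
        table.locus_set.subset(considered_loci)
        if considered_loci is not None
        else table.locus_set
    )
    sub = marginalize_to(table, loci) if tuple(loci) != tuple(table.locus_set) else table
    return genotype_probability(sub, g.restrict(loci))


def _multiset_intersection(a1, a2, b1, b2):
    """Vectorized size of the multiset intersection of allele pairs {a1,a2}, {b1,b2}."""
    het_inter = ((a1 == b1) | (a1 == b2)).astype(np.int64) + (
        (a2 == b1) | (a2 == b2)
    ).astype(np.int64)
    hom_inter = np.minimum(
        2, (b1 == a1).astype(np.int64) + (b2 == a1).astype(np.int64)
    )
    return np.where(a1 == a2, hom_inter, het_inter)


def mismatch_matrix(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Pairwise allele-mismatch counts between two encoded genotype arrays.

    ``codes_a`` has shape (nA, L, 2) and ``codes_b`` (nB, L, 2); alleles are
    integer codes under a shared encoding.  Returns an (nA, nB) matrix of
    total mismatches, equal entrywise to :func:`genotypes.mismatch_count`.
    """
    n_loci = codes_a.shape[1]
    out = np.zeros((codes_a.shape[0], codes_b.shape[0]), dtype=np.int64)
    for l in range(n_loci):
        a1 = codes_a[:, None, l, 0]
        a2 = codes_a[:, None, l, 1]
        b1 = codes_b[None, :, l, 0]
        b2 = codes_b[None, :, l, 1]
        out += 2 - _multiset_intersection(a1, a2, b1, b2)
    return out


@dataclass
class GenotypeProbabilityMap:
    """Exhaustive HWE genotype distribution for one population.

    Entries cover every genotype with nonzero probability over the considered
    loci; probabilities sum to 1.  Genotypes are also kept as an integer-coded
    array for vectorized mismatch queries.
    """

    loci: tuple[str, ...]
    population: str
    genotypes: list[UnphasedGenotype]
    probs: np.ndarray
    _entries: dict[UnphasedGenotype, float] = field(repr=False)
    _allele_codes: list[dict[str, int]] = field(repr=False)
    codes: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.genotypes)

    def prob(self, g: UnphasedGenotype) -> float:
        return self._entries.get(g.restrict(self.loci), 0.0)

    def total(self) -> float:
        return float(self.probs.sum())

    def encode(self, genotypes: Sequence[UnphasedGenotype]) -> np.ndarray:
        """Encode genotypes with this map's allele coding.

        Alleles absent from the map receive fresh negative codes (consistent
        within the call), so they compare unequal to every map allele.
        """
        n = len(genotypes)
        L = len(self.loci)
        out = np.empty((n, L, 2), dtype=np.int64)
        unseen: dict[tuple[int, str], int] = {}
        for gi, g in enumerate(genotypes):
            gr = g.restrict(self.loci)
            for li, (a, b) in enumerate(gr.pairs):
                for k, allele in enumerate((a, b)):
                    code = self._allele_codes[li].get(allele)
                    if code is None:
                        code = unseen.setdefault(
                            (li, allele), -(len(unseen) + 1)
                        )
                    out[gi, li, k] = code
        return out


def build_genotype_probability_map(
    table: HaplotypeFrequencyTable,
    considered_loci: Iterable[str] | None = None,
    cap: int = DEFAULT_SUPPORT_CAP,
) -> GenotypeProbabilityMap:
    """Aggregate all unordered haplotype pairs into a genotype distribution.

    One O(H^2) pass; distinct phase pairs that collapse to the same unphased
    genotype are accumulated.  Raises :class:`SupportCapExceeded` when the
    pair count exceeds ``cap`` (use the registry model's Monte Carlo mode for
    such supports).
    """
    sub = (
        marginalize_to(table, table.locus_set.subset(considered_loci))
        if considered_loci is not None
        else table
    )
    haps = sub.sorted_haplotypes()
    H = len(haps)
    n_pairs = H * (H + 1) // 2
    if n_pairs > cap:
        raise SupportCapExceeded(
            f"{n_pairs} genotype pairs exceed the exact-enumeration cap "
            f"({cap}); use Monte Carlo mode instead"
        )
    loci = tuple(sub.locus_set)
    entries: dict[UnphasedGenotype, float] = {}
    for i in range(H):
        fi = sub.freqs[haps[i]]
        for j in range(i, H):
            p = fi * sub.freqs[haps[j]]
            if i != j:
                p *= 2.0
            g = UnphasedGenotype.from_haplotypes(haps[i], haps[j], loci)
            entries[g] = entries.get(g, 0.0) + p

    genotypes = list(entries)
    probs = np.array([entries[g] for g in genotypes], dtype=float)
    allele_codes: list[dict[str, int]] = []
    for li in range(len(loci)):
        codes: dict[str, int] = {}
        for g in genotypes:
            for allele in g.pairs[li]:
                codes.setdefault(allele, len(codes))
        allele_codes.append(codes)
    codes_arr = np.empty((len(genotypes), len(loci), 2), dtype=np.int64)
    for gi, g in enumerate(genotypes):
        for li, (a, b) in enumerate(g.pairs):
            codes_arr[gi, li, 0] = allele_codes[li][a]
            codes_arr[gi, li, 1] = allele_codes[li][b]
    return GenotypeProbabilityMap(
        loci=loci,
        population=sub.population,
        genotypes=genotypes,
        probs=probs,
        _entries=entries,
        _allele_codes=allele_codes,
        codes=codes_arr,
    )


def match_prob_vector(
    pop_map: GenotypeProbabilityMap,
    patient_genotypes: Sequence[UnphasedGenotype],
    allowed_mismatches: int,
) -> np.ndarray:
    """q_k(g) for a batch of patient genotypes against one population map."""
    patient_codes = pop_map.encode(patient_genotypes)
    mm = mismatch_matrix(patient_codes, pop_map.codes)
    return (mm <= allowed_mismatches) @ pop_map.probs


def donor_match_prob(
    table_k: HaplotypeFrequencyTable,
    patient_g: UnphasedGenotype,
    stringency: MatchStringency,
    pop_map: GenotypeProbabilityMap | None = None,
    cap: int = DEFAULT_SUPPORT_CAP,
) -> float:
    """Probability that a random population-k donor matches the patient.

    q_k(g) sums the HWE probability of every donor genotype within the
    stringency's mismatch budget of the patient over the considered loci; at
    zero budget this reduces to a single map lookup.
    """
    if pop_map is None:
        pop_map = build_genotype_probability_map(
            table_k, stringency.considered_loci, cap=cap
        )
    patient = patient_g.restrict(pop_map.loci)
    if stringency.allowed_mismatches == 0:
        return pop_map.prob(patient)
    return float(
        match_prob_vector(pop_map, [patient], stringency.allowed_mismatches)[0]
    )
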