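"""Synthetic multi-population haplotype pools, genotype samples and registries.

The generator emulates the structure of a large multi-population donor
registry: each population has its own haplotype frequency spectrum defined at
the haplotype level (linkage disequilibrium arises because each population's
support is a sparse subset of the allele-combination space, not a product of
allele frequencies), a fraction of haplotypes shared with a common pool, the
rest population-private, and per-population donor counts and availability
rates.  A "minority" population is one whose haplotypes are mostly private
and individually rare.

Also houses the brute-force oracles used to validate the analytic machinery:
exhaustive donor-pair enumeration for per-donor match probabilities and full
registry simulation for the at-least-one-match likelihood.

Randomness: one master seed is split with ``numpy.random.SeedSequence`` into
named substreams (stream 0: haplotype support sampling; stream 1+i:
population i frequency draw), so every output is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import (
    Haplotype,
    LocusSet,
    MatchStringency,
    UnphasedGenotype,
    mismatch_count,
)
from .registry import Population, Registry, effective_donors
from .tables import HaplotypeFrequencyTable

DEFAULT_SCENARIO_SEED = 1729

BRUTE_FORCE_MAX_SUPPORT = 200


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator, for recovery tests."""

    tables: dict[str, HaplotypeFrequencyTable]
    shared_pool: list[Haplotype]
    n_loci: int
    alleles_per_locus: int
    n_haplotypes: tuple[int, ...]
    overlap: tuple[float, ...]
    concentration: float
    seed: int


def _decode(index: int, n_loci: int, alleles_per_locus: int, loci) -> Haplotype:
    alleles = []
    for li in range(n_loci):
        index, a = divmod(index, alleles_per_locus)
        alleles.append(f"{loci[li]}*{a + 1:02d}")
    return Haplotype(tuple(alleles))


def generate_population_tables(
    n_populations: int,
    n_loci: int = 4,
    alleles_per_locus: int = 4,
    n_haplotypes: int | Sequence[int] = 20,
    overlap: float | Sequence[float] = 0.3,
    concentration: float = 0.5,
    seed: int = 0,
    population_labels: Sequence[str] | None = None,
    locus_names: Sequence[str] | None = None,
) -> SyntheticTruth:
    """Draw per-population haplotype supports and Dirichlet frequencies.

    Each population's support contains ``round(overlap * n_haplotypes)``
    haplotypes taken from a common shared pool; the remainder is private and
    disjoint across populations.  Frequencies are a symmetric
    Dirichlet(``concentration``) draw; the default 0.5 gives the skewed
    spectra characteristic of HLA haplotype tables.
    """
    if n_populations < 1:
        raise ValueError("need at least one population")
    n_hap = (
        tuple(n_haplotypes)
        if not isinstance(n_haplotypes, int)
        else (n_haplotypes,) * n_populations
    )
    ov = (
        tuple(overlap)
        if isinstance(overlap, Sequence)
        else (float(overlap),) * n_populations
    )
    if len(n_hap) != n_populations or len(ov) != n_populations:
        raise ValueError("n_haplotypes / overlap length must match populations")
    for o in ov:
        if not 0.0 <= o <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
    loci = tuple(locus_names) if locus_names else tuple(
        ("A", "B", "C", "DRB1")[:n_loci]
        if n_loci <= 4
        else [f"L{i + 1}" for i in range(n_loci)]
    )
    if len(loci) != n_loci:
        raise ValueError("locus_names length must equal n_loci")
    labels = (
        list(population_labels)
        if population_labels
        else [f"POP{i + 1}" for i in range(n_populations)]
    )

    space = alleles_per_locus**n_loci
    n_shared_per_pop = [round(o * nh) for o, nh in zip(ov, n_hap)]
    pool_size = max(n_shared_per_pop) if n_shared_per_pop else 0
    n_private = [nh - ns for nh, ns in zip(n_hap, n_shared_per_pop)]
    needed = pool_size + sum(n_private)
    if needed > space:
        raise ValueError(
            f"support of {needed} haplotypes infeasible in a space of "
            f"{space} allele combinations"
        )

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + n_populations)
    support_rng = np.random.default_rng(children[0])

    used: set[int] = set()

    def draw_distinct(rng: np.random.Generator, k: int) -> list[int]:
        out: list[int] = []
        while len(out) < k:
            cand = int(rng.integers(space))
            if cand not in used:
                used.add(cand)
                out.append(cand)
        return out

    pool_idx = draw_distinct(support_rng, pool_size)
    shared_pool = [
        _decode(i, n_loci, alleles_per_locus, loci) for i in pool_idx
    ]
    locus_set = LocusSet(loci)

    tables: dict[str, HaplotypeFrequencyTable] = {}
    for p in range(n_populations):
        private_idx = draw_distinct(support_rng, n_private[p])
        support = shared_pool[: n_shared_per_pop[p]] + [
            _decode(i, n_loci, alleles_per_locus, loci) for i in private_idx
        ]
        freq_rng = np.random.default_rng(children[1 + p])
        f = freq_rng.dirichlet(np.full(len(support), concentration))
        tables[labels[p]] = HaplotypeFrequencyTable(
            locus_set,
            labels[p],
            {h: float(fi) for h, fi in zip(support, f)},
        )
    return SyntheticTruth(
        tables=tables,
        shared_pool=shared_pool,
        n_loci=n_loci,
        alleles_per_locus=alleles_per_locus,
        n_haplotypes=n_hap,
        overlap=ov,
        concentration=concentration,
        seed=seed,
    )


def sample_genotypes(
    table: HaplotypeFrequencyTable,
    n: int,
    seed: int | None = None,
    id_prefix: str | None = None,
) -> list[UnphasedGenotype]:
    """Sample n unphased genotypes under HWE (two i.i.d. haplotype draws)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    haps = table.sorted_haplotypes()
    p = np.array([table.freqs[h] for h in haps], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(haps), size=(n, 2), p=p)
    loci = tuple(table.locus_set)
    prefix = id_prefix or table.population
    return [
        UnphasedGenotype.from_haplotypes(
            haps[i],
            haps[j],
            loci,
            population=table.population,
            id=f"{prefix}-{k:06d}",
        )
        for k, (i, j) in enumerate(idx)
    ]


def brute_force_match_prob(
    table_k: HaplotypeFrequencyTable,
    patient_g: UnphasedGenotype,
    stringency: MatchStringency,
) -> float:
    """Per-donor match probability by exhaustive ordered-pair enumeration.

    Independent oracle for :func:`hlamatch.algebra.donor_match_prob`: sums
    f(h1) f(h2) over all ordered donor haplotype pairs whose unphased
    genotype is within the mismatch budget of the patient.
    """
    if len(table_k) > BRUTE_FORCE_MAX_SUPPORT:
        raise ValueError(
            f"brute force limited to {BRUTE_FORCE_MAX_SUPPORT} haplotypes"
        )
    loci = tuple(
        l for l in table_k.locus_set if l in set(stringency.considered_loci)
    )
    indices = [table_k.locus_set.index(l) for l in loci]
    patient = patient_g.restrict(loci)
    haps = table_k.sorted_haplotypes()
    total = 0.0
    for h1 in haps:
        f1 = table_k.freqs[h1]
        r1 = h1.restrict(indices)
        for h2 in haps:
            donor = UnphasedGenotype.from_haplotypes(
                r1, h2.restrict(indices), loci
            )
            if (
                mismatch_count(donor, patient, loci)
                <= stringency.allowed_mismatches
            ):
                total += f1 * table_k.freqs[h2]
    return total


def simulate_registry_search(
    registry: Registry,
    patient_population: str,
    stringency: MatchStringency,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Empirical at-least-one-match frequency by full registry simulation.

    Independent oracle for the analytic registry likelihood on small
    registries: per replicate, draws one patient genotype and every donor's
    genotype from their populations' HWE distributions and records whether
    any donor is within the mismatch budget.  Effective donor counts
    (donors x availability) must be integers.  Returns the empirical match
    frequency and its binomial standard error.
    """
    if n_replicates < 1000:
        raise ValueError("need >= 1000 replicates for a stable estimate")
    n_eff = effective_donors(registry)
    counts: dict[str, int] = {}
    for label, n in n_eff.items():
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"effective donor count for {label!r} is {n}, not an integer"
            )
        counts[label] = int(round(n))
    if sum(counts.values()) > 1000:
        raise ValueError("simulation oracle is intended for small registries")

    loci = tuple(
        l for l in registry.locus_set if l in set(stringency.considered_loci)
    )
    budget = stringency.allowed_mismatches
    rng = np.random.default_rng(seed)

    # shared integer coding across all populations so codes are comparable
    from .algebra import marginalize_to

    sub_tables = {
        p.label: marginalize_to(p.table, registry.locus_set.subset(loci))
        for p in registry.populations
    }
    allele_codes: list[dict[str, int]] = [dict() for _ in loci]
    hap_codes: dict[str, np.ndarray] = {}
    hap_probs: dict[str, np.ndarray] = {}
    for label, sub in sub_tables.items():
        haps = sub.sorted_haplotypes()
        arr = np.empty((len(haps), len(loci)), dtype=np.int64)
        for hi, h in enumerate(haps):
            for li, a in enumerate(h.alleles):
                arr[hi, li] = allele_codes[li].setdefault(a, len(allele_codes[li]))
        hap_codes[label] = arr
        p = np.array([sub.freqs[h] for h in haps], dtype=float)
        hap_probs[label] = p / p.sum()

    pat = patient_population
    pat_idx = rng.choice(
        hap_codes[pat].shape[0], size=(n_replicates, 2), p=hap_probs[pat]
    )
    # patient allele pairs per locus: (n_replicates,) each
    pa = hap_codes[pat][pat_idx[:, 0], :]  # (R, L)
    pb = hap_codes[pat][pat_idx[:, 1], :]

    matched = np.zeros(n_replicates, dtype=bool)
    for label, n_donors in counts.items():
        if n_donors == 0:
            continue
        didx = rng.choice(
            hap_codes[label].shape[0],
            size=(n_replicates, n_donors, 2),
            p=hap_probs[label],
        )
        da = hap_codes[label][didx[..., 0], :]  # (R, D, L)
        db = hap_codes[label][didx[..., 1], :]
        mm = np.zeros((n_replicates, n_donors), dtype=np.int64)
        for li in range(len(loci)):
            a1 = da[..., li]
            a2 = db[..., li]
            b1 = pa[:, None, li]
            b2 = pb[:, None, li]
            het = ((a1 == b1) | (a1 == b2)).astype(np.int64) + (
                (a2 == b1) | (a2 == b2)
            ).astype(np.int64)
            hom = np.minimum(
                2, (b1 == a1).astype(np.int64) + (b2 == a1).astype(np.int64)
            )
            mm += 2 - np.where(a1 == a2, hom, het)
        matched |= (mm <= budget).any(axis=1)

    freq = float(matched.mean())
    se = math.sqrt(freq * (1.0 - freq) / n_replicates)
    return freq, se


def minority_scenario(seed: int = DEFAULT_SCENARIO_SEED) -> tuple[SyntheticTruth, Registry]:
    """The packaged two-population scenario used by the replica workflow.

    A majority population (support mostly shared with the common pool, 20
    haplotypes, many available donors) and a minority population (support
    mostly private, 36 individually rarer haplotypes, few available donors).
    By construction the minority population has a lower baseline full-match
    likelihood and benefits more from dropping a locus from consideration.
    """
    truth = generate_population_tables(
        n_populations=2,
        n_loci=4,
        alleles_per_locus=6,
        n_haplotypes=(20, 36),
        overlap=(0.9, 0.1),
        concentration=0.5,
        seed=seed,
        population_labels=["MAJ", "MIN"],
    )
    registry = Registry(
        [
            Population("MAJ", truth.tables["MAJ"], donors=4000, availability=0.6),
            Population("MIN", truth.tables["MIN"], donors=500, availability=0.4),
        ]
    )
    return truth, registry
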