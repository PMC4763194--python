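"""Expectation-maximization estimation of multi-locus haplotype frequencies.

Unphased genotypes leave the gametic phase ambiguous: a genotype heterozygous
at H loci is compatible with 2^(H-1) unordered haplotype pairs.  The EM
algorithm resolves this by alternating between (E) distributing each genotype
over its compatible phase pairs in proportion to the current haplotype
frequencies — pair (h1, h2) gets weight f(h1) f(h2), doubled when h1 != h2
because two ordered phases realize it — and (M) setting each haplotype
frequency to its expected gamete count divided by 2n.  The observed-data
log-likelihood is non-decreasing across iterations; this is asserted at every
step.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .genotypes import Haplotype, LocusSet, UnphasedGenotype
from .tables import HaplotypeFrequencyTable

logger = logging.getLogger(__name__)

PRUNE_THRESHOLD = 1e-12


@dataclass
class EMResult:
    """Outcome of one EM run: the fitted table plus convergence diagnostics."""

    table: HaplotypeFrequencyTable
    log_likelihood: float
    n_iterations: int
    converged: bool
    init: str = "uniform"
    seed: int | None = None


def enumerate_phase_decompositions(
    g: UnphasedGenotype,
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs whose per-locus multisets reproduce ``g``.

    Returns 2^(H-1) distinct pairs for H >= 1 heterozygous loci and a single
    (h, h) pair for a fully homozygous genotype.
    """
    het = [i for i, (a, b) in enumerate(g.pairs) if a != b]
    n = len(g.pairs)
    if not het:
        h = Haplotype(tuple(a for a, _ in g.pairs))
        return [(h, h)]
    pairs: list[tuple[Haplotype, Haplotype]] = []
    # fix the orientation of the first heterozygous locus: enumerates each
    # unordered pair exactly once
    for flips in itertools.product((False, True), repeat=len(het) - 1):
        a1 = [a for a, _ in g.pairs]
        a2 = [b for _, b in g.pairs]
        for locus_idx, flip in zip(het[1:], flips):
            if flip:
                a1[locus_idx], a2[locus_idx] = a2[locus_idx], a1[locus_idx]
        pairs.append((Haplotype(tuple(a1)), Haplotype(tuple(a2))))
    return pairs


def genotype_probability(
    table: HaplotypeFrequencyTable, g: UnphasedGenotype
) -> float:
    """P(g) under Hardy-Weinberg equilibrium for the table's population."""
    p = 0.0
    for h1, h2 in enumerate_phase_decompositions(g):
        f1 = table.get(h1)
        if f1 == 0.0:
            continue
        f2 = table.get(h2)
        p += (1.0 if h1 == h2 else 2.0) * f1 * f2
    return p


def zero_probability_ids(
    table: HaplotypeFrequencyTable, genotypes: Iterable[UnphasedGenotype]
) -> list[str]:
    """Ids of genotypes with zero probability under the table."""
    return [
        g.id or f"<row {i}>"
        for i, g in enumerate(genotypes)
        if genotype_probability(table, g) == 0.0
    ]


def log_likelihood(
    table: HaplotypeFrequencyTable, genotypes: Sequence[UnphasedGenotype]
) -> float:
    """Observed-data log-likelihood Sum_g log P(g).

    Returns ``-inf`` when any genotype has zero probability; the offending
    genotype ids are reported on the module logger.
    """
    total = 0.0
    offenders: list[str] = []
    for i, g in enumerate(genotypes):
        p = genotype_probability(table, g)
        if p <= 0.0:
            offenders.append(g.id or f"<row {i}>")
        else:
            total += math.log(p)
    if offenders:
        logger.warning(
            "%d genotype(s) have zero probability under the table: %s",
            len(offenders),
            ", ".join(offenders),
        )
        return float("-inf")
    return total


def _aggregate(
    genotypes: Sequence[UnphasedGenotype], locus_set: LocusSet
) -> tuple[list[UnphasedGenotype], np.ndarray]:
    """Unique genotypes (restricted to the locus set) with multiplicities."""
    counts: dict[UnphasedGenotype, int] = {}
    order: list[UnphasedGenotype] = []
    for g in genotypes:
        key = g.restrict(locus_set) if g.loci != tuple(locus_set) else g
        if key not in counts:
            counts[key] = 0
            order.append(key)
        counts[key] += 1
    return order, np.array([counts[g] for g in order], dtype=float)


def em_estimate(
    genotypes: Sequence[UnphasedGenotype],
    locus_set: LocusSet | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: str = "uniform",
    seed: int | None = None,
    population: str | None = None,
) -> EMResult:
    """Run EM on unphased genotypes; see :class:`HaplotypeFrequencyEM`."""
    est = HaplotypeFrequencyEM(
        locus_set=locus_set,
        tol=tol,
        max_iter=max_iter,
        init=init,
        random_state=seed,
        population=population,
    )
    est.fit(genotypes)
    return EMResult(
        table=est.table_,
        log_likelihood=est.log_likelihood_,
        n_iterations=est.n_iter_,
        converged=est.converged_,
        init=init,
        seed=seed,
    )


class HaplotypeFrequencyEM(BaseEstimator):
    """Maximum-likelihood haplotype frequencies from unphased genotypes.

    Parameters
    ----------
    locus_set : LocusSet, optional
        Loci over which haplotypes are defined; defaults to the loci of the
        first genotype seen in :meth:`fit`.
    tol : float, default 1e-8
        Convergence threshold on the change in observed-data log-likelihood.
    max_iter : int, default 1000
        Iteration cap.
    init : {"uniform", "random"}, default "uniform"
        ``"uniform"`` starts from equal mass on every haplotype compatible
        with at least one observation; ``"random"`` draws the start from a
        flat Dirichlet using ``random_state``.  The uniform start can sit on
        a stationary ridge (e.g. data made only of double heterozygotes);
        random restarts expose such multimodality.
    random_state : int, optional
        Seed for the random initialization.
    population : str, optional
        Label stored on the fitted table; defaults to the genotypes' label.

    Attributes
    ----------
    table_ : HaplotypeFrequencyTable
        Fitted frequency table (pruned of mass below 1e-12, renormalized).
    haplotypes_ : list[Haplotype]
        Support, aligned with ``frequencies_``.
    frequencies_ : ndarray
        Fitted frequencies.
    log_likelihood_ : float
        Final observed-data log-likelihood.
    n_iter_ : int
        Iterations performed.
    converged_ : bool
        Whether the tolerance was met before ``max_iter``.
    """

    def __init__(
        self,
        locus_set: LocusSet | None = None,
        tol: float = 1e-8,
        max_iter: int = 1000,
        init: str = "uniform",
        random_state: int | None = None,
        population: str | None = None,
    ) -> None:
        self.locus_set = locus_set
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state
        self.population = population

    def fit(self, X: Sequence[UnphasedGenotype], y=None) -> "HaplotypeFrequencyEM":
        genotypes = list(X)
        if not genotypes:
            raise ValueError("em_estimate requires at least one genotype")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init not in ("uniform", "random"):
            raise ValueError(f"unknown init {self.init!r}")
        locus_set = self.locus_set or LocusSet(genotypes[0].loci)

        uniq, counts = _aggregate(genotypes, locus_set)
        n = counts.sum()

        # support: every haplotype compatible with >= 1 observation
        hap_index: dict[Haplotype, int] = {}
        decomps: list[list[tuple[int, int]]] = []
        for g in uniq:
            pairs = []
            for h1, h2 in enumerate_phase_decompositions(g):
                i = hap_index.setdefault(h1, len(hap_index))
                j = hap_index.setdefault(h2, len(hap_index))
                pairs.append((i, j))
            decomps.append(pairs)
        haplotypes = list(hap_index)
        H = len(haplotypes)

        if self.init == "uniform":
            f = np.full(H, 1.0 / H)
        else:
            rng = np.random.default_rng(self.random_state)
            f = rng.dirichlet(np.ones(H))

        prev_ll = -np.inf
        ll = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            expected = np.zeros(H)
            ll = 0.0
            for g_idx, pairs in enumerate(decomps):
                c = counts[g_idx]
                ws = [
                    (2.0 if i != j else 1.0) * f[i] * f[j] for i, j in pairs
                ]
                s = sum(ws)
                ll += c * math.log(s)
                for (i, j), w in zip(pairs, ws):
                    share = c * w / s
                    expected[i] += share
                    expected[j] += share
            f = expected / (2.0 * n)
            # EM guarantees monotone likelihood; a violation beyond round-off
            # indicates an implementation bug
            if ll < prev_ll - 1e-8 * (abs(prev_ll) + 1.0):
                raise RuntimeError(
                    f"log-likelihood decreased at iteration {n_iter}: "
                    f"{prev_ll} -> {ll}"
                )
            if math.isfinite(prev_ll) and abs(ll - prev_ll) < self.tol:
                converged = True
                break
            prev_ll = ll

        keep = f >= PRUNE_THRESHOLD
        f_kept = f[keep]
        f_kept = f_kept / f_kept.sum()
        kept_haps = [h for h, k in zip(haplotypes, keep) if k]
        freqs = {h: float(fi) for h, fi in zip(kept_haps, f_kept)}

        label = self.population or (genotypes[0].population or "pop")
        self.table_ = HaplotypeFrequencyTable(locus_set, label, freqs)
        self.haplotypes_ = kept_haps
        self.frequencies_ = f_kept
        self.log_likelihood_ = float(ll)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def score(self, X: Sequence[UnphasedGenotype], y=None) -> float:
        """Mean per-genotype log-likelihood under the fitted table."""
        genotypes = list(X)
        return log_likelihood(self.table_, genotypes) / len(genotypes)
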