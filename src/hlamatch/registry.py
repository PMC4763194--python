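"""Registry-scale match likelihood under the Hardy-Weinberg matching model.

A registry is a set of populations, each with a haplotype-frequency table, a
registered donor count and an availability rate.  The effective donor count
is N_k = donors_k x availability_k (kept real-valued: the model is a
population-level expectation, not a census of individuals).

For a patient genotype g the probability that at least one of the registry's
effective donors matches at the chosen stringency is

    1 - prod_k (1 - q_k(g))^(N_k)

where q_k(g) is the per-donor match probability in population k.  The match
likelihood for a patient population is the expectation of this quantity over
the population's own HWE genotype distribution, computed either exactly (by
enumerating the patient genotype-probability map) or by Monte Carlo over
sampled patient genotypes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .algebra import (
    DEFAULT_SUPPORT_CAP,
    GenotypeProbabilityMap,
    build_genotype_probability_map,
    match_prob_vector,
)
from .genotypes import LocusSet, MatchStringency, UnphasedGenotype
from .tables import (
    HaplotypeFrequencyTable,
    read_frequency_tables_csv,
    read_frequency_tables_json,
)

MIN_MC_SAMPLES = 100
DEFAULT_MC_SAMPLES = 100_000


@dataclass
class Population:
    label: str
    table: HaplotypeFrequencyTable
    donors: int
    availability: float

    def __post_init__(self) -> None:
        if self.donors < 0:
            raise ValueError("donor count must be non-negative")
        if not 0.0 <= self.availability <= 1.0:
            raise ValueError("availability rate must lie in [0, 1]")


@dataclass
class Registry:
    populations: list[Population]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate population labels in {labels!r}")
        if not self.populations:
            raise ValueError("registry must contain at least one population")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def get(self, label: str) -> Population:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(f"no population {label!r} in registry")

    @property
    def locus_set(self) -> LocusSet:
        return self.populations[0].table.locus_set


@dataclass
class MatchLikelihoodResult:
    """Match likelihood for one patient population at one stringency."""

    patient_population: str
    stringency: str
    likelihood: float
    method: str  # "exact" | "monte_carlo"
    n_samples: int | None = None
    seed: int | None = None
    standard_error: float | None = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.likelihood <= 1.0 + 1e-12:
            raise ValueError(f"likelihood {self.likelihood} outside [0, 1]")
        self.likelihood = min(1.0, max(0.0, self.likelihood))
        if self.method == "monte_carlo":
            if self.n_samples is None or self.seed is None or (
                self.standard_error is None
            ):
                raise ValueError(
                    "monte_carlo results must carry n_samples, seed and "
                    "standard_error"
                )


def effective_donors(registry: Registry) -> dict[str, float]:
    """N_k = registered donors x availability rate, per population (unrounded)."""
    return {p.label: p.donors * p.availability for p in registry.populations}


def _miss_probability(
    q_by_pop: Mapping[str, np.ndarray], n_eff: Mapping[str, float]
) -> np.ndarray:
    """prod_k (1 - q_k)^(N_k), vectorized over patient genotypes.

    Computed as exp(sum_k N_k log1p(-q_k)) for numerical stability with tiny
    q and large N; q = 1 short-circuits to a zero factor.
    """
    first = next(iter(q_by_pop.values()))
    log_miss = np.zeros_like(first, dtype=float)
    for label, q in q_by_pop.items():
        n = n_eff[label]
        if n == 0.0:
            continue
        q = np.clip(q, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            log_miss += np.where(q >= 1.0, -np.inf, n * np.log1p(-q))
    return np.exp(log_miss)


def _stringency_label(stringency: MatchStringency) -> str:
    if stringency.name:
        return stringency.name
    return (
        f"{2 * len(stringency.considered_loci) - stringency.allowed_mismatches}"
        f"/{2 * len(stringency.considered_loci)}"
    )


def registry_match_likelihood(
    registry: Registry,
    patient_population: str,
    stringency: MatchStringency,
    method: str = "exact",
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | None = None,
    cap: int = DEFAULT_SUPPORT_CAP,
) -> MatchLikelihoodResult:
    """Probability that the registry holds >= 1 matching donor for a patient.

    The patient genotype is drawn from the patient population's own HWE
    distribution; donors of every population count toward the search.  Exact
    mode enumerates the patient genotype map; Monte Carlo mode averages over
    sampled patient genotypes and reports the standard error of the mean.
    """
    patient_pop = registry.get(patient_population)
    n_eff = effective_donors(registry)
    budget = stringency.allowed_mismatches

    donor_maps: dict[str, GenotypeProbabilityMap] = {
        p.label: build_genotype_probability_map(
            p.table, stringency.considered_loci, cap=cap
        )
        for p in registry.populations
    }

    if method == "exact":
        patient_map = build_genotype_probability_map(
            patient_pop.table, stringency.considered_loci, cap=cap
        )
        q_by_pop = {
            label: match_prob_vector(dmap, patient_map.genotypes, budget)
            for label, dmap in donor_maps.items()
        }
        hit = 1.0 - _miss_probability(q_by_pop, n_eff)
        likelihood = float(patient_map.probs @ hit)
        return MatchLikelihoodResult(
            patient_population=patient_population,
            stringency=_stringency_label(stringency),
            likelihood=likelihood,
            method="exact",
        )

    if method == "monte_carlo":
        if n_samples < MIN_MC_SAMPLES:
            raise ValueError(
                f"monte_carlo requires n_samples >= {MIN_MC_SAMPLES}"
            )
        if seed is None:
            raise ValueError("monte_carlo requires an explicit seed")
        from .algebra import marginalize_to  # local import avoids cycle risk

        sub = marginalize_to(
            patient_pop.table,
            patient_pop.table.locus_set.subset(stringency.considered_loci),
        )
        haps = sub.sorted_haplotypes()
        p = np.array([sub.freqs[h] for h in haps], dtype=float)
        p = p / p.sum()
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(haps), size=(n_samples, 2), p=p)
        loci = tuple(sub.locus_set)
        # aggregate identical sampled genotypes: q is computed once per
        # distinct genotype
        counts: dict[UnphasedGenotype, int] = {}
        for i, j in idx:
            g = UnphasedGenotype.from_haplotypes(haps[i], haps[j], loci)
            counts[g] = counts.get(g, 0) + 1
        uniq = list(counts)
        w = np.array([counts[g] for g in uniq], dtype=float)
        q_by_pop = {
            label: match_prob_vector(dmap, uniq, budget)
            for label, dmap in donor_maps.items()
        }
        hit = 1.0 - _miss_probability(q_by_pop, n_eff)
        mean = float(w @ hit) / n_samples
        var = float(w @ (hit - mean) ** 2) / (n_samples - 1)
        se = math.sqrt(var / n_samples)
        return MatchLikelihoodResult(
            patient_population=patient_population,
            stringency=_stringency_label(stringency),
            likelihood=mean,
            method="monte_carlo",
            n_samples=n_samples,
            seed=seed,
            standard_error=se,
        )

    raise ValueError(f"unknown method {method!r}")


def locus_drop_report(
    registry: Registry,
    patient_populations: Sequence[str] | None = None,
    base_locus_set: LocusSet | None = None,
    method: str = "exact",
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | None = None,
    cap: int = DEFAULT_SUPPORT_CAP,
) -> pd.DataFrame:
    """Per-population likelihood table for the locus-elimination analysis.

    For each patient population the report gives the baseline full-locus
    likelihoods (8/8 and 7/8 for four loci) and, for each single locus
    dropped from consideration, the perfect-match and one-mismatch
    likelihoods (6/6 and 5/6) together with their absolute gains over the
    corresponding baseline — the "open bar" increments of a stacked report.
    """
    base = base_locus_set or registry.locus_set
    pops = list(patient_populations or registry.labels)
    L = len(base)
    full_name = f"{2 * L}/{2 * L}"
    one_mm_name = f"{2 * L - 1}/{2 * L}"
    d_full = 2 * (L - 1)
    drop_names = {
        locus: (f"{d_full}/{d_full}:{locus}", f"{d_full - 1}/{d_full}:{locus}")
        for locus in base
    }

    def run(pop: str, stringency: MatchStringency) -> float:
        return registry_match_likelihood(
            registry,
            pop,
            stringency,
            method=method,
            n_samples=n_samples,
            seed=seed,
            cap=cap,
        ).likelihood

    rows = []
    for pop in pops:
        row: dict[str, object] = {"population": pop}
        p_full = run(pop, MatchStringency(base, 0, name=full_name))
        p_one = run(pop, MatchStringency(base, 1, name=one_mm_name))
        row[full_name] = p_full
        row[one_mm_name] = p_one
        for locus in base:
            name0, name1 = drop_names[locus]
            reduced = base.drop(locus)
            p0 = run(pop, MatchStringency(reduced, 0, name=name0))
            p1 = run(pop, MatchStringency(reduced, 1, name=name1))
            row[name0] = p0
            row[name1] = p1
            row[f"gain_{name0}"] = p0 - p_full
            row[f"gain_{name1}"] = p1 - p_one
        rows.append(row)
    return pd.DataFrame(rows)


def load_registry_config(path: Union[str, Path]) -> Registry:
    """Read a registry from a YAML or JSON config.

    Layout::

        populations:
          - label: EUR
            frequency_table: eur_freqs.csv   # path relative to the config
            donors: 100000
            availability: 0.6

    Frequency tables may be the CSV or JSON dialect of :mod:`hlamatch.tables`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, Mapping) or "populations" not in cfg:
        raise ValueError(f"registry config {path} lacks a 'populations' list")
    populations = []
    for entry in cfg["populations"]:
        table_path = Path(entry["frequency_table"])
        if not table_path.is_absolute():
            table_path = path.parent / table_path
        if table_path.suffix.lower() == ".json":
            tables = read_frequency_tables_json(table_path)
        else:
            tables = read_frequency_tables_csv(table_path)
        label = entry["label"]
        if label in tables:
            table = tables[label]
        elif len(tables) == 1:
            table = next(iter(tables.values()))
        else:
            raise ValueError(
                f"frequency table {table_path} has no population {label!r}"
            )
        populations.append(
            Population(
                label=label,
                table=table,
                donors=int(entry["donors"]),
                availability=float(entry["availability"]),
            )
        )
    return Registry(populations)
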