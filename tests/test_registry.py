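"""Registry-scale match likelihood: effective donors, closed forms, modes, report."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hlamatch import (
    MatchStringency,
    Population,
    Registry,
    effective_donors,
    generate_population_tables,
    locus_drop_report,
    registry_match_likelihood,
    simulate_registry_search,
)

from helpers import FOUR_LOCI, TWO_LOCI, table


def two_pop_registry(seed=0, donors=(200, 50), availability=(0.5, 0.5)):
    truth = generate_population_tables(
        2, n_loci=4, alleles_per_locus=3, n_haplotypes=8, overlap=0.4,
        seed=seed,
    )
    pops = [
        Population(label, t, donors=d, availability=a)
        for (label, t), d, a in zip(truth.tables.items(), donors, availability)
    ]
    return Registry(pops)


class TestEffectiveDonors:
    def test_direct_product(self):
        reg = two_pop_registry(donors=(100, 10), availability=(0.6, 1.0))
        n = effective_donors(reg)
        assert n[reg.labels[0]] == 60.0
        assert n[reg.labels[1]] == 10.0

    def test_zero_availability(self):
        reg = two_pop_registry(donors=(100, 10), availability=(0.0, 0.5))
        assert effective_donors(reg)[reg.labels[0]] == 0.0


class TestRegistryLikelihood:
    def test_degenerate_pool_every_donor_matches(self):
        t = table({("A1", "B1", "C1", "D1"): 1.0}, population="P")
        reg = Registry([Population("P", t, donors=5, availability=1.0)])
        for budget in (0, 1):
            r = registry_match_likelihood(
                reg, "P", MatchStringency(FOUR_LOCI, budget)
            )
            assert r.likelihood == 1.0

    def test_closed_form_constant_q(self):
        # patient population is a single haplotype, so the patient genotype
        # is unique; the donor pool matches exactly when the donor is
        # homozygous for the shared haplotype: q = s^2 with s = sqrt(1/2),
        # N = 2 effective donors, hence 1 - (1 - 1/2)^2 = 3/4
        s = math.sqrt(0.5)
        pat = table({("A1", "B1"): 1.0}, loci=TWO_LOCI, population="PAT")
        donor = table(
            {("A1", "B1"): s, ("A2", "B2"): 1.0 - s},
            loci=TWO_LOCI,
            population="DON",
        )
        reg = Registry(
            [
                Population("PAT", pat, donors=0, availability=1.0),
                Population("DON", donor, donors=2, availability=1.0),
            ]
        )
        q = s * s
        expected = 1.0 - (1.0 - q) ** 2
        r = registry_match_likelihood(reg, "PAT", MatchStringency(TWO_LOCI, 0))
        assert r.likelihood == pytest.approx(expected, abs=1e-12)
        assert r.likelihood == pytest.approx(0.75, abs=1e-12)

    def test_fractional_effective_donors_in_exponent(self):
        # availability scales the exponent, not a rounded count
        s = math.sqrt(0.5)
        pat = table({("A1", "B1"): 1.0}, loci=TWO_LOCI, population="PAT")
        donor = table(
            {("A1", "B1"): s, ("A2", "B2"): 1.0 - s},
            loci=TWO_LOCI,
            population="DON",
        )
        reg = Registry(
            [
                Population("PAT", pat, donors=0, availability=1.0),
                Population("DON", donor, donors=5, availability=0.5),
            ]
        )
        r = registry_match_likelihood(reg, "PAT", MatchStringency(TWO_LOCI, 0))
        assert r.likelihood == pytest.approx(1.0 - 0.5**2.5, abs=1e-12)

    def test_all_zero_donors_gives_zero(self):
        reg = two_pop_registry(donors=(0, 0))
        r = registry_match_likelihood(
            reg, reg.labels[0], MatchStringency(FOUR_LOCI, 1)
        )
        assert r.likelihood == 0.0

    def test_monotone_in_registry_size(self):
        s = MatchStringency(FOUR_LOCI, 0)
        prev = 0.0
        for donors in (10, 50, 200, 1000):
            reg = two_pop_registry(donors=(donors, donors // 2))
            lik = registry_match_likelihood(reg, reg.labels[0], s).likelihood
            assert lik >= prev - 1e-12
            prev = lik

    def test_exact_and_monte_carlo_agree(self):
        reg = two_pop_registry(seed=3)
        s = MatchStringency(FOUR_LOCI, 1)
        exact = registry_match_likelihood(reg, reg.labels[0], s).likelihood
        mc = registry_match_likelihood(
            reg, reg.labels[0], s, method="monte_carlo",
            n_samples=50_000, seed=11,
        )
        assert mc.standard_error is not None and mc.standard_error > 0
        assert abs(mc.likelihood - exact) < 3 * mc.standard_error

    def test_monte_carlo_requires_seed_and_enough_samples(self):
        reg = two_pop_registry()
        s = MatchStringency(FOUR_LOCI, 0)
        with pytest.raises(ValueError):
            registry_match_likelihood(
                reg, reg.labels[0], s, method="monte_carlo", n_samples=50, seed=1
            )
        with pytest.raises(ValueError):
            registry_match_likelihood(
                reg, reg.labels[0], s, method="monte_carlo", n_samples=1000
            )

    def test_monte_carlo_deterministic_under_seed(self):
        reg = two_pop_registry()
        s = MatchStringency(FOUR_LOCI, 0)
        r1 = registry_match_likelihood(
            reg, reg.labels[0], s, method="monte_carlo", n_samples=1000, seed=7
        )
        r2 = registry_match_likelihood(
            reg, reg.labels[0], s, method="monte_carlo", n_samples=1000, seed=7
        )
        assert r1.likelihood == r2.likelihood
        assert r1.standard_error == r2.standard_error

    def test_unknown_patient_population(self):
        reg = two_pop_registry()
        with pytest.raises(KeyError):
            registry_match_likelihood(
                reg, "NOPE", MatchStringency(FOUR_LOCI, 0)
            )


class TestSimulationOracle:
    def test_analytic_likelihood_within_three_se(self):
        reg = two_pop_registry(seed=5, donors=(20, 10), availability=(1.0, 1.0))
        s = MatchStringency(FOUR_LOCI, 1)
        exact = registry_match_likelihood(reg, reg.labels[0], s).likelihood
        freq, se = simulate_registry_search(
            reg, reg.labels[0], s, n_replicates=10_000, seed=17
        )
        assert abs(freq - exact) < 3 * max(se, 1e-6)

    def test_single_haplotype_world(self):
        t = table({("A1", "B1", "C1", "D1"): 1.0}, population="P")
        reg = Registry([Population("P", t, donors=3, availability=1.0)])
        freq, se = simulate_registry_search(
            reg, "P", MatchStringency(FOUR_LOCI, 0), n_replicates=1000, seed=1
        )
        assert freq == 1.0

    def test_zero_donor_registry(self):
        t = table({("A1", "B1", "C1", "D1"): 1.0}, population="P")
        reg = Registry([Population("P", t, donors=0, availability=1.0)])
        freq, _ = simulate_registry_search(
            reg, "P", MatchStringency(FOUR_LOCI, 0), n_replicates=1000, seed=1
        )
        assert freq == 0.0

    def test_non_integer_effective_counts_rejected(self):
        reg = two_pop_registry(donors=(3, 3), availability=(0.5, 1.0))
        with pytest.raises(ValueError, match="integer"):
            simulate_registry_search(
                reg, reg.labels[0], MatchStringency(FOUR_LOCI, 0),
                n_replicates=1000, seed=1,
            )


class TestLocusDropReport:
    def test_degenerate_registry_all_ones(self):
        t = table({("A1", "B1", "C1", "D1"): 1.0}, population="P")
        reg = Registry([Population("P", t, donors=5, availability=1.0)])
        df = locus_drop_report(reg)
        likelihood_cols = [
            c for c in df.columns if c != "population" and not c.startswith("gain_")
        ]
        assert (df[likelihood_cols] == 1.0).all().all()
        gain_cols = [c for c in df.columns if c.startswith("gain_")]
        assert (df[gain_cols] == 0.0).all().all()

    def test_report_shape(self):
        reg = two_pop_registry()
        df = locus_drop_report(reg)
        assert len(df) == 2
        likelihood_cols = [
            c for c in df.columns if c != "population" and not c.startswith("gain_")
        ]
        assert len(likelihood_cols) == 2 + 2 * 4
        assert {"8/8", "7/8", "6/6:A", "5/6:DRB1"} <= set(df.columns)

    def test_stringency_orderings_hold(self):
        df = locus_drop_report(two_pop_registry(seed=9))
        for _, row in df.iterrows():
            assert row["8/8"] <= row["7/8"] + 1e-12
            for locus in FOUR_LOCI:
                assert row[f"6/6:{locus}"] >= row["8/8"] - 1e-12
                assert row[f"5/6:{locus}"] >= row[f"6/6:{locus}"] - 1e-12
                assert row[f"5/6:{locus}"] >= row["7/8"] - 1e-12

    def test_minority_pattern_on_constructed_registry(self):
        # low-overlap minority with rarer haplotypes: lower baseline, strictly
        # positive gain from dropping any locus
        truth = generate_population_tables(
            2, n_loci=4, alleles_per_locus=5, n_haplotypes=(12, 24),
            overlap=(0.9, 0.1), seed=21, population_labels=["MAJ", "MIN"],
        )
        reg = Registry(
            [
                Population("MAJ", truth.tables["MAJ"], 2000, 0.6),
                Population("MIN", truth.tables["MIN"], 300, 0.4),
            ]
        )
        df = locus_drop_report(reg).set_index("population")
        assert df.loc["MIN", "8/8"] < df.loc["MAJ", "8/8"]
        for locus in FOUR_LOCI:
            assert df.loc["MIN", f"gain_6/6:{locus}"] > 0.0
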