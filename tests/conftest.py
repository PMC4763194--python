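"""Shared fixtures."""

from __future__ import annotations

import pytest

from hlamatch import HaplotypeFrequencyTable, LocusSet

from helpers import FOUR_LOCI, TWO_LOCI, table


@pytest.fixture
def four_loci() -> LocusSet:
    return FOUR_LOCI


@pytest.fixture
def two_loci() -> LocusSet:
    return TWO_LOCI


@pytest.fixture
def two_hap_table() -> HaplotypeFrequencyTable:
    """Two equifrequent 4-locus haplotypes differing at every locus."""
    return table(
        {
            ("A1", "B1", "C1", "D1"): 0.5,
            ("A2", "B2", "C2", "D2"): 0.5,
        }
    )
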