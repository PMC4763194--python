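"""Domain types for HLA loci, haplotypes, unphased genotypes and match stringencies.

The matching problem is defined over a fixed, ordered set of HLA loci
(classically A, B, C, DRB1).  A haplotype is one allele per locus on a single
chromosome; an unphased genotype is the per-locus unordered allele pair an
individual carries, without phase information.  Allele codes are opaque
strings: no HLA nomenclature parsing or truncation is performed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

DEFAULT_LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1")


class GenotypeFormatError(ValueError):
    """A genotype table violates the expected CSV layout."""


@dataclass(frozen=True)
class LocusSet:
    """Ordered, canonical set of locus names used to index haplotype tuples."""

    loci: tuple[str, ...] = DEFAULT_LOCI

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if not self.loci:
            raise ValueError("LocusSet must contain at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError(f"duplicate locus names in {self.loci!r}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[str]:
        return iter(self.loci)

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci

    def index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in {self.loci!r}") from None

    def subset(self, keep: Iterable[str]) -> "LocusSet":
        """Sub-LocusSet preserving this set's canonical order."""
        keep = set(keep)
        unknown = keep - set(self.loci)
        if unknown:
            raise KeyError(f"unknown loci {sorted(unknown)!r}")
        return LocusSet(tuple(l for l in self.loci if l in keep))

    def drop(self, locus: str) -> "LocusSet":
        if locus not in self.loci:
            raise KeyError(f"locus {locus!r} not in {self.loci!r}")
        remaining = tuple(l for l in self.loci if l != locus)
        if not remaining:
            raise ValueError("cannot drop the last locus")
        return LocusSet(remaining)


@dataclass(frozen=True)
class Haplotype:
    """One allele per locus of a LocusSet; hashable so it can key frequency tables."""

    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))

    def __len__(self) -> int:
        return len(self.alleles)

    def drop(self, index: int) -> "Haplotype":
        return Haplotype(self.alleles[:index] + self.alleles[index + 1 :])

    def restrict(self, indices: Sequence[int]) -> "Haplotype":
        return Haplotype(tuple(self.alleles[i] for i in indices))


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True, eq=False)
class UnphasedGenotype:
    """Per-locus unordered allele pairs for one individual.

    Pairs are stored in canonical (sorted) order, so genotypes that list the
    same alleles in a different order compare equal.  ``population`` and ``id``
    are carried as annotations and excluded from equality and hashing.
    """

    loci: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    population: str | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        loci = tuple(self.loci)
        if len(loci) != len(self.pairs):
            raise ValueError("one allele pair required per locus")
        object.__setattr__(self, "loci", loci)
        object.__setattr__(
            self, "pairs", tuple(_canonical_pair(a, b) for a, b in self.pairs)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnphasedGenotype):
            return NotImplemented
        return self.loci == other.loci and self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash((self.loci, self.pairs))

    def pair_at(self, locus: str) -> tuple[str, str]:
        try:
            return self.pairs[self.loci.index(locus)]
        except ValueError:
            raise KeyError(f"genotype lacks locus {locus!r}") from None

    def restrict(self, loci: Iterable[str]) -> "UnphasedGenotype":
        """Genotype over a locus subset, in the order the subset is given."""
        loci = tuple(loci)
        return UnphasedGenotype(
            loci,
            tuple(self.pair_at(l) for l in loci),
            population=self.population,
            id=self.id,
        )

    @classmethod
    def from_haplotypes(
        cls,
        h1: Haplotype,
        h2: Haplotype,
        loci: Sequence[str],
        population: str | None = None,
        id: str | None = None,
    ) -> "UnphasedGenotype":
        if len(h1) != len(loci) or len(h2) != len(loci):
            raise ValueError("haplotype length must equal locus count")
        pairs = tuple(
            _canonical_pair(a, b) for a, b in zip(h1.alleles, h2.alleles)
        )
        return cls(tuple(loci), pairs, population=population, id=id)


@dataclass(frozen=True)
class MatchStringency:
    """Considered locus set plus an allele-mismatch budget.

    Presets follow registry usage: ``8/8`` is zero mismatches over four loci,
    ``7/8`` allows a single allele mismatch, and ``6/6``/``5/6`` are the
    analogous criteria after one locus is removed from consideration
    (``"6/6:A"`` drops locus A).
    """

    considered_loci: LocusSet
    allowed_mismatches: int = 0
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.considered_loci) == 0:
            raise ValueError("considered_loci must be non-empty")
        if not 0 <= self.allowed_mismatches <= 2 * len(self.considered_loci):
            raise ValueError(
                "allowed_mismatches must lie in [0, 2 x number of considered loci]"
            )

    @classmethod
    def from_string(
        cls, text: str, locus_set: LocusSet | None = None
    ) -> "MatchStringency":
        """Parse ``"8/8"``, ``"7/8"``, ``"6/6:L"`` or ``"5/6:L"``."""
        locus_set = locus_set or LocusSet()
        head, _, dropped = text.partition(":")
        head = head.strip()
        dropped = dropped.strip()
        if head in ("8/8", "7/8"):
            if dropped:
                raise ValueError(f"{head} takes no dropped locus: {text!r}")
            return cls(locus_set, 0 if head == "8/8" else 1, name=text)
        if head in ("6/6", "5/6"):
            if not dropped:
                raise ValueError(
                    f"{head} requires a dropped locus, e.g. '{head}:A'"
                )
            return cls(
                locus_set.drop(dropped), 0 if head == "6/6" else 1, name=text
            )
        raise ValueError(f"unknown stringency {text!r}")


def mismatch_count(
    g1: UnphasedGenotype,
    g2: UnphasedGenotype,
    stringency_loci: Iterable[str],
) -> int:
    """Total allele mismatches between two genotypes over the considered loci.

    Per locus the mismatch is ``2 - |multiset intersection|`` of the two
    allele pairs (a homozygote contributes its allele twice), so the total
    ranges over ``[0, 2 x number of loci]`` and is symmetric.
    """
    total = 0
    for locus in stringency_loci:
        a1, a2 = g1.pair_at(locus)
        b1, b2 = g2.pair_at(locus)
        if a1 == a2:
            inter = min(2, (b1 == a1) + (b2 == a1))
        elif b1 == b2:
            inter = (a1 == b1) + (a2 == b1)
        else:
            inter = (a1 in (b1, b2)) + (a2 in (b1, b2))
        total += 2 - inter
    return total


def parse_genotype_table(
    source: Union[str, Path, TextIO],
    locus_set: LocusSet | None = None,
) -> list[UnphasedGenotype]:
    """Read unphased genotypes from a CSV table.

    Expected header: ``id,population`` followed by ``<locus>_1,<locus>_2`` for
    every locus of ``locus_set``.  Lines starting with ``#`` are treated as
    metadata and skipped.  Missing columns, empty allele cells and duplicate
    ids raise :class:`GenotypeFormatError`; untyped loci are not supported.
    """
    locus_set = locus_set or LocusSet()
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return parse_genotype_table(fh, locus_set)

    filtered = (line for line in source if not line.startswith("#"))
    reader = csv.DictReader(filtered)
    if reader.fieldnames is None:
        raise GenotypeFormatError("empty genotype table: no header row")
    required = ["id", "population"] + [
        f"{locus}_{k}" for locus in locus_set for k in (1, 2)
    ]
    for col in required:
        if col not in reader.fieldnames:
            raise GenotypeFormatError(f"missing required column {col!r}")

    genotypes: list[UnphasedGenotype] = []
    seen_ids: set[str] = set()
    for row in reader:
        row_id = (row.get("id") or "").strip()
        if not row_id:
            raise GenotypeFormatError("row with empty id")
        if row_id in seen_ids:
            raise GenotypeFormatError(f"duplicate id {row_id!r}")
        seen_ids.add(row_id)
        pairs = []
        for locus in locus_set:
            a = (row.get(f"{locus}_1") or "").strip()
            b = (row.get(f"{locus}_2") or "").strip()
            if not a or not b:
                raise GenotypeFormatError(
                    f"empty allele cell at locus {locus} for id {row_id!r} "
                    "(missing typing is not supported)"
                )
            pairs.append((a, b))
        genotypes.append(
            UnphasedGenotype(
                tuple(locus_set),
                tuple(pairs),
                population=(row.get("population") or "").strip() or None,
                id=row_id,
            )
        )
    return genotypes


def write_genotype_table(
    genotypes: Sequence[UnphasedGenotype],
    path: Union[str, Path],
    locus_set: LocusSet | None = None,
    header_comment: str | None = None,
) -> None:
    """Write genotypes as the CSV dialect read by :func:`parse_genotype_table`."""
    if not genotypes:
        raise ValueError("no genotypes to write")
    locus_set = locus_set or LocusSet(genotypes[0].loci)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "population"]
            + [f"{l}_{k}" for l in locus_set for k in (1, 2)]
        )
        for i, g in enumerate(genotypes):
            cells = [g.id or f"G{i:06d}", g.population or ""]
            for locus in locus_set:
                a, b = g.pair_at(locus)
                cells.extend([a, b])
            writer.writerow(cells)
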