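"""Population haplotype-frequency tables and their CSV/JSON serialization.

A table holds, for one population, a probability distribution f(h) over
multi-locus haplotypes.  Frequencies live at the haplotype level, never as
products of allele frequencies, which is how linkage disequilibrium between
the loci is represented.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

from .genotypes import Haplotype, LocusSet

# frequencies are serialized with 17 significant digits: lossless for float64
_FLOAT_FMT = "%.17g"

SUM_TOL = 1e-9


@dataclass
class HaplotypeFrequencyTable:
    """Distribution over haplotypes for one population.

    Invariants (checked on construction): every frequency is non-negative,
    every key conforms to the locus set, and the frequencies sum to 1 within
    ``SUM_TOL``.
    """

    locus_set: LocusSet
    population: str
    freqs: dict[Haplotype, float]

    def __post_init__(self) -> None:
        n_loci = len(self.locus_set)
        total = 0.0
        for hap, f in self.freqs.items():
            if len(hap) != n_loci:
                raise ValueError(
                    f"haplotype {hap.alleles!r} does not conform to "
                    f"{len(self.locus_set)}-locus set {tuple(self.locus_set)!r}"
                )
            if not (f >= 0.0) or not math.isfinite(f):
                raise ValueError(f"invalid frequency {f!r} for {hap.alleles!r}")
            total += f
        if not self.freqs:
            raise ValueError("frequency table must contain at least one haplotype")
        if abs(total - 1.0) > SUM_TOL:
            raise ValueError(
                f"frequencies for population {self.population!r} sum to "
                f"{total!r}, not 1"
            )

    def __len__(self) -> int:
        return len(self.freqs)

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.freqs)

    def items(self):
        return self.freqs.items()

    def get(self, hap: Haplotype, default: float = 0.0) -> float:
        return self.freqs.get(hap, default)

    def sorted_haplotypes(self) -> list[Haplotype]:
        """Haplotypes in a deterministic (lexicographic) order."""
        return sorted(self.freqs, key=lambda h: h.alleles)

    def alleles_at(self, locus: str) -> set[str]:
        i = self.locus_set.index(locus)
        return {h.alleles[i] for h in self.freqs}


def write_frequency_tables_csv(
    tables: Iterable[HaplotypeFrequencyTable],
    path: Union[str, Path],
    header_comment: str | None = None,
) -> None:
    """Write one or more population tables to a single CSV.

    Columns: ``population``, one column per locus, ``frequency``.  Frequencies
    are printed with 17 significant digits so a read/write round trip is
    lossless.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to write")
    locus_set = tables[0].locus_set
    for t in tables:
        if tuple(t.locus_set) != tuple(locus_set):
            raise ValueError("all tables in one file must share a locus set")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["population", *locus_set, "frequency"])
        for t in tables:
            for hap in t.sorted_haplotypes():
                writer.writerow(
                    [t.population, *hap.alleles, _FLOAT_FMT % t.freqs[hap]]
                )


def read_frequency_tables_csv(
    path: Union[str, Path], locus_set: LocusSet | None = None
) -> dict[str, HaplotypeFrequencyTable]:
    """Read population tables from CSV; returns ``{population: table}``."""
    with open(path, newline="", encoding="utf-8") as fh:
        filtered = (line for line in fh if not line.startswith("#"))
        reader = csv.reader(filtered)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"empty frequency table file {path}") from None
        if header[0] != "population" or header[-1] != "frequency":
            raise ValueError(
                "frequency CSV must have columns population,<loci...>,frequency"
            )
        file_loci = LocusSet(tuple(header[1:-1]))
        if locus_set is not None and tuple(locus_set) != tuple(file_loci):
            raise ValueError(
                f"file loci {tuple(file_loci)!r} do not match expected "
                f"{tuple(locus_set)!r}"
            )
        per_pop: dict[str, dict[Haplotype, float]] = {}
        for row in reader:
            if not row:
                continue
            pop, *alleles, freq = row
            per_pop.setdefault(pop, {})[Haplotype(tuple(alleles))] = float(freq)
    return {
        pop: HaplotypeFrequencyTable(file_loci, pop, freqs)
        for pop, freqs in per_pop.items()
    }


def tables_to_json_dict(tables: Iterable[HaplotypeFrequencyTable]) -> dict:
    tables = list(tables)
    locus_set = tables[0].locus_set
    return {
        "loci": list(locus_set),
        "populations": [
            {
                "population": t.population,
                "haplotypes": [
                    {"alleles": list(h.alleles), "frequency": t.freqs[h]}
                    for h in t.sorted_haplotypes()
                ],
            }
            for t in tables
        ],
    }


def tables_from_json_dict(obj: Mapping) -> dict[str, HaplotypeFrequencyTable]:
    locus_set = LocusSet(tuple(obj["loci"]))
    out: dict[str, HaplotypeFrequencyTable] = {}
    for entry in obj["populations"]:
        freqs = {
            Haplotype(tuple(h["alleles"])): float(h["frequency"])
            for h in entry["haplotypes"]
        }
        out[entry["population"]] = HaplotypeFrequencyTable(
            locus_set, entry["population"], freqs
        )
    return out


def write_frequency_tables_json(
    tables: Iterable[HaplotypeFrequencyTable],
    path: Union[str, Path],
    meta: Mapping | None = None,
) -> None:
    obj = tables_to_json_dict(tables)
    if meta:
        obj["meta"] = dict(meta)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_frequency_tables_json(
    path: Union[str, Path]
) -> dict[str, HaplotypeFrequencyTable]:
    with open(path, encoding="utf-8") as fh:
        return tables_from_json_dict(json.load(fh))
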