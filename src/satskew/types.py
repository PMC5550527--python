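"""Core domain types shared by every stage of the pipeline.

Alleles are PCR fragment lengths in integer base pairs (codominant diploid
markers).  A genotype is an *unordered* pair of alleles; ``MISSING`` (0)
marks an untyped locus.  Dates are ``datetime.date``; residency intervals
are half-open ``[start, end)`` so that adjacent intervals never
double-count a day.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

#: Sentinel for an untyped allele (GenePop convention).
MISSING: int = 0


class RepeatClass(str, Enum):
    DI = "di"
    TETRA = "tetra"


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker: a name, its repeat class and its allele registry."""

    name: str
    repeat_class: RepeatClass = RepeatClass.TETRA
    alleles: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alleles):
            raise ValueError(f"locus {self.name}: allele lengths must be positive")


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid genotype of one individual at one locus.

    Normalised so ``allele_a <= allele_b``; both alleles are MISSING or
    both are present.
    """

    individual_id: str
    locus: str
    allele_a: int
    allele_b: int

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a == MISSING) != (b == MISSING):
            raise ValueError(
                f"{self.individual_id}@{self.locus}: half-missing genotype {a}/{b}"
            )
        if a < 0 or b < 0:
            raise ValueError(f"negative allele length {a}/{b}")
        if a > b:
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a == MISSING

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.allele_a != self.allele_b

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele_a, self.allele_b)


class GenotypePanel:
    """Consensus diploid genotypes for a set of individuals over a marker panel.

    Thin mapping ``(individual_id, locus) -> Genotype`` plus per-locus
    allele registries.  Missing genotypes may be stored explicitly or
    simply absent; :meth:`get` treats both as untyped.
    """

    def __init__(self, genotypes: Iterable[Genotype] = ()) -> None:
        self._calls: dict[tuple[str, str], Genotype] = {}
        self.loci: list[str] = []
        self.individuals: list[str] = []
        for g in genotypes:
            self.add(g)

    def add(self, g: Genotype) -> None:
        key = (g.individual_id, g.locus)
        if key in self._calls:
            raise ValueError(f"duplicate genotype row for {key}")
        self._calls[key] = g
        if g.locus not in self.loci:
            self.loci.append(g.locus)
        if g.individual_id not in self.individuals:
            self.individuals.append(g.individual_id)

    def get(self, individual_id: str, locus: str) -> Genotype | None:
        """Return the call, or None when untyped/absent."""
        g = self._calls.get((individual_id, locus))
        if g is None or g.is_missing:
            return None
        return g

    def __iter__(self) -> Iterator[Genotype]:
        return iter(self._calls.values())

    def __len__(self) -> int:
        return len(self._calls)

    def allele_registry(self, locus: str) -> list[int]:
        """Sorted distinct non-missing alleles observed at *locus*."""
        out = {
            a
            for (_, loc), g in self._calls.items()
            if loc == locus and not g.is_missing
            for a in g.alleles
        }
        return sorted(out)

    def typed_loci(self, individual_id: str) -> list[str]:
        return [
            loc for loc in self.loci if self.get(individual_id, loc) is not None
        ]

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypePanel":
        keep = set(ids)
        return GenotypePanel(
            g for (ind, _), g in self._calls.items() if ind in keep
        )


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


@dataclass
class Individual:
    id: str
    sex: Sex = Sex.UNKNOWN
    group: str | None = None
    natal_group: str | None = None
    birth_date: _dt.date | None = None
    mother_id: str | None = None
    candidate_sire: bool = False

    def __post_init__(self) -> None:
        if self.candidate_sire and self.sex != Sex.MALE:
            raise ValueError(f"{self.id}: candidate sire must be male")


@dataclass(frozen=True)
class ResidencyRecord:
    """One male's continuous residency in one group, half-open [start, end)."""

    male_id: str
    group: str
    start_date: _dt.date
    end_date: _dt.date

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError(
                f"{self.male_id}@{self.group}: empty residency interval"
            )

    def days_in_year(self, year: int) -> int:
        """Number of residency days falling in calendar *year*."""
        lo = max(self.start_date, _dt.date(year, 1, 1))
        hi = min(self.end_date, _dt.date(year + 1, 1, 1))
        return max(0, (hi - lo).days)

    def covers(self, day: _dt.date) -> bool:
        return self.start_date <= day < self.end_date


@dataclass(frozen=True)
class OffspringCase:
    offspring_id: str
    mother_id: str
    birth_group: str
    birth_date: _dt.date
    conception_date: _dt.date

    def __post_init__(self) -> None:
        if self.conception_date >= self.birth_date:
            raise ValueError(
                f"{self.offspring_id}: conception on/after birth"
            )


@dataclass
class Demography:
    """Validated bundle of field observations: who is who, where and when."""

    individuals: dict[str, Individual]
    residencies: list[ResidencyRecord]
    offspring_cases: list[OffspringCase]
    dominance_periods: dict[str, "object"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for ind in self.individuals.values():
            if ind.mother_id is not None:
                mother = self.individuals.get(ind.mother_id)
                if mother is None:
                    raise ValueError(f"{ind.id}: dangling mother_id {ind.mother_id}")
                if mother.sex == Sex.MALE:
                    raise ValueError(f"{ind.id}: mother {mother.id} is male")
        # non-overlap of one male's intervals within a group
        by_key: dict[tuple[str, str], list[ResidencyRecord]] = {}
        for r in self.residencies:
            by_key.setdefault((r.male_id, r.group), []).append(r)
        for (male, group), recs in by_key.items():
            recs = sorted(recs, key=lambda r: r.start_date)
            for prev, nxt in zip(recs, recs[1:]):
                if nxt.start_date < prev.end_date:
                    raise ValueError(
                        f"overlapping residency for {male} in {group}"
                    )
        for case in self.offspring_cases:
            if case.mother_id not in self.individuals:
                raise ValueError(f"{case.offspring_id}: unknown mother {case.mother_id}")

    def candidate_sires(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.candidate_sire]

    def residencies_for(self, male_id: str) -> list[ResidencyRecord]:
        return [r for r in self.residencies if r.male_id == male_id]

    def resident_in(self, male_id: str, group: str, day: _dt.date) -> bool:
        return any(
            r.covers(day)
            for r in self.residencies
            if r.male_id == male_id and r.group == group
        )


def frequencies_valid(freqs: Mapping[int, float], tol: float = 1e-9) -> bool:
    total = sum(freqs.values())
    return abs(total - 1.0) <= tol and all(f >= 0 for f in freqs.values())
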