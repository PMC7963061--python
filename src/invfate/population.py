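"""Haplotype/individual/population data model and fitness.

Selection is multiplicative across loci and fully recessive: only mutations
carried on both haplotypes of an individual reduce its fitness, each by a
factor max(0, 1 + s). Heterokaryotypes (IS) get the imposed advantage
``1 + s_het`` regardless of allelic content. Because selection is soft
(offspring always refill the population, fitness is relative), mutations fixed
in the whole population contribute no load and are pruned into a substitution
log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .params import GenomeLayout

__all__ = [
    "Mutation",
    "Haplotype",
    "Individual",
    "Population",
    "SubstitutionRecord",
    "ExtinctionError",
    "karyotype",
    "individual_fitness",
    "haplotype_load",
    "prune_global_fixations",
]

STANDARD = "S"
INVERTED = "I"


class ExtinctionError(RuntimeError):
    """All individuals have fitness zero; no parent can be drawn."""


@dataclass(frozen=True)
class Mutation:
    """A deleterious recessive mutation at a coding position."""

    id: int
    chrom: int
    pos: int
    s: float
    origin_gen: int

    def __post_init__(self) -> None:
        if self.s >= 0:
            raise ValueError(f"mutations are deleterious; got s = {self.s}")

    def region_class(self, layout: GenomeLayout) -> str:
        return layout.region_class(self.chrom, self.pos)

    @property
    def sort_key(self) -> tuple[int, int, int]:
        return (self.chrom, self.pos, self.id)


class Haplotype:
    """An ordered collection of mutations plus an arrangement flag.

    Mutations are kept sorted by (chrom, pos, id). Instances share mutation
    objects freely (copy-on-write by contract: gamete construction builds new
    tuples, never mutates a parent's).
    """

    __slots__ = ("mutations", "arrangement")

    def __init__(self, mutations: Iterable[Mutation] = (), arrangement: str = STANDARD):
        muts = tuple(sorted(mutations, key=lambda m: m.sort_key))
        if arrangement not in (STANDARD, INVERTED):
            raise ValueError(f"arrangement must be 'S' or 'I', got {arrangement!r}")
        self.mutations = muts
        self.arrangement = arrangement

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def mutation_ids(self) -> frozenset[int]:
        return frozenset(m.id for m in self.mutations)

    def with_arrangement(self, arrangement: str) -> "Haplotype":
        h = Haplotype.__new__(Haplotype)
        h.mutations = self.mutations
        h.arrangement = arrangement
        return h

    def __repr__(self) -> str:
        return f"Haplotype(n={len(self.mutations)}, arrangement={self.arrangement})"


@dataclass
class Individual:
    hap_a: Haplotype
    hap_b: Haplotype
    cached_fitness: Optional[float] = None


@dataclass
class SubstitutionRecord:
    """A mutation fixed in the whole population, removed from all haplotypes."""

    mutation: Mutation
    fixation_gen: int
    region_class: str
    scope: str = "whole-population"


@dataclass
class Population:
    """Exactly N diploid individuals plus bookkeeping."""

    individuals: list[Individual]
    generation: int = 0
    substitutions: list[SubstitutionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.individuals) < 1:
            raise ValueError("population must contain at least one individual")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def haplotypes(self) -> list[Haplotype]:
        out = []
        for ind in self.individuals:
            out.append(ind.hap_a)
            out.append(ind.hap_b)
        return out

    @property
    def inversion_present(self) -> bool:
        return any(h.arrangement == INVERTED for h in self.haplotypes())

    def inversion_count(self) -> int:
        return sum(1 for h in self.haplotypes() if h.arrangement == INVERTED)


def karyotype(ind: Individual) -> str:
    """Diploid arrangement combination: 'SS', 'IS' or 'II' (order-insensitive)."""
    a, b = ind.hap_a.arrangement, ind.hap_b.arrangement
    if a == b:
        return "II" if a == INVERTED else "SS"
    return "IS"


def individual_fitness(ind: Individual, s_het: float) -> float:
    """Multiplicative recessive fitness with heterokaryotype advantage.

    w = prod over mutations on BOTH haplotypes of max(0, 1 + s), times
    (1 + s_het) iff the individual is a heterokaryotype. Heterozygous
    mutations contribute nothing (full recessivity). Factors are clamped at
    zero so that gamma-tail draws with |s| >= 1 act as lethals.
    """
    shared = ind.hap_a.mutation_ids() & ind.hap_b.mutation_ids()
    w = 1.0
    if shared:
        for m in ind.hap_a.mutations:
            if m.id in shared:
                w *= max(0.0, 1.0 + m.s)
    if karyotype(ind) == "IS":
        w *= 1.0 + s_het
    return w


def haplotype_load(h: Haplotype) -> float:
    """1 minus the fitness of a hypothetical homozygote for this haplotype."""
    w = 1.0
    for m in h.mutations:
        w *= max(0.0, 1.0 + m.s)
    return 1.0 - w


def prune_global_fixations(pop: Population, layout: GenomeLayout) -> list[SubstitutionRecord]:
    """Remove mutations carried by all 2N haplotypes; log them as substitutions.

    Under soft selection this multiplies every individual's fitness by the
    same constant and therefore leaves the offspring sampling distribution
    (and any seeded trajectory) unchanged.
    """
    haps = pop.haplotypes()
    counts: dict[int, int] = {}
    by_id: dict[int, Mutation] = {}
    for h in haps:
        for m in h.mutations:
            counts[m.id] = counts.get(m.id, 0) + 1
            by_id[m.id] = m
    total = len(haps)
    fixed_ids = {mid for mid, c in counts.items() if c == total}
    if not fixed_ids:
        return []
    records = [
        SubstitutionRecord(
            mutation=by_id[mid],
            fixation_gen=pop.generation,
            region_class=by_id[mid].region_class(layout),
        )
        for mid in sorted(fixed_ids)
    ]
    for ind in pop.individuals:
        for attr in ("hap_a", "hap_b"):
            h: Haplotype = getattr(ind, attr)
            kept = tuple(m for m in h.mutations if m.id not in fixed_ids)
            if len(kept) != len(h.mutations):
                nh = Haplotype.__new__(Haplotype)
                nh.mutations = kept
                nh.arrangement = h.arrangement
                setattr(ind, attr, nh)
        ind.cached_fitness = None
    pop.substitutions.extend(records)
    return records
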