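"""Meiosis and Wright-Fisher generation turnover (reference implementation).

This module is the executable definition of the reproduction model: how
recombination initiations are drawn, how crossovers are suppressed in the
inverted region of heterokaryotypes, how a gamete is assembled, and how the
next generation is sampled under soft selection. It favours clarity over
speed; :mod:`invfate.engine` runs the identical model on flat arrays for
long simulations.

Model summary
-------------
* The number of recombination initiations per meiosis is Poisson(r * L) with
  r the overall per-bp initiation rate and L the whole genome (coding and
  non-coding alike). Each initiation is independently a crossover with
  probability rho/(rho+gamma), otherwise a gene-conversion tract whose length
  is Poisson(lambda), extending rightward and truncated at the chromosome end.
* In heterokaryotype (IS) parents, crossover breakpoints inside the inversion
  span are deleted — no gamete death, fecundity preserved. Gene-conversion
  tracts are never deleted: only gene conversion mediates gene flux between
  arrangements. Double crossovers inside the span are excluded wholesale.
* Chromosomes assort independently (a fair coin chooses the starting parental
  haplotype per chromosome).
* New mutations arrive at Poisson(mu * coding bp) per gamete, uniform over
  coding positions, with fresh gamma DFE draws.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .params import (
    DFEParams,
    GenomeLayout,
    RecombinationParams,
    SimulationParameters,
    sample_selection_coefficient,
)
from .population import (
    ExtinctionError,
    Haplotype,
    Individual,
    Mutation,
    Population,
    individual_fitness,
    karyotype,
    prune_global_fixations,
)

__all__ = [
    "MeiosisEvents",
    "draw_meiosis_events",
    "suppress_heterokaryotype_crossovers",
    "make_gamete",
    "next_generation",
]


@dataclass
class MeiosisEvents:
    """Realized recombination initiations for one meiosis.

    ``crossovers`` holds (chrom, pos) breakpoints; ``gc_tracts`` holds
    (chrom, lo, hi) half-open tract intervals, already truncated at the
    chromosome end.
    """

    crossovers: list[tuple[int, int]] = field(default_factory=list)
    gc_tracts: list[tuple[int, int, int]] = field(default_factory=list)

    def n_events(self) -> int:
        return len(self.crossovers) + len(self.gc_tracts)


def draw_meiosis_events(
    rng: np.random.Generator, layout: GenomeLayout, recomb: RecombinationParams
) -> MeiosisEvents:
    """Draw crossover breakpoints and gene-conversion tracts for one meiosis."""
    L = layout.total_bp
    rate = recomb.total_initiation_rate * L
    n = rng.poisson(rate) if rate > 0 else 0
    events = MeiosisEvents()
    offsets = layout.chrom_offsets
    for _ in range(n):
        gpos = int(rng.integers(0, L))
        chrom, pos = layout.local_position(gpos)
        if rng.random() < recomb.p_crossover:
            events.crossovers.append((chrom, pos))
        else:
            tract_len = int(rng.poisson(recomb.gc_tract_mean))
            hi = min(pos + tract_len, layout.chromosomes[chrom])
            if hi > pos:
                events.gc_tracts.append((chrom, pos, hi))
    events.crossovers.sort()
    return events


def suppress_heterokaryotype_crossovers(
    events: MeiosisEvents, karyo: str, inversion_span: Optional[tuple[int, int]]
) -> MeiosisEvents:
    """Delete crossovers inside the inversion span for IS parents.

    Single crossovers inside an inversion heterokaryotype would produce
    unbalanced, inviable gametes; under soft selection, deleting the
    breakpoint (rather than killing and redrawing the gamete) yields the same
    genotype frequencies while preserving fecundity. Gene-conversion tracts
    are retained everywhere; homokaryotypes (SS, II) are unaffected.
    """
    if karyo != "IS" or inversion_span is None:
        return events
    lo, hi = inversion_span
    kept = [
        (c, p) for c, p in events.crossovers if not (c == 0 and lo <= p < hi)
    ]
    return MeiosisEvents(crossovers=kept, gc_tracts=list(events.gc_tracts))


def _segment_sources(
    rng: np.random.Generator,
    layout: GenomeLayout,
    events: MeiosisEvents,
) -> tuple[list[int], Callable[[int, int], int]]:
    """Build per-chromosome starting phases and a crossover-phase query.

    Returns ``start_phase`` (0 = hap_a leads, per chromosome) and a function
    mapping (chrom, pos) to the crossover phase at that position. Phase
    excludes gene conversion; a breakpoint at position b flips positions
    >= b.
    """
    start_phase = [int(rng.integers(0, 2)) for _ in layout.chromosomes]
    by_chrom: dict[int, list[int]] = {}
    for c, p in events.crossovers:
        by_chrom.setdefault(c, []).append(p)
    for lst in by_chrom.values():
        lst.sort()

    def phase(chrom: int, pos: int) -> int:
        bps = by_chrom.get(chrom, ())
        k = np.searchsorted(bps, pos, side="right") if bps else 0
        return (start_phase[chrom] + int(k)) % 2

    return start_phase, phase


def make_gamete(
    rng: np.random.Generator,
    parent: Individual,
    events: MeiosisEvents,
    layout: GenomeLayout,
    mu: float,
    dfe: DFEParams,
    generation: int,
    id_allocator: Optional[Callable[[], int]] = None,
) -> Haplotype:
    """Assemble one gamete from a parent given suppression-filtered events.

    The gamete alternates parental haplotypes at crossover breakpoints and
    copies the homologous haplotype across gene-conversion tracts. The
    arrangement flag is inherited from the haplotype contributing the
    inversion span (well defined because crossovers never fall inside the
    span of an IS parent). New mutations are then added at Poisson(mu *
    coding bp), uniform over coding positions.
    """
    if id_allocator is None:
        counter = itertools.count(10**12)  # test convenience; real runs pass one
        id_allocator = lambda: next(counter)

    haps = (parent.hap_a, parent.hap_b)
    _, phase = _segment_sources(rng, layout, events)

    def in_gc(chrom: int, pos: int) -> bool:
        return any(c == chrom and lo <= pos < hi for c, lo, hi in events.gc_tracts)

    def source(chrom: int, pos: int) -> int:
        return phase(chrom, pos) ^ (1 if in_gc(chrom, pos) else 0)

    new_muts: list[Mutation] = []
    seen: set[int] = set()
    for side, hap in enumerate(haps):
        for m in hap.mutations:
            if m.id in seen:
                continue
            other = haps[1 - side]
            if source(m.chrom, m.pos) == side:
                new_muts.append(m)
                seen.add(m.id)
            elif any(o.id == m.id for o in other.mutations):
                # carried by both parents: present regardless of source
                new_muts.append(m)
                seen.add(m.id)

    # arrangement from the crossover phase at the span (GC never moves it)
    span = layout.inversion_span
    if span is not None:
        arrangement = haps[phase(0, span[0])].arrangement
    else:
        arrangement = haps[phase(0, 0)].arrangement

    n_new = rng.poisson(mu * layout.coding_bp) if mu > 0 else 0
    if n_new:
        starts, ends = layout.coding_intervals_global()
        lens = ends - starts
        cum = np.concatenate([[0], np.cumsum(lens)])
        for _ in range(n_new):
            u = int(rng.integers(0, cum[-1]))
            seg = int(np.searchsorted(cum, u, side="right") - 1)
            gpos = int(starts[seg] + (u - cum[seg]))
            chrom, pos = layout.local_position(gpos)
            s = float(sample_selection_coefficient(rng, dfe))
            new_muts.append(
                Mutation(id=id_allocator(), chrom=chrom, pos=pos, s=s, origin_gen=generation)
            )

    return Haplotype(new_muts, arrangement=arrangement)


def next_generation(
    rng: np.random.Generator,
    pop: Population,
    params: SimulationParameters,
    id_allocator: Optional[Callable[[], int]] = None,
    prune: bool = True,
) -> Population:
    """One Wright-Fisher turnover under soft selection.

    N offspring are formed, each from two parents drawn independently with
    probability proportional to fitness (selfing permitted), one gamete per
    parent. Whole-population fixations are pruned afterwards.
    """
    layout = params.layout
    w = np.array([individual_fitness(ind, params.s_het) for ind in pop.individuals])
    total = w.sum()
    if total <= 0:
        raise ExtinctionError(f"all fitnesses are zero at generation {pop.generation}")
    probs = w / total
    generation = pop.generation + 1
    if id_allocator is None:
        start = 1 + max(
            (m.id for h in pop.haplotypes() for m in h.mutations), default=-1
        )
        counter = itertools.count(start)
        id_allocator = lambda: next(counter)

    span = layout.inversion_span
    offspring: list[Individual] = []
    for _ in range(pop.n):
        gametes = []
        for _parent_slot in range(2):
            p = pop.individuals[int(rng.choice(pop.n, p=probs))]
            events = draw_meiosis_events(rng, layout, params.recomb)
            events = suppress_heterokaryotype_crossovers(events, karyotype(p), span)
            gametes.append(
                make_gamete(
                    rng, p, events, layout, params.mu, params.dfe, generation, id_allocator
                )
            )
        offspring.append(Individual(hap_a=gametes[0], hap_b=gametes[1]))

    new_pop = Population(
        individuals=offspring, generation=generation, substitutions=list(pop.substitutions)
    )
    if prune:
        prune_global_fixations(new_pop, layout)
    return new_pop
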