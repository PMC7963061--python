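"""Array-backed population engine wrapping the numba kernel.

The :class:`Engine` owns the flat-array state consumed by
:mod:`invfate._kernel`, handles buffer growth and the substitution log, and
converts to and from the object model of :mod:`invfate.population` so that
all downstream statistics can work on either representation.

One engine at a time should drive the (global, seeded) kernel RNG; the
experiment layer runs replicates sequentially with sub-seeds derived from the
master seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel as K
from .params import SimulationParameters
from .population import (
    ExtinctionError,
    Haplotype,
    Individual,
    Mutation,
    Population,
    SubstitutionRecord,
)

__all__ = ["Engine"]

_SUB_COLUMNS = ["uid", "gpos", "s", "origin_gen", "fixation_gen"]


class Engine:
    """Wright-Fisher simulation state with kernel-backed turnover."""

    def __init__(
        self,
        params: SimulationParameters,
        seed: int,
        hap_cap: int = 256,
        mut_cap: int = 1 << 15,
        population: Optional[Population] = None,
    ):
        self.params = params
        self.seed = int(seed)
        layout = params.layout
        n_hap = 2 * params.N

        self._cap = int(hap_cap)
        self._mcap = int(mut_cap)
        self._hap = [
            np.zeros((n_hap, self._cap), dtype=np.int32),
            np.zeros((n_hap, self._cap), dtype=np.int32),
        ]
        self._hn = [np.zeros(n_hap, dtype=np.int32), np.zeros(n_hap, dtype=np.int32)]
        self._arr = [np.zeros(n_hap, dtype=np.uint8), np.zeros(n_hap, dtype=np.uint8)]
        self._alloc_mut_table(self._mcap)
        self.state = np.zeros(8, dtype=np.int64)
        self._sub_log = np.zeros((8192, 5), dtype=np.float64)
        self._sub_n = np.zeros(1, dtype=np.int64)
        self._sub_frames: list[pd.DataFrame] = []

        self.chrom_bounds = layout.chrom_offsets
        starts, ends = layout.coding_intervals_global()
        self.coding_lo = starts
        self.coding_cum = np.concatenate([[0], np.cumsum(ends - starts)]).astype(np.int64)
        self._span = (-1, -1)
        self._W = np.zeros(params.N, dtype=np.float64)
        self._Wc = np.zeros(params.N, dtype=np.float64)
        self._co_buf = np.zeros(64, dtype=np.int64)
        self._gc_lo = np.zeros(32, dtype=np.int64)
        self._gc_hi = np.zeros(32, dtype=np.int64)

        K.seed_rng(self.seed % (2**32))
        if population is not None:
            self._load_population(population)

    # -- construction -------------------------------------------------------

    def _alloc_mut_table(self, mcap: int) -> None:
        self.m_gpos = np.zeros(mcap, dtype=np.int64)
        self.m_s = np.zeros(mcap, dtype=np.float64)
        self.m_origin = np.zeros(mcap, dtype=np.int64)
        self.m_uid = np.zeros(mcap, dtype=np.int64)
        self.m_count = np.zeros(mcap, dtype=np.int64)
        self.m_inuse = np.zeros(mcap, dtype=np.uint8)
        self.m_remove = np.zeros(mcap, dtype=np.uint8)
        self._free = np.zeros(mcap, dtype=np.int64)
        self._mcap = mcap

    def _load_population(self, pop: Population) -> None:
        if pop.n != self.params.N:
            raise ValueError(f"population has {pop.n} individuals, params say {self.params.N}")
        layout = self.params.layout
        haps = pop.haplotypes()
        uid_map: dict[int, int] = {}
        slot = 0
        for h_i, h in enumerate(haps):
            row = []
            for m in h.mutations:
                if m.id not in uid_map:
                    uid_map[m.id] = slot
                    self.m_gpos[slot] = layout.global_position(m.chrom, m.pos)
                    self.m_s[slot] = m.s
                    self.m_origin[slot] = m.origin_gen
                    self.m_uid[slot] = m.id
                    self.m_inuse[slot] = 1
                    slot += 1
                row.append(uid_map[m.id])
            row.sort(key=lambda sl: (self.m_gpos[sl], self.m_uid[sl]))
            n = len(row)
            if n > self._cap:
                self._grow_hap(max(2 * self._cap, n + 64))
            cur = int(self.state[K.ST_PARITY])
            self._hap[cur][h_i, :n] = row
            self._hn[cur][h_i] = n
            self._arr[cur][h_i] = 1 if h.arrangement == "I" else 0
        self.state[K.ST_MNEXT] = slot
        self.state[K.ST_UID] = 1 + max(uid_map.keys(), default=-1)
        self.state[K.ST_GEN] = pop.generation
        if (self._arr[int(self.state[K.ST_PARITY])] == 1).any():
            self.state[K.ST_INV] = 1

    # -- growth -------------------------------------------------------------

    def _grow_hap(self, new_cap: Optional[int] = None) -> None:
        new_cap = new_cap or 2 * self._cap
        for k in range(2):
            grown = np.zeros((self._hap[k].shape[0], new_cap), dtype=np.int32)
            grown[:, : self._cap] = self._hap[k]
            self._hap[k] = grown
        self._cap = new_cap

    def _grow_mut(self) -> None:
        old = (
            self.m_gpos, self.m_s, self.m_origin, self.m_uid,
            self.m_count, self.m_inuse, self.m_remove, self._free,
        )
        n = self._mcap
        self._alloc_mut_table(2 * n)
        for new, prev in zip(
            (self.m_gpos, self.m_s, self.m_origin, self.m_uid,
             self.m_count, self.m_inuse, self.m_remove, self._free),
            old,
        ):
            new[:n] = prev

    def _drain_sub_log(self) -> None:
        n = int(self._sub_n[0])
        if n:
            self._sub_frames.append(
                pd.DataFrame(self._sub_log[:n].copy(), columns=_SUB_COLUMNS)
            )
            self._sub_n[0] = 0

    # -- core ---------------------------------------------------------------

    @property
    def generation(self) -> int:
        return int(self.state[K.ST_GEN])

    @property
    def n_hap(self) -> int:
        return 2 * self.params.N

    def _cur(self) -> int:
        return int(self.state[K.ST_PARITY])

    @property
    def hap(self) -> np.ndarray:
        return self._hap[self._cur()]

    @property
    def hap_n(self) -> np.ndarray:
        return self._hn[self._cur()]

    @property
    def arrangement(self) -> np.ndarray:
        return self._arr[self._cur()]

    def inversion_count(self) -> int:
        return int(self.arrangement.sum())

    def run(self, n_gens: int) -> str:
        """Advance up to ``n_gens`` generations.

        Returns ``'ok'`` (all generations done), ``'lost'`` or ``'fixed'``
        (inversion absorbed; simulation stops there). Raises
        :class:`ExtinctionError` if every individual has fitness zero.
        """
        p = self.params
        remaining = int(n_gens)
        while remaining > 0:
            status, done = K.advance(
                self._hap[0], self._hn[0], self._arr[0],
                self._hap[1], self._hn[1], self._arr[1],
                self.m_gpos, self.m_s, self.m_origin, self.m_uid,
                self.m_count, self.m_inuse, self.m_remove,
                self._free, self.state,
                self.chrom_bounds, self.coding_lo, self.coding_cum,
                p.mu * p.layout.coding_bp,
                p.recomb.total_initiation_rate * p.layout.total_bp,
                p.recomb.p_crossover,
                p.recomb.gc_tract_mean,
                p.dfe.shape, p.dfe.scale,
                self._span[0], self._span[1], p.s_het,
                remaining,
                self._sub_log, self._sub_n,
                self._W, self._Wc, self._co_buf, self._gc_lo, self._gc_hi,
            )
            remaining -= done
            if status == K.STATUS_OK:
                continue
            if status == K.STATUS_INV_LOST:
                return "lost"
            if status == K.STATUS_INV_FIXED:
                return "fixed"
            if status == K.STATUS_EXTINCT:
                raise ExtinctionError(
                    f"all fitnesses zero at generation {self.generation + 1}"
                )
            if status == K.STATUS_GROW_HAP:
                self._grow_hap()
            elif status == K.STATUS_GROW_MUT:
                self._grow_mut()
            elif status == K.STATUS_SUBLOG_FULL:
                self._drain_sub_log()
        return "ok"

    def introduce_inversion(self, hap_index: int, span: tuple[int, int]) -> None:
        """Flag one haplotype copy as inverted and start tracking its fate.

        ``span`` is in local chromosome-1 coordinates; the layout in
        ``params`` must already carry it (see experiment orchestration).
        """
        arr = self.arrangement
        if arr.any():
            raise ValueError("an inversion is already present")
        arr[hap_index] = 1
        lo = self.params.layout.global_position(0, span[0])
        hi = self.params.layout.global_position(0, span[1])
        self._span = (lo, hi)
        self.state[K.ST_INV] = 1

    def reseed(self, seed: int) -> None:
        """Reseed the kernel RNG (e.g. per replicate from a shared burn-in)."""
        self.seed = int(seed)
        K.seed_rng(self.seed % (2**32))

    def copy(self) -> "Engine":
        """Deep copy of the simulation state (shares nothing mutable)."""
        new = Engine.__new__(Engine)
        new.params = self.params
        new.seed = self.seed
        new._cap = self._cap
        new._mcap = self._mcap
        new._hap = [a.copy() for a in self._hap]
        new._hn = [a.copy() for a in self._hn]
        new._arr = [a.copy() for a in self._arr]
        for name in ("m_gpos", "m_s", "m_origin", "m_uid", "m_count", "m_inuse", "m_remove"):
            setattr(new, name, getattr(self, name).copy())
        new._free = self._free.copy()
        new.state = self.state.copy()
        new._sub_log = self._sub_log.copy()
        new._sub_n = self._sub_n.copy()
        new._sub_frames = [df.copy() for df in self._sub_frames]
        new.chrom_bounds = self.chrom_bounds
        new.coding_lo = self.coding_lo
        new.coding_cum = self.coding_cum
        new._span = self._span
        new._W = self._W.copy()
        new._Wc = self._Wc.copy()
        new._co_buf = self._co_buf.copy()
        new._gc_lo = self._gc_lo.copy()
        new._gc_hi = self._gc_hi.copy()
        return new

    def clear_inversion(self) -> None:
        """Stop tracking a lost inversion so a new one can be introduced."""
        if self.inversion_count() != 0:
            raise ValueError("inversion still segregating; cannot clear")
        self.state[K.ST_INV] = 0
        self._span = (-1, -1)

    # -- inspection ----------------------------------------------------------

    def fitnesses(self) -> np.ndarray:
        """Current per-individual fitness (recomputed, not cached)."""
        out = np.zeros(self.params.N, dtype=np.float64)
        K.fitness_into(
            self.hap, self.hap_n, self.arrangement,
            self.m_gpos, self.m_uid, self.m_s, self.params.s_het, out,
        )
        return out

    def haplotype_slots(self, h: int) -> np.ndarray:
        return self.hap[h, : self.hap_n[h]]

    def haplotype_loads(self) -> np.ndarray:
        """1 - homozygote fitness for every haplotype copy."""
        out = np.empty(self.n_hap, dtype=np.float64)
        for h in range(self.n_hap):
            out[h] = 1.0 - K.homozygote_fitness(self.hap[h], int(self.hap_n[h]), self.m_s)
        return out

    def virtual_homozygote_fitness(
        self, arrangement: int, n_pairs: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Fitness of random same-arrangement haplotype pairings (no s_het).

        Used to probe homokaryotype viability when real homokaryotypes are
        rare or absent.
        """
        idx = np.flatnonzero(self.arrangement == arrangement)
        if idx.size < 2:
            return np.empty(0)
        out = np.empty(n_pairs, dtype=np.float64)
        for k in range(n_pairs):
            a, b = rng.choice(idx, size=2, replace=False)
            out[k] = K.shared_fitness(
                self.hap[a], int(self.hap_n[a]), self.hap[b], int(self.hap_n[b]),
                self.m_gpos, self.m_uid, self.m_s,
            )
        return out

    def allele_counts(self, hap_subset: Optional[np.ndarray] = None) -> np.ndarray:
        """Derived-allele counts per mutation slot, over all or some haplotypes."""
        mnext = int(self.state[K.ST_MNEXT])
        rows = range(self.n_hap) if hap_subset is None else hap_subset
        ids = [self.hap[h, : self.hap_n[h]] for h in rows]
        if not ids:
            return np.zeros(mnext, dtype=np.int64)
        return np.bincount(np.concatenate(ids), minlength=mnext)[:mnext]

    def active_slots(self) -> np.ndarray:
        mnext = int(self.state[K.ST_MNEXT])
        return np.flatnonzero(self.m_inuse[:mnext] == 1)

    def site_table(self) -> pd.DataFrame:
        """Metadata for all segregating mutations (one row per slot)."""
        layout = self.params.layout
        slots = self.active_slots()
        gpos = self.m_gpos[slots]
        offsets = layout.chrom_offsets
        chrom = np.searchsorted(offsets, gpos, side="right") - 1
        pos = gpos - offsets[chrom]
        region = np.array(
            [layout.region_class(int(c), int(p)) for c, p in zip(chrom, pos)], dtype=object
        )
        return pd.DataFrame(
            {
                "slot": slots,
                "uid": self.m_uid[slots],
                "chrom": chrom,
                "pos": pos,
                "gpos": gpos,
                "s": self.m_s[slots],
                "origin_gen": self.m_origin[slots],
                "region_class": region,
            }
        )

    def substitutions(self) -> pd.DataFrame:
        """Whole-population fixations pruned so far (soft selection)."""
        self._drain_sub_log()
        if not self._sub_frames:
            return pd.DataFrame(columns=_SUB_COLUMNS)
        df = pd.concat(self._sub_frames, ignore_index=True)
        for col in ("uid", "gpos", "origin_gen", "fixation_gen"):
            df[col] = df[col].astype(np.int64)
        layout = self.params.layout
        offsets = layout.chrom_offsets
        chrom = np.searchsorted(offsets, df["gpos"].to_numpy(), side="right") - 1
        pos = df["gpos"].to_numpy() - offsets[chrom]
        df["chrom"] = chrom
        df["pos"] = pos
        df["region_class"] = [
            layout.region_class(int(c), int(p)) for c, p in zip(chrom, pos)
        ]
        return df

    def to_population(self) -> Population:
        """Materialize the object model (for small populations / round trips)."""
        layout = self.params.layout
        slots = self.active_slots()
        muts: dict[int, Mutation] = {}
        for sl in slots:
            chrom, pos = layout.local_position(int(self.m_gpos[sl]))
            muts[int(sl)] = Mutation(
                id=int(self.m_uid[sl]),
                chrom=chrom,
                pos=pos,
                s=float(self.m_s[sl]),
                origin_gen=int(self.m_origin[sl]),
            )
        individuals = []
        for i in range(self.params.N):
            haps = []
            for h in (2 * i, 2 * i + 1):
                row = self.haplotype_slots(h)
                haps.append(
                    Haplotype(
                        (muts[int(sl)] for sl in row),
                        arrangement="I" if self.arrangement[h] else "S",
                    )
                )
            individuals.append(Individual(hap_a=haps[0], hap_b=haps[1]))
        pop = Population(individuals=individuals, generation=self.generation)
        subs = self.substitutions()
        for _, r in subs.iterrows():
            pop.substitutions.append(
                SubstitutionRecord(
                    mutation=Mutation(
                        id=int(r["uid"]), chrom=int(r["chrom"]), pos=int(r["pos"]),
                        s=float(r["s"]), origin_gen=int(r["origin_gen"]),
                    ),
                    fixation_gen=int(r["fixation_gen"]),
                    region_class=str(r["region_class"]),
                )
            )
        return pop
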