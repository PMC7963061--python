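"""Experiment orchestration: burn-in, inversion introduction, recording, sweeps.

A run proceeds as: (1) burn the population in to mutation-selection-drift
equilibrium without an inversion; (2) pick a founder haplotype (random, best,
worst, or median mutational load); (3) flag that single copy as the inverted
arrangement; (4) iterate Wright-Fisher generations, recording a summary row
every ``record_interval`` generations, until the inversion is lost, fixes, or
the horizon is reached. Parameter sweeps (gene-conversion grid, s_het grid,
inversion size, population size) drive many such runs with sub-seeds derived
from one master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel as K
from .engine import Engine
from .params import (
    ConfigurationError,
    SimulationParameters,
    default_inversion_span,
)
from .population import Haplotype, Population, haplotype_load
from .summaries import SITE_COLUMNS, ArrangementSnapshot

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "run_burn_in",
    "rank_and_select_founders",
    "introduce_inversion",
    "run_inversion_experiment",
    "run_conditioned_replicate",
    "run_low_recombination_variant",
    "sweep",
    "engine_snapshot",
    "derive_subseed",
]

DESIGN_FLAGS = {
    "suppression_mode": "breakpoint-deletion",
    "fst_estimator": "hudson",
    "layout_convention": "coding-segment-at-origin, leftover non-coding at chromosome end",
    "gc_tract_direction": "rightward",
    "inversion_placement": "centered on chromosome 1",
    "mating": "random union with replacement, selfing allowed",
}


@dataclass
class ExperimentConfig:
    """One experiment family: base parameters plus sweep axes."""

    params: SimulationParameters
    founder_mode: str = "random"  # random | best | worst | median
    replicates: int = 1
    gc_grid: Optional[Sequence[float]] = None
    s_het_grid: Optional[Sequence[float]] = None
    inversion_fraction_of_genome: float = 0.10
    co_multiplier: float = 1.0  # crossover-rate multiplier for the no-inversion variant
    snapshot_size: int = 100  # haplotypes sampled per arrangement
    virtual_pairs: int = 50  # same-arrangement pairings per fitness probe

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not 0.0 <= self.co_multiplier <= 1.0:
            raise ConfigurationError("co_multiplier must be in [0, 1]")
        for grid_name in ("gc_grid", "s_het_grid"):
            grid = getattr(self, grid_name)
            if grid is not None and len(grid) == 0:
                raise ConfigurationError(f"{grid_name} must be non-empty when given")

    def inversion_span(self) -> tuple[int, int]:
        layout = self.params.layout
        chrom_fraction = (
            self.inversion_fraction_of_genome * layout.total_bp / layout.chromosomes[0]
        )
        return default_inversion_span(layout, chrom_fraction)

    def params_with_span(self) -> SimulationParameters:
        return replace(
            self.params, layout=self.params.layout.with_inversion(self.inversion_span())
        )


@dataclass
class RunResult:
    """Recorded time series and terminal state of one replicate."""

    series: pd.DataFrame
    fate: str  # 'lost' | 'fixed' | 'polymorphic'
    fate_gen: Optional[int]  # generations since introduction, for absorptions
    intro_gen: int
    snapshots: list[ArrangementSnapshot] = field(default_factory=list)
    substitutions: pd.DataFrame = field(default_factory=pd.DataFrame)
    arrangement_fixed: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)


def derive_subseed(master_seed: int, *key: int) -> int:
    """Reproducible sub-seed for one grid point / replicate (< 2**31)."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# burn-in and founders
# ---------------------------------------------------------------------------

def run_burn_in(
    params: SimulationParameters, seed: int, n_checkpoints: int = 4
) -> tuple[Engine, dict]:
    """Evolve to mutation-selection-drift equilibrium without an inversion.

    Returns the engine plus a stationarity diagnostic: the mean haplotype
    load at each burn-in quarter, and the difference between the last two
    quarters.
    """
    eng = Engine(params, seed=seed)
    loads = []
    chunk = max(1, params.burn_in_gens // n_checkpoints)
    done = 0
    while done < params.burn_in_gens:
        step = min(chunk, params.burn_in_gens - done)
        eng.run(step)
        done += step
        loads.append(float(eng.haplotype_loads().mean()))
    diag = {
        "mean_load_per_quarter": loads,
        "late_drift": abs(loads[-1] - loads[-2]) if len(loads) >= 2 else 0.0,
    }
    return eng, diag


def rank_and_select_founders(
    loads: np.ndarray, mode: str, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Select founder haplotype indices by mutational-load ranking.

    ``loads`` holds one load per haplotype copy (index h belongs to
    individual h // 2). ``best``/``worst`` take the k lowest/highest loads;
    ``median`` the single haplotype closest to the median load; ``random``
    takes both haplotypes from ceil(k/2) distinct random individuals.
    """
    loads = np.asarray(loads, dtype=float)
    n_hap = loads.size
    if k > n_hap:
        raise ValueError(f"cannot select {k} founders from {n_hap} haplotypes")
    if mode == "best":
        return np.argsort(loads, kind="stable")[:k]
    if mode == "worst":
        return np.argsort(loads, kind="stable")[::-1][:k]
    if mode == "median":
        med = np.median(loads)
        return np.array([int(np.argmin(np.abs(loads - med)))])
    if mode == "random":
        n_ind = (k + 1) // 2
        inds = rng.choice(n_hap // 2, size=n_ind, replace=False)
        haps = np.concatenate([[2 * i, 2 * i + 1] for i in inds])
        return haps[:k]
    raise ValueError(f"unknown founder mode {mode!r}")


def introduce_inversion(
    pop: Population, founder: Haplotype, span: tuple[int, int]
) -> Population:
    """Flag one haplotype copy of ``pop`` as the inverted arrangement.

    Object-model counterpart of :meth:`Engine.introduce_inversion`; the
    founder haplotype becomes arrangement I at frequency 1/(2N).
    """
    if pop.inversion_present:
        raise ValueError("an inversion is already present")
    for ind in pop.individuals:
        for attr in ("hap_a", "hap_b"):
            if getattr(ind, attr) is founder:
                setattr(ind, attr, founder.with_arrangement("I"))
                return pop
    raise ValueError("founder haplotype not found in the population")


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

def engine_snapshot(
    eng: Engine,
    n_per_arrangement: int,
    rng: np.random.Generator,
    span_only: bool = True,
    chrom: Optional[int] = None,
) -> ArrangementSnapshot:
    """Sample haplotypes per arrangement into a binary site matrix.

    ``span_only`` restricts columns to the inversion span; ``chrom``
    restricts to one chromosome instead (used by the no-inversion variant).
    """
    layout = eng.params.layout
    arr = eng.arrangement
    rows: list[int] = []
    for a in (1, 0):
        idx = np.flatnonzero(arr == a)
        if idx.size == 0:
            continue
        take = min(n_per_arrangement, idx.size)
        rows.extend(rng.choice(idx, size=take, replace=False).tolist())
    slot_lists = [eng.haplotype_slots(h) for h in rows]
    all_slots = (
        np.unique(np.concatenate(slot_lists)) if slot_lists else np.empty(0, dtype=np.int32)
    )
    if all_slots.size:
        gpos = eng.m_gpos[all_slots]
        if span_only and layout.inversion_span_global is not None:
            lo, hi = layout.inversion_span_global
            keep = (gpos >= lo) & (gpos < hi)
        elif chrom is not None:
            off = layout.chrom_offsets
            keep = (gpos >= off[chrom]) & (gpos < off[chrom + 1])
        else:
            keep = np.ones(all_slots.size, dtype=bool)
        all_slots = all_slots[keep]
        order = np.lexsort((eng.m_uid[all_slots], eng.m_gpos[all_slots]))
        all_slots = all_slots[order]
    col = {int(sl): j for j, sl in enumerate(all_slots)}
    matrix = np.zeros((len(rows), all_slots.size), dtype=np.uint8)
    for i, slots in enumerate(slot_lists):
        for sl in slots:
            j = col.get(int(sl))
            if j is not None:
                matrix[i, j] = 1
    offsets = layout.chrom_offsets
    chroms = np.searchsorted(offsets, eng.m_gpos[all_slots], side="right") - 1
    poss = eng.m_gpos[all_slots] - offsets[chroms]
    sites = pd.DataFrame(
        {
            "uid": eng.m_uid[all_slots],
            "chrom": chroms,
            "pos": poss,
            "s": eng.m_s[all_slots],
            "origin_gen": eng.m_origin[all_slots],
            "region_class": [
                layout.region_class(int(c), int(p)) for c, p in zip(chroms, poss)
            ],
        }
    )
    return ArrangementSnapshot(
        matrix=matrix,
        arrangements=np.array(["I" if arr[h] else "S" for h in rows], dtype=object),
        sites=sites,
        generation=eng.generation,
    )


def _record_row(eng: Engine, intro_gen: int, rng: np.random.Generator, cfg: ExperimentConfig) -> dict:
    layout = eng.params.layout
    arr = eng.arrangement
    W = eng.fitnesses()
    mean_w = W.mean()
    rel = W / mean_w if mean_w > 0 else W
    kary = arr[0::2] + arr[1::2]  # 0=SS, 1=IS, 2=II
    row = {
        "gen": eng.generation,
        "gen_since_intro": eng.generation - intro_gen,
        "inv_count": int(arr.sum()),
        "p_inv": float(arr.mean()),
        "mean_fitness": float(mean_w),
    }
    for kval, name in ((0, "SS"), (1, "IS"), (2, "II")):
        m = kary == kval
        row[f"n_{name}"] = int(m.sum())
        row[f"w_{name}"] = float(rel[m].mean()) if m.any() else np.nan
    for a, nm in ((1, "I"), (0, "S")):
        v = eng.virtual_homozygote_fitness(a, cfg.virtual_pairs, rng)
        row[f"virt_w_{nm}"] = float((v / mean_w).mean()) if v.size and mean_w > 0 else np.nan

    mnext = int(eng.state[K.ST_MNEXT])
    active = eng.m_inuse[:mnext] == 1
    gpos = eng.m_gpos[:mnext]
    span_g = layout.inversion_span_global
    if span_g is not None:
        in_span = (gpos >= span_g[0]) & (gpos < span_g[1]) & active
        idx_i = np.flatnonzero(arr == 1)
        idx_s = np.flatnonzero(arr == 0)
        c_i = eng.allele_counts(idx_i) if idx_i.size else np.zeros(mnext, dtype=np.int64)
        c_s = eng.allele_counts(idx_s) if idx_s.size else np.zeros(mnext, dtype=np.int64)
        post = eng.m_origin[:mnext] > intro_gen
        row["fixed_in_I_span"] = int(((c_i == idx_i.size) & in_span).sum()) if idx_i.size else 0
        row["fixed_in_S_span"] = int(((c_s == idx_s.size) & in_span).sum()) if idx_s.size else 0
        row["span_shared_postintro"] = int(((c_i > 0) & (c_s > 0) & in_span & post).sum())
        row["span_muts_per_hap_I"] = (
            float(c_i[in_span].sum() / idx_i.size) if idx_i.size else np.nan
        )
        row["span_muts_per_hap_S"] = (
            float(c_s[in_span].sum() / idx_s.size) if idx_s.size else np.nan
        )
    row["seg_sites"] = int(active.sum())
    row["mean_load"] = float(eng.haplotype_loads().mean())
    return row


def _arrangement_fixed_table(eng: Engine, intro_gen: int) -> pd.DataFrame:
    """Final-state table of mutations fixed within either arrangement."""
    layout = eng.params.layout
    arr = eng.arrangement
    mnext = int(eng.state[K.ST_MNEXT])
    active = eng.m_inuse[:mnext] == 1
    frames = []
    for a, nm in ((1, "I"), (0, "S")):
        idx = np.flatnonzero(arr == a)
        if idx.size == 0:
            continue
        counts = eng.allele_counts(idx)
        other = np.flatnonzero(arr != a)
        counts_other = (
            eng.allele_counts(other) if other.size else np.zeros(mnext, dtype=np.int64)
        )
        fixed = np.flatnonzero((counts == idx.size) & active)
        if fixed.size == 0:
            continue
        offsets = layout.chrom_offsets
        chroms = np.searchsorted(offsets, eng.m_gpos[fixed], side="right") - 1
        poss = eng.m_gpos[fixed] - offsets[chroms]
        frames.append(
            pd.DataFrame(
                {
                    "uid": eng.m_uid[fixed],
                    "chrom": chroms,
                    "pos": poss,
                    "s": eng.m_s[fixed],
                    "origin_gen": eng.m_origin[fixed],
                    "region_class": [
                        layout.region_class(int(c), int(p)) for c, p in zip(chroms, poss)
                    ],
                    "arrangement": nm,
                    "freq_other": counts_other[fixed] / max(other.size, 1),
                    "post_introduction": eng.m_origin[fixed] > intro_gen,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=SITE_COLUMNS + ["arrangement", "freq_other", "post_introduction"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# the main experiment
# ---------------------------------------------------------------------------

def run_inversion_experiment(
    config: ExperimentConfig,
    seed: int,
    engine: Optional[Engine] = None,
    founder_index: Optional[int] = None,
) -> RunResult:
    """One replicate: burn-in (unless an engine is supplied), introduce the
    inversion into the selected founder haplotype, follow it to loss,
    fixation, or the horizon.

    The recorded series has one row per ``record_interval`` generations plus
    a final row at absorption. A haplotype snapshot of the inversion span is
    taken at the final recorded generation.
    """
    params = config.params_with_span()
    rng = np.random.default_rng(derive_subseed(seed, 0xA11CE))
    if engine is None:
        engine, _ = run_burn_in(params, seed)
    else:
        engine.params = params  # same genome; span + grid values may differ
        engine.reseed(derive_subseed(seed, 0xE17))  # order-independent replicates
    span = params.layout.inversion_span
    if founder_index is None:
        loads = engine.haplotype_loads()
        founder_index = int(
            rank_and_select_founders(loads, config.founder_mode, 1, rng)[0]
        )
    engine.introduce_inversion(founder_index, span)
    intro_gen = engine.generation

    rows = [_record_row(engine, intro_gen, rng, config)]
    status = "ok"
    while status == "ok" and engine.generation - intro_gen < params.max_gens:
        step = min(
            params.record_interval, params.max_gens - (engine.generation - intro_gen)
        )
        status = engine.run(step)
        rows.append(_record_row(engine, intro_gen, rng, config))

    fate = {"ok": "polymorphic", "lost": "lost", "fixed": "fixed"}[status]
    fate_gen = engine.generation - intro_gen if fate != "polymorphic" else None
    snapshots = []
    if fate == "polymorphic":
        # full-genome snapshot: inverted, linked, and collinear sites alike
        snapshots.append(engine_snapshot(engine, config.snapshot_size, rng, span_only=False))
    result = RunResult(
        series=pd.DataFrame(rows),
        fate=fate,
        fate_gen=fate_gen,
        intro_gen=intro_gen,
        snapshots=snapshots,
        substitutions=engine.substitutions(),
        arrangement_fixed=_arrangement_fixed_table(engine, intro_gen),
        metadata={
            "seed": int(seed),
            "founder_index": int(founder_index),
            "founder_mode": config.founder_mode,
            "intro_gen": intro_gen,
            "params": _params_dict(params),
            "design_flags": dict(DESIGN_FLAGS),
            "code_version": _code_version(),
        },
    )
    if fate == "lost":
        engine.clear_inversion()
    return result


def run_conditioned_replicate(
    config: ExperimentConfig,
    seed: int,
    engine: Optional[Engine] = None,
    max_attempts: int = 300,
) -> RunResult:
    """Repeat inversion origination until one survives to the horizon.

    Mimics estimating fates conditional on invasion: after each loss the
    (inversion-free, still-equilibrated) population keeps evolving and a new
    random founder receives the inversion. Returns the first replicate whose
    fate is not 'lost'; the attempt count lands in the metadata.
    """
    params = config.params_with_span()
    if engine is None:
        engine, _ = run_burn_in(params, seed)
    for attempt in range(1, max_attempts + 1):
        result = run_inversion_experiment(
            config, derive_subseed(seed, 0xF0, attempt), engine=engine
        )
        if result.fate != "lost":
            result.metadata["attempts"] = attempt
            return result
    raise RuntimeError(f"inversion never established in {max_attempts} attempts")


def run_low_recombination_variant(
    config: ExperimentConfig, seed: int
) -> RunResult:
    """No-inversion control: same genome, crossover rate scaled down.

    The crossover initiation rate is multiplied by ``config.co_multiplier``
    (gene conversion keeps its configured rate) and no inversion is ever
    introduced; haplotype structuring is then probed on all of chromosome 1.
    The returned result carries a whole-chromosome snapshot and, in its
    metadata, a virtual-homozygote fitness sample of random haplotype pairs.
    """
    base = config.params
    params = replace(
        base,
        recomb=replace(
            base.recomb, crossover_rate=base.recomb.crossover_rate * config.co_multiplier
        ),
    )
    rng = np.random.default_rng(derive_subseed(seed, 0x10))
    engine, _ = run_burn_in(params, seed)
    intro_gen = engine.generation
    rows = [_record_row(engine, intro_gen, rng, config)]
    while engine.generation - intro_gen < params.max_gens:
        step = min(
            params.record_interval, params.max_gens - (engine.generation - intro_gen)
        )
        engine.run(step)
        rows.append(_record_row(engine, intro_gen, rng, config))
    snap = engine_snapshot(
        engine, config.snapshot_size, rng, span_only=False, chrom=0
    )
    W = engine.fitnesses()
    virt = engine.virtual_homozygote_fitness(0, 200, rng)
    return RunResult(
        series=pd.DataFrame(rows),
        fate="polymorphic",
        fate_gen=None,
        intro_gen=intro_gen,
        snapshots=[snap],
        substitutions=engine.substitutions(),
        arrangement_fixed=pd.DataFrame(),
        metadata={
            "seed": int(seed),
            "co_multiplier": config.co_multiplier,
            "virtual_homozygote_relative_fitness": (virt / W.mean()).tolist()
            if W.mean() > 0
            else [],
            "params": _params_dict(params),
            "design_flags": dict(DESIGN_FLAGS),
            "code_version": _code_version(),
        },
    )


def sweep(config: ExperimentConfig, master_seed: int) -> pd.DataFrame:
    """Grid of runs over gc_grid x s_het_grid x replicates.

    Each grid point / replicate gets a reproducible sub-seed derived from the
    master seed, so parallel and serial execution give identical per-run
    outputs. Returns one summary row per run.
    """
    gc_values = list(config.gc_grid) if config.gc_grid is not None else [
        config.params.recomb.gc_init_rate
    ]
    sh_values = list(config.s_het_grid) if config.s_het_grid is not None else [
        config.params.s_het
    ]
    rows = []
    for gi, gc in enumerate(gc_values):
        for si, sh in enumerate(sh_values):
            point = replace(
                config,
                params=replace(
                    config.params,
                    recomb=replace(config.params.recomb, gc_init_rate=gc),
                    s_het=sh,
                ),
            )
            for rep in range(config.replicates):
                sub = derive_subseed(master_seed, gi, si, rep)
                res = run_inversion_experiment(point, sub)
                last = res.series.iloc[-1]
                rows.append(
                    {
                        "gc_init_rate": gc,
                        "s_het": sh,
                        "replicate": rep,
                        "seed": sub,
                        "fate": res.fate,
                        "fate_gen": res.fate_gen,
                        "final_p_inv": float(last["p_inv"]),
                        "final_gen": int(last["gen_since_intro"]),
                    }
                )
    return pd.DataFrame(rows)


def _params_dict(params: SimulationParameters) -> dict:
    d = asdict(params)
    d["layout"]["inversion_span"] = params.layout.inversion_span
    return d


def _code_version() -> str:
    try:
        from importlib.metadata import version

        return version("invfate")
    except Exception:  # pragma: no cover - metadata missing in odd installs
        return "unknown"
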