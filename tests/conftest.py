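"""Shared fixtures.

The heavy session fixtures build the desk-scale simulation cohorts used by
the model-level tests: a shared burn-in population, gene-conversion-free
replicates paired with default-gene-conversion replicates (N = 500), and a
small-population cohort (N = 100) where mutation accumulation is expected to
degrade both arrangements. Problem sizes are chosen so the whole suite runs
on a workstation; see docs/methods.md for the scaling rationale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from invfate.config import profile_config
from invfate.experiment import (
    ExperimentConfig,
    derive_subseed,
    run_burn_in,
    run_conditioned_replicate,
)

COHORT_SEED = 20260920  # master seed for all desk cohorts
DESK_HORIZON = 5_000
N_PAIRS = 5
SMALL_N_REPS = 10
SMALL_N_HORIZON = 10_000


def _no_gc(cfg: ExperimentConfig) -> ExperimentConfig:
    return replace(
        cfg, params=replace(cfg.params, recomb=replace(cfg.params.recomb, gc_init_rate=0.0))
    )


def polymorphic_replicate(cfg, burnin_engine, seed, max_rounds=6):
    """A replicate conditioned on still segregating at the horizon."""
    for round_ in range(max_rounds):
        res = run_conditioned_replicate(
            cfg, derive_subseed(seed, round_), engine=burnin_engine.copy()
        )
        if res.fate == "polymorphic":
            return res
    raise RuntimeError(f"no polymorphic replicate in {max_rounds} rounds (seed {seed})")


@pytest.fixture(scope="session")
def desk_config() -> ExperimentConfig:
    cfg = profile_config("desk")
    return replace(cfg, params=replace(cfg.params, max_gens=DESK_HORIZON))


@pytest.fixture(scope="session")
def desk_burnin(desk_config):
    """One equilibrated gene-conversion-free population, shared by all pairs."""
    cfg = _no_gc(desk_config)
    engine, diag = run_burn_in(cfg.params_with_span(), seed=COHORT_SEED)
    return engine, diag


@pytest.fixture(scope="session")
def desk_cohort(desk_config, desk_burnin):
    """Paired desk-scale replicates: gamma = 0 vs the default GC rate.

    Both arms of each pair start from the same burn-in state and replicate
    seed; only the gene-conversion initiation rate differs.
    """
    engine, _ = desk_burnin
    cfg0 = _no_gc(desk_config)
    runs_nogc, runs_gc = [], []
    for rep in range(N_PAIRS):
        seed = derive_subseed(COHORT_SEED, 7, rep)
        runs_nogc.append(polymorphic_replicate(cfg0, engine, seed))
        runs_gc.append(polymorphic_replicate(desk_config, engine, seed))
    return runs_nogc, runs_gc


@pytest.fixture(scope="session")
def small_n_cohort():
    """Ten polymorphic N = 100, gamma = 0 replicates run to a long horizon."""
    cfg = profile_config("desk-small-n")
    cfg = _no_gc(replace(cfg, params=replace(cfg.params, max_gens=SMALL_N_HORIZON)))
    runs = []
    for rep in range(SMALL_N_REPS):
        seed = derive_subseed(COHORT_SEED, 11, rep)
        engine, _ = run_burn_in(cfg.params_with_span(), seed=seed)
        runs.append(polymorphic_replicate(cfg, engine, seed))
    return runs


@pytest.fixture(scope="session")
def single_locus_control():
    """The 2,000-replicate overdominant single-locus benchmark."""
    from invfate.single_locus import simulate_overdominant_locus

    return simulate_overdominant_locus(
        N=2500, s_het=0.03, reps=2000, horizon=10_000, rng=1
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
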