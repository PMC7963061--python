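"""Orchestration: burn-in, founders, introduction, stopping, sweeps."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from invfate.engine import Engine
from invfate.experiment import (
    ExperimentConfig,
    derive_subseed,
    engine_snapshot,
    introduce_inversion,
    rank_and_select_founders,
    run_burn_in,
    run_inversion_experiment,
    run_low_recombination_variant,
    sweep,
)
from invfate.params import SimulationParameters, rescale
from invfate.population import Haplotype, Individual, Mutation, Population


def tiny_config(n=40, burn=150, horizon=400, record=50, gc=None, **cfg_kwargs):
    params = replace(
        rescale(SimulationParameters(), 100.0),
        N=n, burn_in_gens=burn, max_gens=horizon, record_interval=record,
    )
    if gc is not None:
        params = replace(params, recomb=replace(params.recomb, gc_init_rate=gc))
    return ExperimentConfig(params=params, **cfg_kwargs)


class TestBurnIn:
    def test_generation_counter_and_diagnostic(self):
        cfg = tiny_config(burn=200)
        eng, diag = run_burn_in(cfg.params, seed=1)
        assert eng.generation == 200
        assert len(diag["mean_load_per_quarter"]) == 4
        assert diag["late_drift"] >= 0.0

    def test_burn_in_approaches_stationarity(self):
        """Mean load in the last two quarters of a long-enough burn-in
        should differ by much less than the load itself."""
        cfg = tiny_config(n=100, burn=1_200)
        _, diag = run_burn_in(cfg.params, seed=2)
        q = diag["mean_load_per_quarter"]
        assert abs(q[-1] - q[-2]) < 0.5 * max(q[-1], 1e-3) + 0.05


class TestFounderSelection:
    loads = np.array([0.5, 0.1, 0.9, 0.3, 0.7, 0.2])

    def test_best_k(self, rng):
        assert rank_and_select_founders(self.loads, "best", 2, rng).tolist() == [1, 5]

    def test_worst_k(self, rng):
        assert rank_and_select_founders(self.loads, "worst", 2, rng).tolist() == [2, 4]

    def test_median_returns_single_closest(self, rng):
        idx = rank_and_select_founders(self.loads, "median", 1, rng)
        assert idx.size == 1
        med = np.median(self.loads)
        assert abs(self.loads[idx[0]] - med) == np.abs(self.loads - med).min()

    def test_random_mode_takes_both_haplotypes_of_distinct_individuals(self, rng):
        loads = np.zeros(200)
        idx = rank_and_select_founders(loads, "random", 200, rng)
        assert idx.size == 200
        individuals = idx // 2
        assert len(np.unique(individuals)) == 100
        counts = np.bincount(individuals, minlength=100)
        assert (counts[np.unique(individuals)] == 2).all()

    def test_k_exceeding_population_is_an_error(self, rng):
        with pytest.raises(ValueError):
            rank_and_select_founders(self.loads, "best", 7, rng)


class TestIntroduceInversion:
    def test_single_copy_flagged(self):
        pop = Population([Individual(Haplotype(), Haplotype()) for _ in range(5)])
        founder = pop.individuals[2].hap_b
        out = introduce_inversion(pop, founder, (350, 650))
        assert out.inversion_count() == 1
        assert out.individuals[2].hap_b.arrangement == "I"

    def test_double_introduction_is_an_error(self):
        pop = Population([Individual(Haplotype((), "I"), Haplotype())])
        with pytest.raises(ValueError):
            introduce_inversion(pop, pop.individuals[0].hap_b, (0, 1))

    def test_unknown_founder_is_an_error(self):
        pop = Population([Individual(Haplotype(), Haplotype())])
        with pytest.raises(ValueError):
            introduce_inversion(pop, Haplotype(), (0, 1))

    def test_default_span_fraction(self):
        cfg = tiny_config()
        lo, hi = cfg.inversion_span()
        layout = cfg.params.layout
        assert (hi - lo) / layout.total_bp == pytest.approx(0.10, abs=1e-3)

    def test_engine_introduction_frequency(self):
        cfg = tiny_config()
        eng, _ = run_burn_in(cfg.params_with_span(), seed=3)
        eng.introduce_inversion(7, cfg.inversion_span())
        assert eng.inversion_count() == 1


class TestRunExperiment:
    def test_series_recorded_and_fate_consistent(self):
        res = run_inversion_experiment(tiny_config(), seed=11)
        last = res.series.iloc[-1]
        if res.fate == "lost":
            assert last["inv_count"] == 0
            assert res.fate_gen == last["gen_since_intro"]
        elif res.fate == "fixed":
            assert last["inv_count"] == 2 * 40
        else:
            assert 0 < last["inv_count"] < 2 * 40
        # stopping correctness: nothing recorded past the fate generation
        if res.fate_gen is not None:
            assert (res.series["gen_since_intro"] <= res.fate_gen).all()
        assert res.series["gen"].is_monotonic_increasing

    def test_identical_seed_and_config_reproduce_bitwise(self):
        a = run_inversion_experiment(tiny_config(), seed=13)
        b = run_inversion_experiment(tiny_config(), seed=13)
        assert a.fate == b.fate
        pd.testing.assert_frame_equal(a.series, b.series)
        pd.testing.assert_frame_equal(a.substitutions, b.substitutions)

    def test_metadata_records_design_flags_and_founder(self):
        res = run_inversion_experiment(tiny_config(), seed=17)
        assert res.metadata["design_flags"]["suppression_mode"] == "breakpoint-deletion"
        assert "founder_index" in res.metadata
        assert res.metadata["params"]["N"] == 40


class TestSweep:
    def test_grid_times_replicates_rows_with_distinct_subseeds(self):
        cfg = tiny_config(n=20, burn=60, horizon=100, record=50,
                          gc_grid=[0.0, 1e-4], replicates=2)
        table = sweep(cfg, master_seed=5)
        assert len(table) == 4
        assert table["seed"].nunique() == 4
        # reproducible: the same master seed regenerates the same table
        pd.testing.assert_frame_equal(table, sweep(cfg, master_seed=5))

    def test_subseed_derivation_is_stable_and_bounded(self):
        s1 = derive_subseed(42, 1, 2, 3)
        assert s1 == derive_subseed(42, 1, 2, 3)
        assert s1 != derive_subseed(42, 1, 2, 4)
        assert 0 <= s1 < 2**31


class TestLowRecombinationVariant:
    def test_zero_multiplier_removes_crossovers(self):
        cfg = tiny_config(n=80, burn=60, horizon=100, co_multiplier=0.0)
        res = run_low_recombination_variant(cfg, seed=23)
        assert res.metadata["params"]["recomb"]["crossover_rate"] == 0.0
        assert res.metadata["co_multiplier"] == 0.0
        assert res.snapshots and res.snapshots[0].n_haplotypes > 0
        assert len(res.metadata["virtual_homozygote_relative_fitness"]) > 0

    def test_control_keeps_configured_crossover_rate(self):
        cfg = tiny_config(n=30, burn=50, horizon=100, co_multiplier=1.0)
        res = run_low_recombination_variant(cfg, seed=29)
        assert res.metadata["params"]["recomb"]["crossover_rate"] == pytest.approx(
            cfg.params.recomb.crossover_rate
        )

    def test_structuring_arises_without_inversion_when_crossing_over_is_off(self):
        """A plain chromosome with no crossing-over and no gene conversion
        develops complementary haplotype clusters (associative
        overdominance), while the normal-recombination control does not."""
        from invfate.config import profile_config
        from invfate.experiment import derive_subseed
        from invfate.outcomes import detect_haplotype_structuring
        from dataclasses import replace as rep

        base = profile_config("desk")
        base = rep(base, params=rep(base.params, N=200, burn_in_gens=1_000,
                                    max_gens=3_000,
                                    recomb=rep(base.params.recomb, gc_init_rate=0.0)),
                   snapshot_size=60)
        detected = {}
        for co_mult, n_reps in ((0.0, 2), (1.0, 2)):
            cfg = rep(base, co_multiplier=co_mult)
            hits = 0
            for r in range(n_reps):
                res = run_low_recombination_variant(cfg, derive_subseed(5, r))
                virt = np.asarray(res.metadata["virtual_homozygote_relative_fitness"])
                report = detect_haplotype_structuring(res.snapshots[0].matrix, virt)
                hits += report.detected
            detected[co_mult] = hits
        assert detected[0.0] >= 1  # structuring without an inversion
        assert detected[1.0] == 0  # essentially never under normal crossing-over


class TestFounderFitnessAtIntroduction:
    def test_few_homozygotes_match_mean_standard_fitness(self, desk_burnin):
        """At mutation-selection balance almost every haplotype carries
        enough recessive load that its homozygote would be less fit than the
        average standard individual, so only a minority of possible II
        homokaryotypes start out competitive."""
        engine, _ = desk_burnin
        homozygote_w = 1.0 - engine.haplotype_loads()
        mean_w = engine.fitnesses().mean()
        assert (homozygote_w >= mean_w).mean() < 0.5


class TestSnapshotFromEngine:
    def test_snapshot_shapes_and_labels(self):
        cfg = tiny_config()
        eng, _ = run_burn_in(cfg.params_with_span(), seed=31)
        eng.introduce_inversion(0, cfg.inversion_span())
        eng.run(100)
        if 0 < eng.inversion_count() < eng.n_hap:
            snap = engine_snapshot(eng, 10, np.random.default_rng(0), span_only=False)
            assert snap.n_haplotypes <= 10 + eng.n_hap
            assert set(snap.arrangements) <= {"I", "S"}
            assert set(snap.sites["region_class"]) <= {"inverted", "linked", "collinear"}
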