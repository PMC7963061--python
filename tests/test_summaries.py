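"""Arrangement-divergence statistics on constructed haplotype fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invfate.params import DFEParams, build_genome_layout, sample_selection_coefficient
from invfate.population import Haplotype, Individual, Mutation, Population
from invfate.summaries import (
    ArrangementSnapshot,
    build_snapshot,
    cumulative_fixation_curves,
    fixed_difference_count,
    haplotype_matrix,
    neutral_fraction_of_fixed,
    per_site_fst,
)


def make_snapshot(matrix, arrangements, s=None, region=None):
    matrix = np.asarray(matrix, dtype=np.uint8)
    n_sites = matrix.shape[1]
    sites = pd.DataFrame(
        {
            "uid": np.arange(n_sites),
            "chrom": np.zeros(n_sites, dtype=int),
            "pos": np.arange(n_sites) * 10,
            "s": s if s is not None else np.full(n_sites, -0.01),
            "origin_gen": np.zeros(n_sites, dtype=int),
            "region_class": region if region is not None else ["inverted"] * n_sites,
        }
    )
    return ArrangementSnapshot(matrix=matrix, arrangements=np.array(arrangements, dtype=object), sites=sites)


class TestFixedDifferences:
    def _fixture(self):
        # 4 I + 4 S haplotypes; sites 0-2 fixed in I only, site 3 fixed in S only,
        # site 4 shared polymorphism, site 5 private polymorphism
        matrix = np.zeros((8, 6), dtype=np.uint8)
        matrix[:4, 0:3] = 1
        matrix[4:, 3] = 1
        matrix[[0, 4], 4] = 1
        matrix[1, 5] = 1
        return make_snapshot(matrix, ["I"] * 4 + ["S"] * 4)

    def test_hand_enumerated_count(self):
        out = fixed_difference_count(self._fixture(), span_bp=2000)
        assert out["count"] == 4
        assert out["per_kb"] == pytest.approx(2.0)

    def test_identical_arrangements_give_zero(self):
        matrix = np.tile([1, 0, 1], (6, 1))
        snap = make_snapshot(matrix, ["I"] * 3 + ["S"] * 3)
        assert fixed_difference_count(snap)["count"] == 0

    def test_symmetric_under_label_swap(self):
        snap = self._fixture()
        swapped = make_snapshot(
            snap.matrix, ["S" if a == "I" else "I" for a in snap.arrangements]
        )
        assert fixed_difference_count(snap)["count"] == fixed_difference_count(swapped)["count"]

    def test_one_arrangement_absent_is_an_error(self):
        snap = make_snapshot(np.ones((4, 2)), ["I"] * 4)
        with pytest.raises(ValueError):
            fixed_difference_count(snap)


class TestPerSiteFst:
    def test_fixed_difference_has_fst_one(self):
        matrix = np.array([[1], [1], [0], [0]])
        snap = make_snapshot(matrix, ["I", "I", "S", "S"])
        assert per_site_fst(snap)["fst"].tolist() == [1.0]

    def test_equal_frequencies_have_fst_zero(self):
        matrix = np.array([[1], [0], [1], [0]])
        snap = make_snapshot(matrix, ["I", "I", "S", "S"])
        assert per_site_fst(snap)["fst"].tolist() == [0.0]

    def test_against_textbook_oracle_100_haplotypes(self):
        """p_I = 0.5, p_S = 0: compare with an independently coded
        Hudson-style estimate from first principles."""
        matrix = np.zeros((200, 1), dtype=np.uint8)
        matrix[:50, 0] = 1  # 50 of 100 I haplotypes carry the allele
        snap = make_snapshot(matrix, ["I"] * 100 + ["S"] * 100)
        p1, p2 = 0.5, 0.0
        h_w = ((2 * p1 * (1 - p1)) + (2 * p2 * (1 - p2))) / 2
        h_b = p1 * (1 - p2) + p2 * (1 - p1)
        oracle = 1 - h_w / h_b
        assert per_site_fst(snap)["fst"].iloc[0] == pytest.approx(oracle)

    def test_pooled_monomorphic_sites_skipped(self):
        matrix = np.ones((4, 2), dtype=np.uint8)
        matrix[:, 1] = [1, 0, 1, 0]
        snap = make_snapshot(matrix, ["I", "I", "S", "S"])
        out = per_site_fst(snap)
        assert out["uid"].tolist() == [1]

    def test_identical_samples_give_all_zero(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 2, size=(5, 12))
        snap = make_snapshot(np.vstack([block, block]), ["I"] * 5 + ["S"] * 5)
        assert (per_site_fst(snap)["fst"].to_numpy() == 0).all()

    def test_neutral_flag_uses_total_population_size(self):
        matrix = np.array([[1], [1], [0], [0]])
        snap = make_snapshot(matrix, ["I", "I", "S", "S"], s=np.array([-1e-5]))
        out = per_site_fst(snap, n_total=25_000)
        assert bool(out["effectively_neutral"].iloc[0]) is True

    def test_fixed_differences_equal_fst_one_monomorphic_sites(self):
        """Cross-check between two operations on one random snapshot."""
        rng = np.random.default_rng(7)
        matrix = rng.integers(0, 2, size=(30, 40), dtype=np.uint8)
        matrix[:15, :5] = 1
        matrix[15:, :5] = 0
        snap = make_snapshot(matrix, ["I"] * 15 + ["S"] * 15)
        fst = per_site_fst(snap)
        p_i = snap.matrix[:15].mean(axis=0)
        p_s = snap.matrix[15:].mean(axis=0)
        mono_fst1 = {
            int(u)
            for u, f in zip(fst["uid"], fst["fst"])
            if f == 1.0 and p_i[int(u)] in (0.0, 1.0) and p_s[int(u)] in (0.0, 1.0)
        }
        assert len(mono_fst1) == fixed_difference_count(snap)["count"]


class TestFixationCurves:
    def test_empty_log_gives_zero_curves(self):
        curves = cumulative_fixation_curves(
            pd.DataFrame({"origin_gen": [], "class": []}), {"inverted": 30.0}
        )
        assert curves["inverted"].empty

    def test_curves_non_decreasing_and_per_kb(self):
        log = pd.DataFrame(
            {"origin_gen": [5, 1, 3, 3, 9], "class": ["I", "I", "I", "S", "S"]}
        )
        curves = cumulative_fixation_curves(log, {"I": 2.0, "S": 2.0})
        ci = curves["I"]
        assert (np.diff(ci["cum_per_kb"]) >= 0).all()
        assert ci["cum_per_kb"].iloc[-1] == pytest.approx(3 / 2.0)
        assert list(ci["origin_gen"]) == [1, 3, 5]

    def test_whole_population_fixations_nested_in_both_arrangements(self, desk_cohort):
        """Any mutation fixed population-wide inside the span must, by
        definition, be fixed in both arrangements; the pruned substitution
        log of the span and the arrangement-fixation tables must therefore
        not contradict each other (no span substitution while the inversion
        segregates without gene conversion)."""
        runs_nogc, _ = desk_cohort
        for run in runs_nogc:
            subs = run.substitutions
            if len(subs) == 0:
                continue
            post = subs[subs["origin_gen"] > run.intro_gen]
            assert (post["region_class"] != "inverted").all()


class TestNeutralFraction:
    def test_hand_counted_fraction(self):
        s = np.array([-1e-5] * 3 + [-0.01] * 7)
        assert neutral_fraction_of_fixed(s, 25_000) == pytest.approx(0.3)

    def test_all_below_threshold(self):
        assert neutral_fraction_of_fixed(np.full(5, -1e-6), 25_000) == 1.0

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            neutral_fraction_of_fixed(np.array([]), 25_000)

    def test_raw_dfe_draw_fraction_is_about_five_percent(self, rng):
        s = sample_selection_coefficient(rng, DFEParams(), size=200_000)
        assert neutral_fraction_of_fixed(s, 25_000) == pytest.approx(0.0504, abs=0.004)


class TestHaplotypeMatrix:
    def _pop(self):
        layout = build_genome_layout().with_inversion((350_000, 650_000))
        inside = [Mutation(id=i, chrom=0, pos=400_000 + i, s=-0.01, origin_gen=0) for i in range(3)]
        outside = Mutation(id=99, chrom=1, pos=10, s=-0.01, origin_gen=0)
        h1 = Haplotype(inside[:2] + [outside], "I")
        h2 = Haplotype(inside[2:], "I")
        h3 = Haplotype([outside], "S")
        pop = Population([Individual(h1, h2), Individual(h3, Haplotype())])
        return pop, layout

    def test_single_row_matches_haplotype_vector(self, rng):
        pop, layout = self._pop()
        pop2 = Population([Individual(pop.individuals[0].hap_a, pop.individuals[0].hap_a)])
        snap = haplotype_matrix(pop2, layout, "I", 1, rng)
        assert snap.matrix.shape == (1, 2)
        assert snap.matrix.sum() == 2  # exactly the two within-span mutations

    def test_columns_are_within_span_sites_only(self, rng):
        pop, layout = self._pop()
        snap = haplotype_matrix(pop, layout, "I", 2, rng)
        assert (snap.sites["region_class"] == "inverted").all()
        assert snap.n_sites == 3

    def test_absent_arrangement_is_an_error(self, rng):
        pop, layout = self._pop()
        with pytest.raises(ValueError):
            haplotype_matrix(pop, layout, "I", 5, rng)

    def test_two_cluster_fixture_round_trip(self, rng):
        """A constructed two-block pattern survives snapshotting."""
        layout = build_genome_layout().with_inversion((350_000, 650_000))
        a_muts = [Mutation(id=i, chrom=0, pos=400_000 + i, s=-0.5, origin_gen=0) for i in range(5)]
        b_muts = [Mutation(id=100 + i, chrom=0, pos=500_000 + i, s=-0.5, origin_gen=0) for i in range(5)]
        haps = [Haplotype(a_muts, "I")] * 4 + [Haplotype(b_muts, "I")] * 4
        snap = build_snapshot(haps, layout, span_only=True)
        order = np.argsort(snap.matrix[:, 0])[::-1]
        m = snap.matrix[order]
        assert (m[:4, :5] == 1).all() and (m[:4, 5:] == 0).all()
        assert (m[4:, 5:] == 1).all() and (m[4:, :5] == 0).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_fst_invariant_to_row_permutation(seed):
    rng = np.random.default_rng(seed)
    matrix = rng.integers(0, 2, size=(12, 8), dtype=np.uint8)
    arrangements = np.array(["I"] * 6 + ["S"] * 6, dtype=object)
    snap = make_snapshot(matrix, arrangements)
    perm = rng.permutation(12)
    snap_p = make_snapshot(matrix[perm], arrangements[perm])
    a = per_site_fst(snap).sort_values("uid")["fst"].to_numpy()
    b = per_site_fst(snap_p).sort_values("uid")["fst"].to_numpy()
    assert np.allclose(a, b)
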