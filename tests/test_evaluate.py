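"""Precision/recall, toy phaser, switch errors, grid search."""

from itertools import product

import numpy as np
import pytest

from nanofilter.evaluate import (
    P1_GRID,
    P2_GRID,
    P3_GRID,
    PhaseResult,
    block_n50,
    greedy_phase,
    grid_search,
    precision_recall,
    switch_errors,
)
from nanofilter.filtering import FilterConfig, FilterDecision
from nanofilter.simulate import TRUE_VARIANT, FALSE_POSITIVE

from conftest import make_sites, matrix_from_patterns


def decisions_for(sites, kept):
    return {
        s.vcf_index: FilterDecision(s.vcf_index, k, "kept" if k else "step1_max_le_p1")
        for s, k in zip(sites, kept)
    }


class TestPrecisionRecall:
    def test_all_kept_half_false(self):
        sites = make_sites(4)
        labels = {1: TRUE_VARIANT, 2: FALSE_POSITIVE, 3: TRUE_VARIANT, 4: FALSE_POSITIVE}
        r = precision_recall(decisions_for(sites, [True] * 4), labels, sites, [True] * 4)
        assert (r.precision, r.recall) == (0.5, 1.0)

    def test_perfect_filter(self):
        sites = make_sites(4)
        labels = {1: TRUE_VARIANT, 2: FALSE_POSITIVE, 3: TRUE_VARIANT, 4: FALSE_POSITIVE}
        r = precision_recall(
            decisions_for(sites, [True, False, True, False]), labels, sites, [True] * 4
        )
        assert (r.precision, r.recall) == (1.0, 1.0)
        assert (r.tp, r.fp, r.fn, r.tn) == (2, 0, 0, 2)

    def test_counts_cover_all_filterable_sites(self):
        sites = make_sites(6)
        labels = {i: TRUE_VARIANT if i % 2 else FALSE_POSITIVE for i in range(1, 7)}
        flags = [True, True, True, True, False, False]
        r = precision_recall(
            decisions_for(sites, [True, False] * 3), labels, sites, flags
        )
        assert r.tp + r.fp + r.fn + r.tn == sum(flags)

    def test_missing_label_errors(self):
        sites = make_sites(2)
        with pytest.raises(KeyError):
            precision_recall(decisions_for(sites, [True] * 2), {1: TRUE_VARIANT},
                             sites, [True, True])


class TestGreedyPhase:
    def test_discordant_majority_gives_opposite_phase(self):
        m = matrix_from_patterns(["01"] * 5 + ["10"] * 5)
        ph = greedy_phase(m, [0, 1])
        assert len(ph.blocks) == 1
        assert ph.assignment[0] != ph.assignment[1]

    def test_concordant_majority_gives_same_phase(self):
        m = matrix_from_patterns(["00"] * 6 + ["11"] * 4)
        ph = greedy_phase(m, [0, 1])
        assert ph.assignment[0] == ph.assignment[1]

    def test_unlinked_sites_are_singleton_blocks(self):
        m = matrix_from_patterns(["0.", ".1"] * 3)
        ph = greedy_phase(m, [0, 1])
        assert [len(b) for b in ph.blocks] == [1, 1]

    def test_error_free_simulation_phases_without_switches(self, small_sim):
        m = small_sim.matrix
        ph = greedy_phase(m, list(range(m.n_sites)))
        assert switch_errors(ph, small_sim.truth.phase, m) == 0


class TestSwitchErrors:
    def phase(self, m, labels):
        return PhaseResult({i: l for i, l in enumerate(labels)}, [list(range(len(labels)))])

    def test_identical_assignment_zero_errors(self):
        m = matrix_from_patterns(["00000"] * 3)
        truth = {i + 1: v for i, v in enumerate([0, 1, 0, 1, 1])}
        assert switch_errors(self.phase(m, [0, 1, 0, 1, 1]), truth, m) == 0

    def test_single_flip_mid_block_is_one_error(self):
        m = matrix_from_patterns(["00000"] * 3)
        truth = {i + 1: 0 for i in range(5)}
        assert switch_errors(self.phase(m, [0, 0, 1, 1, 1]), truth, m) == 1

    def test_global_flip_invariance(self):
        rng = np.random.default_rng(0)
        m = matrix_from_patterns(["000000"] * 3)
        truth = {i + 1: int(rng.integers(0, 2)) for i in range(6)}
        labels = [int(rng.integers(0, 2)) for _ in range(6)]
        flipped = [1 - l for l in labels]
        assert switch_errors(self.phase(m, labels), truth, m) == \
            switch_errors(self.phase(m, flipped), truth, m)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_random_assignment_mean_by_enumeration(self, k):
        # exact mean over all 2^k assignments vs truth 0^k is (k-1)/2
        m = matrix_from_patterns(["0" * k] * 3)
        truth = {i + 1: 0 for i in range(k)}
        total = 0
        for bits in product((0, 1), repeat=k):
            total += switch_errors(self.phase(m, list(bits)), truth, m)
        assert total / 2 ** k == pytest.approx((k - 1) / 2)

    def test_fp_sites_excluded_from_comparison(self):
        m = matrix_from_patterns(["000"] * 3)
        truth = {1: 0, 2: None, 3: 0}  # middle site has no truth phase
        assert switch_errors(self.phase(m, [0, 1, 0]), truth, m) == 0


class TestBlockN50:
    def test_spans_and_n50(self):
        m = matrix_from_patterns(["00000"] * 3)
        # blocks over sites at pos 100..300 (span 201) and 400..500 (span 101)
        ph = PhaseResult({i: 0 for i in range(5)}, [[0, 1, 2], [3, 4]])
        assert block_n50(ph, m) == 201

    def test_empty(self):
        m = matrix_from_patterns(["0"])
        assert block_n50(PhaseResult({}, []), m) == 0


class TestGridSearch:
    def admissible(self):
        return [
            (a, b, c) for a, b, c in product(P1_GRID, P2_GRID, P3_GRID) if a < b < c
        ]

    def test_default_grid_row_count_matches_enumeration(self):
        m = matrix_from_patterns(["0000"] * 8 + ["1111"] * 8)
        labels = {i: TRUE_VARIANT for i in range(1, 5)}
        phase = {i: 0 for i in range(1, 5)}
        table = grid_search(m, m.sites, labels, phase,
                            FilterConfig(mode="all_variants"))
        assert len(table) == len(self.admissible())
        assert sorted(map(tuple, table[["p1", "p2", "p3"]].values.tolist())) == \
            sorted(self.admissible())

    def test_single_point_grid(self):
        m = matrix_from_patterns(["00"] * 8)
        labels = {1: TRUE_VARIANT, 2: TRUE_VARIANT}
        phase = {1: 0, 2: 0}
        table = grid_search(m, m.sites, labels, phase, FilterConfig(mode="all_variants"),
                            p1_grid=[0.7], p2_grid=[0.8], p3_grid=[0.9])
        assert len(table) == 1

    def test_inadmissible_grid_is_empty(self):
        m = matrix_from_patterns(["00"] * 8)
        table = grid_search(m, m.sites, {}, {}, FilterConfig(mode="all_variants"),
                            p1_grid=[0.9], p2_grid=[0.8], p3_grid=[0.95])
        assert len(table) == 0
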