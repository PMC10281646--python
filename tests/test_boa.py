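"""Fragrance/move equations, binarization, wrapper cost, search contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionfuse.boa import (
    BOAConfig,
    FitnessEvaluator,
    binarize,
    exhaustive_select,
    fitness,
    fragrance,
    global_search_step,
    local_search_step,
    run_boa,
)
from lesionfuse.errors import InvalidArgumentError

import lesionfuse as lf


class TestFragrance:
    def test_unit_stimulus_returns_modality(self):
        assert fragrance(1.0, 0.5, 0.7) == 0.5

    def test_zero_stimulus_is_zero(self):
        assert fragrance(0.0, 0.01, 0.1) == 0.0

    def test_power_evaluation(self):
        assert fragrance(0.25, 0.01, 0.1) == pytest.approx(0.01 * 0.25**0.1)

    def test_negative_stimulus_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fragrance(-1.0, 0.01, 0.1)


class TestMoveEquations:
    def test_global_zero_fragrance_is_identity(self):
        b = np.array([0.3, 0.6])
        np.testing.assert_array_equal(
            global_search_step(b, np.array([1.0, 0.0]), 0.0, 0.5), b
        )

    def test_global_full_attraction(self):
        # d=1, F=1 lands exactly on c* (inside the cube, no clamping)
        c = np.array([0.9, 0.2])
        out = global_search_step(np.array([0.1, 0.7]), c, 1.0, 1.0)
        np.testing.assert_allclose(out, c)

    def test_global_hand_example(self):
        out = global_search_step(
            np.array([0.2, 0.8]), np.array([1.0, 0.0]), 0.5, 0.5
        )
        np.testing.assert_allclose(out, [0.225, 0.4])

    def test_local_zero_fragrance_is_identity(self):
        b = np.array([0.5, 0.5])
        np.testing.assert_array_equal(
            local_search_step(b, np.array([0.9, 0.1]), 0.0, 0.5), b
        )

    def test_local_self_pair_fixed_point_at_d1(self):
        b = np.array([0.4, 0.6])
        np.testing.assert_allclose(local_search_step(b, b, 1.0, 1.0), b)

    def test_local_hand_example(self):
        out = local_search_step(np.array([0.5]), np.array([0.1]), 1.0, 0.0)
        np.testing.assert_allclose(out, [0.4])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            global_search_step(np.zeros(2), np.zeros(3), 0.5, 0.5)
        with pytest.raises(InvalidArgumentError):
            local_search_step(np.zeros(2), np.zeros(3), 0.5, 0.5)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=6),
        st.lists(st.floats(0, 1), min_size=1, max_size=6),
        st.floats(0, 5),
        st.floats(0, 1),
    )
    def test_moves_stay_in_unit_cube(self, b, o, F, d):
        n = min(len(b), len(o))
        b, o = np.array(b[:n]), np.array(o[:n])
        for out in (
            global_search_step(b, o, F, d),
            local_search_step(b, o, F, d),
        ):
            assert (out >= 0).all() and (out <= 1).all()


class TestBinarize:
    def test_threshold_definition(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.9, 0.1, 0.51])), [True, False, True]
        )

    def test_empty_fallback_picks_largest_lowest_index(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.1, 0.1])), [True, False]
        )

    def test_saturated_all_true(self):
        assert binarize(np.ones(4)).all()


class TestFitness:
    def test_zero_error_cost_is_size_penalty(self, planted_table):
        cfg = BOAConfig(seed=0)
        full_informative = planted_table.informative_mask.copy()
        ev = FitnessEvaluator(planted_table, None, cfg)
        err = ev._knn_error(full_informative)
        cost = ev(full_informative)
        assert cost == pytest.approx(
            0.99 * err + 0.01 * full_informative.sum() / planted_table.n_features
        )

    def test_alpha_one_is_pure_error(self, planted_table):
        cfg = BOAConfig(seed=0, fitness_alpha=1.0)
        ev = FitnessEvaluator(planted_table, None, cfg)
        mask = planted_table.informative_mask
        assert ev(mask) == pytest.approx(ev._knn_error(mask))

    def test_informative_mask_beats_full_mask(self, planted_table):
        cfg = BOAConfig(seed=0)
        ev = FitnessEvaluator(planted_table, None, cfg)
        full = np.ones(planted_table.n_features, bool)
        assert ev(planted_table.informative_mask) < ev(full)

    def test_empty_mask_rejected(self, planted_table):
        with pytest.raises(InvalidArgumentError):
            fitness(
                np.zeros(planted_table.n_features, bool),
                planted_table,
                None,
                BOAConfig(seed=0),
            )

    def test_entropy_term_penalizes_low_entropy_columns(self):
        rng = np.random.default_rng(0)
        n = 120
        labels = np.arange(n) % 2
        spread = rng.uniform(-3, 3, n) + labels * 3.0
        spiky = np.where(rng.uniform(size=n) < 0.95, 0.0, 5.0) + labels * 3.0
        table = np.column_stack([spread, spiky])
        base = BOAConfig(seed=0, fitness_alpha=0.0, entropy_gamma=1.0)
        ev = FitnessEvaluator(table, labels, base)
        c_spread = ev(np.array([True, False]))
        c_spiky = ev(np.array([False, True]))
        assert c_spread < c_spiky


class TestExhaustive:
    def test_single_separating_column_found(self):
        t = lf.make_feature_table(60, 1, 2, 2, 8.0, 3)
        res = exhaustive_select(t, None, BOAConfig(seed=0))
        assert res.selected_indices == [0]

    def test_tie_breaks_toward_smaller_subset(self):
        # duplicate column: {0} and {1} and {0,1} all give the same error;
        # the smaller, lexicographically-first subset must win
        rng = np.random.default_rng(0)
        labels = np.arange(40) % 2
        col = labels * 5.0 + rng.standard_normal(40) * 0.1
        table = np.column_stack([col, col])
        res = exhaustive_select(table, labels, BOAConfig(seed=0))
        assert res.selected_indices == [0]

    def test_dimension_guard(self):
        rng = np.random.default_rng(0)
        table = rng.standard_normal((30, 21))
        with pytest.raises(InvalidArgumentError):
            exhaustive_select(table, np.arange(30) % 2, BOAConfig(seed=0))


class TestRunBoa:
    def test_deterministic_for_fixed_seed(self, planted_table):
        cfg = BOAConfig(seed=11, max_iter=15)
        a = run_boa(planted_table, None, cfg)
        b = run_boa(planted_table, None, cfg)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.best_cost_per_iter, b.best_cost_per_iter)
        assert a.best_cost == b.best_cost

    def test_trajectory_monotone_nonincreasing(self, planted_table):
        res = run_boa(planted_table, None, BOAConfig(seed=2, max_iter=30))
        assert (np.diff(res.best_cost_per_iter) <= 0).all()
        assert res.best_cost == res.best_cost_per_iter[-1]
        assert len(res.best_cost_per_iter) == 30

    def test_mask_nonempty_and_indices_sorted(self, planted_table):
        res = run_boa(planted_table, None, BOAConfig(seed=4, max_iter=10))
        assert res.mask.any()
        assert res.selected_indices == sorted(res.selected_indices)

    def test_single_column_table(self):
        rng = np.random.default_rng(0)
        labels = np.arange(30) % 2
        table = (labels * 4.0 + rng.standard_normal(30)).reshape(-1, 1)
        cfg = BOAConfig(seed=0, max_iter=5)
        res = run_boa(table, labels, cfg)
        np.testing.assert_array_equal(res.mask, [True])
        assert res.best_cost == pytest.approx(
            fitness(np.array([True]), table, labels, cfg)
        )

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidArgumentError):
            run_boa(rng.standard_normal((20, 3)), np.zeros(20, int), BOAConfig(seed=0))

    def test_matches_oracle_on_one_seed(self, planted_table):
        cfg = BOAConfig(seed=0)
        res = run_boa(planted_table, None, cfg)
        opt = exhaustive_select(planted_table, None, cfg)
        assert res.best_cost == opt.best_cost

    def test_reduces_wide_table(self):
        """On a wide synthetic table the selected count drops strictly
        below the input width."""
        t = lf.make_feature_table(60, 4, 96, 3, 3.0, 8)
        cfg = BOAConfig(seed=1, max_iter=10, refine_budget=64)
        res = run_boa(t, None, cfg)
        assert 0 < res.mask.sum() < 100

    def test_config_validation(self):
        with pytest.raises(InvalidArgumentError):
            BOAConfig(switch_prob_p=1.5)
        with pytest.raises(InvalidArgumentError):
            BOAConfig(population=1)
        with pytest.raises(InvalidArgumentError):
            BOAConfig(binarize_threshold=0.0)
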