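import math

import numpy as np
import pytest

from ffavarsel.dataio import RunConfig
from ffavarsel.firefly import (
    attractiveness,
    batch_evaluate,
    distance,
    encode,
    init_population,
    move,
    run_fa_mlr,
    Firefly,
)
from ffavarsel.moo import ObjectiveVector, dominates
from ffavarsel.regression import evaluate_subset


def _cfg(**kw):
    base = dict(n_fireflies=10, max_iterations=5, seed=0, split_sizes=(4, 2, 2))
    base.update(kw)
    return RunConfig(**base)


class TestEncode:
    @pytest.mark.parametrize(
        "position, mask",
        [
            ([0.95, 0.48, 0.45, 0.44, 0.92], [1, 0, 0, 0, 1]),
            ([0.23, 0.89, 0.01, 0.61, 0.73], [0, 1, 0, 1, 1]),
            ([0.60, 0.76, 0.82, 0.79, 0.17], [1, 1, 1, 1, 0]),
        ],
    )
    def test_threshold_encoding(self, position, mask):
        np.testing.assert_array_equal(encode(np.array(position), 0.5), mask)

    def test_boundary_is_strict(self):
        np.testing.assert_array_equal(encode(np.array([0.5, 0.5]), 0.5), [0, 0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            encode(np.array([np.nan]), 0.5)


class TestDistance:
    def test_identical_vectors(self):
        assert distance(np.ones(4), np.ones(4)) == 0.0

    def test_three_four_five(self):
        assert distance(np.zeros(2), np.array([3.0, 4.0])) == pytest.approx(5.0)

    def test_metric_properties(self, rng):
        for _ in range(20):
            a, b, c = rng.random((3, 6))
            assert distance(a, b) == pytest.approx(distance(b, a))
            assert distance(a, c) <= distance(a, b) + distance(b, c) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            distance(np.ones(3), np.ones(4))


class TestAttractiveness:
    def test_r_zero_gives_beta0(self):
        assert attractiveness(0.0, beta0=2.5, gamma=3.0) == 2.5

    def test_gamma_zero_no_absorption(self):
        assert attractiveness(7.0, beta0=2.5, gamma=0.0) == 2.5

    def test_unit_case(self):
        assert attractiveness(1.0, beta0=1.0, gamma=1.0) == pytest.approx(
            math.exp(-1), abs=1e-12
        )

    def test_strictly_decreasing(self):
        vals = [attractiveness(r, 1.0, 1.0) for r in (0.0, 0.5, 1.0, 2.0)]
        assert vals == sorted(vals, reverse=True)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            attractiveness(-0.1, 1.0, 1.0)


class TestMove:
    def test_full_attraction_teleports_to_target(self, rng):
        cfg = _cfg(alpha=0.0, beta0=1.0, gamma=0.0)
        x_i, x_j = rng.random(5), rng.random(5)
        np.testing.assert_allclose(move(x_i, x_j, cfg, rng), x_j, atol=1e-12)

    def test_huge_absorption_freezes_firefly(self, rng):
        cfg = _cfg(alpha=0.0, beta0=1.0, gamma=1e12)
        x_i, x_j = rng.random(5), rng.random(5)
        np.testing.assert_allclose(move(x_i, x_j, cfg, rng), x_i, atol=1e-9)

    def test_unit_distance_displacement(self, rng):
        cfg = _cfg(alpha=0.0, beta0=1.0, gamma=1.0)
        out = move(np.array([0.0]), np.array([1.0]), cfg, rng)
        assert out[0] == pytest.approx(math.exp(-1), abs=1e-12)

    def test_no_self_movement_with_alpha_zero(self, rng):
        cfg = _cfg(alpha=0.0)
        x = rng.random(4)
        np.testing.assert_array_equal(move(x, x, cfg, rng), x)

    def test_output_clamped_to_unit_cube(self, rng):
        cfg = _cfg(alpha=1.0, beta0=1.0, gamma=0.0)
        for _ in range(50):
            out = move(rng.random(6), rng.random(6), cfg, rng)
            assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestInitPopulation:
    def test_same_seed_identical(self):
        a = init_population(8, 5, seed=3)
        b = init_population(8, 5, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.position, fb.position)
            np.testing.assert_array_equal(fa.mask, fb.mask)

    def test_uniform_moments_and_range(self):
        pop = init_population(1000, 10, seed=0)
        P = np.array([f.position for f in pop])
        assert np.all(P >= 0) and np.all(P <= 1)
        assert 0.47 <= P.mean() <= 0.53

    def test_masks_consistent_with_positions(self):
        for f in init_population(20, 7, seed=1):
            np.testing.assert_array_equal(f.mask, encode(f.position, 0.5))

    def test_population_of_one_rejected(self):
        with pytest.raises(ValueError):
            init_population(1, 5, seed=0)


class TestBatchEvaluate:
    def test_matches_sequential_oracle(self, small_planted, rng):
        data, spec, split = small_planted
        pop = []
        for _ in range(50):
            mask = (rng.random(data.n_variables) > 0.5).astype(np.uint8)
            pos = np.where(mask, 0.75, 0.25)
            pop.append(Firefly(position=pos, mask=mask))
        batch = batch_evaluate(pop, data, split)
        for f, obj in zip(pop, batch):
            if f.mask.sum() == 0:
                assert not math.isfinite(obj.error)
            else:
                fit = evaluate_subset(data, split, np.flatnonzero(f.mask))
                assert obj == ObjectiveVector(fit.metrics["rmsep"], int(f.mask.sum()))

    def test_single_firefly(self, small_planted):
        data, spec, split = small_planted
        mask = np.zeros(data.n_variables, dtype=np.uint8)
        mask[list(spec.support)] = 1
        out = batch_evaluate(
            [Firefly(position=mask * 0.75, mask=mask)], data, split
        )
        assert len(out) == 1 and out[0].n_vars == len(spec.support)

    def test_empty_mask_gets_infeasible_sentinel(self, small_planted):
        data, spec, split = small_planted
        K = data.n_variables
        pop = [
            Firefly(position=np.zeros(K), mask=np.zeros(K, dtype=np.uint8)),
            Firefly(position=np.ones(K), mask=np.ones(K, dtype=np.uint8)),
        ]
        out = batch_evaluate(pop, data, split)
        assert math.isinf(out[0].error)
        assert math.isfinite(out[1].error)


@pytest.fixture(scope="module")
def run(small_planted):
    data, spec, split = small_planted
    cfg = RunConfig(
        n_fireflies=40,
        max_iterations=60,
        seed=0,
        gamma=6.0 / data.n_variables,
        split_sizes=(80, 35, 35),
    )
    best, state = run_fa_mlr(data, split, cfg)
    return data, spec, split, cfg, best, state


class TestRunFAMLR:
    def test_same_seed_identical_result(self, run):
        data, spec, split, cfg, best, state = run
        best2, state2 = run_fa_mlr(data, split, cfg)
        assert best2.selected == best.selected
        assert best2.metrics == best.metrics
        np.testing.assert_array_equal(best2.coefficients, best.coefficients)

    def test_best_so_far_error_non_increasing(self, run):
        *_, state = run
        errs = [t["best_error"] for t in state.trace]
        assert all(b <= a for a, b in zip(errs, errs[1:]))

    def test_positions_stay_in_unit_cube(self, run):
        *_, state = run
        P = np.array([f.position for f in state.population])
        assert np.all(P >= 0.0) and np.all(P <= 1.0)

    def test_masks_consistent_with_positions(self, run):
        *_, state = run
        for f in state.population:
            np.testing.assert_array_equal(f.mask, encode(f.position, 0.5))

    def test_archive_mutually_non_dominated(self, run):
        *_, state = run
        objs = [obj for obj, _ in state.archive]
        for a in objs:
            assert not any(dominates(b, a) for b in objs)

    def test_best_is_decision_maker_choice_from_archive(self, run):
        data, spec, split, cfg, best, state = run
        from ffavarsel.moo import decision_maker

        chosen = decision_maker(state.archive)
        assert tuple(np.flatnonzero(chosen)) == best.selected
        assert best.eval_split == "prediction"

    def test_selected_variables_are_planted_support(self, run):
        # on a small planted problem the search recovers the support
        data, spec, split, cfg, best, state = run
        assert set(best.selected) <= set(spec.support)
        assert len(set(best.selected) & set(spec.support)) >= 2

    def test_evaluation_budget_respected(self, run):
        data, spec, split, cfg, best, state = run
        assert state.n_evaluations <= cfg.n_fireflies * (
            1 + cfg.max_iterations * cfg.n_fireflies
        )

    def test_intensity_is_negative_error(self, run):
        *_, state = run
        f = state.population[0]
        assert f.intensity == -f.objectives.error
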