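"""Mechanism-level and loop-level behavior of the baseline optimizer."""

import math

import numpy as np
import pytest

from bimgo.mgo import (
    OptimizerConfig,
    Population,
    bmh,
    coef_BH,
    coef_matrix,
    coef_vector,
    control_factor_linear,
    mgo_minimize,
    mh,
    msf,
    tsm,
    weight_F,
)
from bimgo.problems import get_problem


def make_pop(positions, objective=lambda x: float(np.sum(x**2))):
    positions = np.asarray(positions, dtype=float)
    values = np.array([objective(x) for x in positions])
    pop = Population(positions, values)
    pop.sort()
    return pop


class TestCoefBH:
    def test_identical_rows_return_that_row(self, rng):
        v = np.array([1.5, -2.0, 0.25])
        pop = make_pop(np.tile(v, (6, 1)))
        for _ in range(20):
            assert np.allclose(coef_BH(pop, rng), v)

    def test_requires_sorted_population(self, rng):
        pop = make_pop(np.arange(12.0).reshape(4, 3))
        pop.sorted_flag = False
        with pytest.raises(ValueError):
            coef_BH(pop, rng)

    def test_floor_r1_kills_the_young_male_term(self, rng):
        # with floor(r1)=0 a.s., BH is a mean of population rows, so it lies
        # inside the componentwise convex hull of the population
        pop = make_pop(rng.normal(size=(9, 4)))
        lo = pop.positions.min(axis=0) - 1e-12
        hi = pop.positions.max(axis=0) + 1e-12
        for _ in range(200):
            bh = coef_BH(pop, rng)
            assert np.all(bh >= lo) and np.all(bh <= hi)

    def test_young_male_stratum_indices_uniform(self, rng):
        # N=6: ra ranges over 0-based rows {1..5}; check uniformity at 1e4 draws
        n = 6
        pop = make_pop(np.arange(n, dtype=float)[:, None])
        counts = np.zeros(n)
        trials = 10_000
        for _ in range(trials):
            k = math.ceil(n / 3)
            ra = int(rng.integers(k - 1, n))
            counts[ra] += 1
        assert counts[0] == 0
        expected = trials / 5
        sigma = math.sqrt(trials * (1 / 5) * (4 / 5))
        assert np.all(np.abs(counts[1:] - expected) < 3.5 * sigma)


class TestWeightF:
    def test_scale_endpoints(self, rng):
        f0 = np.array([weight_F(1, 0, 500, rng)[0] for _ in range(20_000)])
        fT = np.array([weight_F(1, 500, 500, rng)[0] for _ in range(100_000)])
        assert np.std(f0) == pytest.approx(math.exp(2.0), rel=0.05)
        assert np.var(fT) == pytest.approx(1.0, rel=0.05)


def test_control_factor_linear_schedule():
    assert control_factor_linear(0, 500) == -1.0
    assert control_factor_linear(500, 500) == -2.0
    assert control_factor_linear(250, 500) == -1.5


class TestCoefVector:
    def test_branch_one_zero_at_endpoint(self):
        class FakeRng:
            def integers(self, *a, **k):
                return 0

            def random(self, size=None):
                return 0.0 if size is None else np.zeros(size)

            def standard_normal(self, size=None):
                return np.zeros(size if size else 1)

        assert np.allclose(coef_vector(-1.0, 5, FakeRng()), 0.0)

    def test_uniform_branch_in_unit_interval(self, rng):
        cof = coef_matrix(-1.5, 8, rng)
        assert np.all((cof[2] >= 0) & (cof[2] < 1))

    def test_branches_chosen_uniformly(self, rng):
        # classify 4e4 realizations by their structural signature
        trials = 40_000
        counts = np.zeros(4)
        for _ in range(trials):
            v = coef_vector(-1.5, 6, rng)
            if np.allclose(v, v[0]):
                counts[0] += 1  # broadcast scalar branch
            elif np.all((v >= 0) & (v < 1)):
                counts[2] += 1  # uniform branch
            else:
                counts[1] += 1  # either gaussian branch (indistinguishable)
        p0 = 1 / 4
        sigma = math.sqrt(trials * p0 * (1 - p0))
        assert abs(counts[0] - trials * p0) < 4 * sigma
        # uniform branch misclassifies a negligible fraction of gaussians
        assert abs(counts[2] - trials * p0) < 5 * sigma
        assert abs(counts[1] - trials * 2 * p0) < 5 * sigma


class TestMechanisms:
    def test_tsm_returns_best_when_absolute_term_vanishes(self, rng):
        pop = make_pop(rng.normal(size=(5, 3)))
        x = pop.positions[2]
        out = tsm(pop, 2, np.zeros(3), x.copy(), np.ones(3), rng)
        assert np.allclose(out, pop.best_position)

    def test_tsm_matches_straight_line_transcription(self):
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        pop = make_pop(np.arange(12.0).reshape(4, 3))
        F = np.array([0.5, -1.0, 2.0])
        BH = np.array([1.0, 1.0, 1.0])
        Cof = np.array([0.1, 0.2, 0.3])
        got = tsm(pop, 1, F, BH, Cof, rng1)
        ri1 = int(rng2.integers(1, 3))
        ri2 = int(rng2.integers(1, 3))
        want = pop.best_position - np.abs((ri1 * BH - ri2 * pop.positions[1]) * F) * Cof
        assert np.array_equal(got, want)

    def test_mh_single_member_population(self, rng):
        pop = make_pop([[2.0, -1.0]])
        BH = pop.positions[0].copy()
        out = mh(pop, 0, BH, -1.0, rng)
        assert out.shape == (2,)

    def test_mh_matches_straight_line_transcription(self):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        pop = make_pop(np.arange(8.0).reshape(4, 2))
        BH = np.array([0.5, 0.5])
        a = -1.3
        got = mh(pop, 0, BH, a, rng1)
        cof = coef_matrix(a, 2, rng2)
        cof1 = cof[int(rng2.integers(4))]
        cof2 = cof[int(rng2.integers(4))]
        ri3 = int(rng2.integers(1, 3))
        ri4 = int(rng2.integers(1, 3))
        x_rand = pop.positions[int(rng2.integers(4))]
        want = (BH + cof1) + (ri3 * pop.best_position - ri4 * x_rand) * cof2
        assert np.array_equal(got, want)

    def test_bmh_zero_population_stays_zero(self, rng):
        pop = make_pop(np.zeros((4, 3)))
        out = bmh(pop, 1, np.zeros(3), np.ones(3), rng)
        assert np.allclose(out, 0.0)

    def test_bmh_matches_straight_line_transcription(self):
        rng1 = np.random.default_rng(11)
        rng2 = np.random.default_rng(11)
        pop = make_pop(np.arange(8.0).reshape(4, 2) - 3.0)
        BH = np.array([1.0, -1.0])
        Cof = np.array([0.5, 0.5])
        got = bmh(pop, 2, BH, Cof, rng1)
        r6 = rng2.random()
        d = (np.abs(pop.positions[2]) + np.abs(pop.best_position)) * (2 * r6 - 1)
        ri5 = int(rng2.integers(1, 3))
        ri6 = int(rng2.integers(1, 3))
        want = (pop.positions[2] - d) + (ri5 * pop.best_position - ri6 * BH) * Cof
        assert np.array_equal(got, want)

    def test_msf_respects_bounds_and_mean(self, rng):
        spec = get_problem("f1", 2)
        pts = np.array([msf(spec, rng) for _ in range(10_000)])
        assert np.all(pts >= spec.lower) and np.all(pts <= spec.upper)
        assert np.allclose(pts.mean(axis=0), 0.0, atol=3.0)

    def test_msf_degenerate_box(self, rng):
        # a zero-width box always returns its single point (formula property;
        # ProblemSpec itself requires strictly positive width)
        class Stub:
            dim = 2
            lower = np.array([1.0, 2.0])
            upper = np.array([1.0, 2.0])

        assert np.array_equal(msf(Stub(), rng), [1.0, 2.0])


class TestMgoMinimize:
    def test_single_iteration_elitism(self):
        spec = get_problem("f1", 5)
        res = mgo_minimize(spec, OptimizerConfig(pop_size=6, max_iter=1, seed=3))
        assert res.trace.shape == (1,)
        assert math.isfinite(res.best_value)

    def test_trace_monotone_and_eval_accounting(self):
        spec = get_problem("f9", 4)
        cfg = OptimizerConfig(pop_size=8, max_iter=30, seed=5)
        res = mgo_minimize(spec, cfg)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.n_evals == cfg.pop_size + cfg.max_iter * 4 * cfg.pop_size

    def test_bitwise_reproducibility(self):
        spec = get_problem("f9", 3)
        cfg = OptimizerConfig(pop_size=6, max_iter=20, seed=77)
        r1 = mgo_minimize(spec, cfg)
        r2 = mgo_minimize(spec, cfg)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.trace, r2.trace)
        r3 = mgo_minimize(spec, OptimizerConfig(pop_size=6, max_iter=20, seed=78))
        assert not np.array_equal(r1.trace, r3.trace)

    def test_result_within_bounds(self):
        spec = get_problem("f8", 5)
        res = mgo_minimize(spec, OptimizerConfig(pop_size=6, max_iter=25, seed=1))
        assert np.all(res.best_position >= spec.lower)
        assert np.all(res.best_position <= spec.upper)

    @pytest.mark.parametrize("seed", range(5))
    def test_converges_on_small_sphere(self, seed):
        spec = get_problem("f1", 2)
        res = mgo_minimize(spec, OptimizerConfig(pop_size=30, max_iter=200, seed=seed))
        assert res.best_value < 1e-6

    def test_pop_size_minimum(self):
        with pytest.raises(ValueError):
            OptimizerConfig(pop_size=3)

    def test_non_finite_objective_raises(self):
        from bimgo.problems import ProblemSpec

        spec = ProblemSpec(
            name="bad", dim=2,
            lower=np.array([-1.0, -1.0]), upper=np.array([1.0, 1.0]),
            objective=lambda x: float("nan"),
        )
        with pytest.raises(FloatingPointError):
            mgo_minimize(spec, OptimizerConfig(pop_size=4, max_iter=2, seed=0))
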