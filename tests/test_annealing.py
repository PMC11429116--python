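"""SA wrapper selection: cost arithmetic, schedule, acceptance, sweep."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import swayrisk as sw
from swayrisk.annealing import (
    LK_GROWTH,
    CostEvaluator,
    SAConfig,
    anneal,
    cost,
    dimension_sweep,
    metropolis_accept,
    random_solution,
    search_space_size,
)
from tests.conftest import make_feature_table

POOL10 = tuple(f"f{i}" for i in range(10))


class TestCostFunction:
    def _fixture(self, informative=None, seed=0, risk_scale=0.35):
        table = make_feature_table(informative=informative, seed=seed,
                                   risk_scale=risk_scale)
        split = sw.stratified_split(table, seed=seed)
        ztable, _ = sw.standardize(table, fit_rows=split.train)
        return ztable, split

    def test_mean_minus_sample_sd_arithmetic(self):
        # on the AUC triple (0.83, 0.78, 0.72) the sample SD is 0.0551,
        # giving cost 0.7767 - 0.0551 = 0.7216
        aucs = np.array([0.83, 0.78, 0.72])
        value = aucs.mean() - aucs.std(ddof=1)
        assert value == pytest.approx(0.7216, abs=5e-5)
        assert aucs.std(ddof=1) == pytest.approx(0.055, abs=5e-4)

    def test_penalty_zeroes_cost(self):
        # a strong planted feature passes; pure noise features trip the
        # sensitivity/specificity floor and are penalized to exactly 0
        ztable, split = self._fixture(
            informative={"std_rd": 3.0, "total_power_ap": 3.0},
            risk_scale=0.2)
        good = cost(("std_rd", "total_power_ap"), split, ztable)
        assert good > 0.5
        noise = cost(("height", "foot_length"), split, ztable,
                     penalty_threshold=0.6)
        assert noise == 0.0

    def test_equal_aucs_give_mean(self):
        aucs = np.array([0.7, 0.7, 0.7])
        assert aucs.mean() - aucs.std(ddof=1) == pytest.approx(0.7)

    def test_cost_deterministic_given_split(self):
        ztable, split = self._fixture(informative={"std_rd": 2.0})
        ev = CostEvaluator(ztable, split)
        subset = ("std_rd", "age", "bmi")
        assert ev(subset) == ev(subset)

    def test_cost_bounded(self):
        ztable, split = self._fixture(informative={"std_rd": 2.0}, seed=3)
        ev = CostEvaluator(ztable, split, penalty_threshold=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = ev(random_solution(sw.ALL_FEATURES, 5, rng))
            assert -1.0 <= c <= 1.0


class TestRandomSolution:
    def test_full_pool(self):
        rng = np.random.default_rng(0)
        assert set(random_solution(POOL10, 10, rng)) == set(POOL10)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            random_solution(POOL10, 11, np.random.default_rng(0))

    def test_seed_determinism(self):
        s1 = random_solution(POOL10, 4, np.random.default_rng(9))
        s2 = random_solution(POOL10, 4, np.random.default_rng(9))
        assert s1 == s2

    def test_single_draws_uniform(self):
        # n=1 from 47: each feature's frequency within 4 sigma of m/47
        pool = tuple(sw.ALL_FEATURES)
        rng = np.random.default_rng(1)
        m = 10_000
        counts = {f: 0 for f in pool}
        for _ in range(m):
            counts[random_solution(pool, 1, rng)[0]] += 1
        p = 1 / len(pool)
        sigma = math.sqrt(m * p * (1 - p))
        for f in pool:
            assert abs(counts[f] - m * p) < 4 * sigma


class TestMetropolis:
    def test_improvement_always_accepted(self):
        assert metropolis_accept(0.0, 0.5, 0.999999)
        assert metropolis_accept(0.3, 1e-9, 0.999999)

    def test_acceptance_rate_matches_boltzmann(self):
        # forced-delta harness: empirical rate ~ exp(delta/T) +- binomial
        rng = np.random.default_rng(12)
        n = 10_000
        for delta, t in ((-0.1, 0.5), (-0.3, 0.5), (-0.05, 0.1)):
            expect = math.exp(delta / t)
            hits = sum(metropolis_accept(delta, t, rng.random())
                       for _ in range(n))
            sigma = math.sqrt(n * expect * (1 - expect))
            assert abs(hits - n * expect) < 4 * sigma


class TestAnneal:
    def test_constant_cost(self):
        cfg = SAConfig(lk0=2, tmin=0.3, pool=POOL10, seed=0)
        res = anneal(3, POOL10[:3], cfg, cost_fn=lambda s: 0.4)
        assert res.best_cost == 0.4
        assert (res.cost_history == 0.4).all()

    def test_default_schedule_has_17_levels(self):
        # smallest j with 0.5979 * 0.82^j <= 0.0232 is 17
        cfg = SAConfig(pool=POOL10, seed=0)
        res = anneal(2, POOL10[:2], cfg, cost_fn=lambda s: 0.0)
        assert res.n_levels == 17
        j = math.ceil(math.log(cfg.tmin / cfg.t0) / math.log(cfg.alpha))
        assert j == 17

    def test_evaluation_count_matches_schedule(self):
        cfg = SAConfig(pool=POOL10, seed=0)
        res = anneal(2, POOL10[:2], cfg, cost_fn=lambda s: 0.0)
        expected = sum(round(30 * LK_GROWTH ** j) for j in range(17))
        assert res.n_evals == expected

    def test_best_cost_is_history_max_and_reproducible(self):
        rng_cost = np.random.default_rng(5)
        seen = {}

        def noisy(subset):
            if subset not in seen:
                seen[subset] = float(rng_cost.random())
            return seen[subset]

        cfg = SAConfig(lk0=5, tmin=0.2, pool=POOL10, seed=3)
        res = anneal(3, POOL10[:3], cfg, cost_fn=noisy)
        assert res.best_cost == res.cost_history.max()
        # the returned subset re-evaluates to the recorded maximum
        assert noisy(res.best_subset) == res.best_cost

    def test_best_so_far_nondecreasing(self):
        cfg = SAConfig(lk0=5, tmin=0.2, pool=POOL10, seed=4)
        rng_cost = np.random.default_rng(0)
        res = anneal(3, POOL10[:3], cfg,
                     cost_fn=lambda s: float(rng_cost.random()))
        running = np.maximum.accumulate(res.cost_history)
        assert (np.diff(running) >= 0).all()

    def test_planted_pair_recovered_quick(self):
        # reduced-schedule sanity run; the full-budget version is part of
        # the acceptance battery
        target = {"f1", "f2"}
        cfg = SAConfig(lk0=10, tmin=0.1, pool=POOL10, seed=0)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = anneal(2, random_solution(POOL10, 2, rng), cfg,
                         cost_fn=lambda s: float(target <= set(s)), rng=rng)
            hits += set(res.best_subset) == target
        assert hits >= 19

    def test_as_printed_mode_evaluates_once_per_level(self):
        cfg = SAConfig(pool=POOL10, seed=1, mode="as_printed")
        res = anneal(2, POOL10[:2], cfg, cost_fn=lambda s: 0.1)
        # literal pseudocode: one candidate per temperature step
        assert res.n_evals == res.n_levels == 17
        assert res.best_cost == 0.1

    def test_wrong_initial_size_rejected(self):
        cfg = SAConfig(pool=POOL10)
        with pytest.raises(ValueError):
            anneal(3, POOL10[:2], cfg, cost_fn=lambda s: 0.0)


class TestDimensionSweep:
    def test_stop_patience_one_with_worsening_cost(self):
        cfg = SAConfig(lk0=2, tmin=0.3, pool=POOL10, seed=0,
                       penalty_threshold=0.0)
        res = dimension_sweep(cfg, None, None, n_start=2, stop_patience=1,
                              initial_features=POOL10[:2],
                              cost_fn=lambda s: -len(s), seed=0)
        assert res.stopped_at == 3
        assert sorted(res.dimensions) == [2, 3]

    def test_tally_accounting_identity(self):
        cfg = SAConfig(lk0=2, tmin=0.3, pool=POOL10, seed=0,
                       penalty_threshold=0.0)
        res = dimension_sweep(cfg, None, None, n_start=2, stop_patience=2,
                              initial_features=POOL10[:2],
                              cost_fn=lambda s: -len(s), seed=0)
        assert sum(res.feature_frequency.values()) == sum(res.dimensions)

    def test_subset_sizes_match_dimension(self):
        cfg = SAConfig(lk0=2, tmin=0.3, pool=POOL10, seed=1,
                       penalty_threshold=0.0)
        rng_cost = np.random.default_rng(2)
        res = dimension_sweep(cfg, None, None, n_start=3, stop_patience=2,
                              initial_features=POOL10[:3],
                              cost_fn=lambda s: float(rng_cost.random()),
                              seed=1)
        for n, r in res.dimensions.items():
            assert len(r.best_subset) == n

    def test_missing_seed_feature_named(self, feature_table):
        split = sw.stratified_split(feature_table, seed=0)
        ztable, _ = sw.standardize(feature_table, fit_rows=split.train)
        cfg = SAConfig(pool=tuple(sw.COP_INDICES), seed=0)  # no descriptives
        with pytest.raises(ValueError, match="sex"):
            dimension_sweep(cfg, split, ztable)

    def test_warm_start_contains_previous_optimum(self):
        cfg = SAConfig(lk0=1, tmin=0.5, pool=POOL10, seed=0,
                       penalty_threshold=0.0)

        def prefer_low_indices(s):
            return -sum(int(f[1:]) for f in s) / 100.0

        res = dimension_sweep(cfg, None, None, n_start=2, stop_patience=3,
                              initial_features=POOL10[:2],
                              cost_fn=prefer_low_indices, seed=0)
        dims = sorted(res.dimensions)
        assert res.dimensions[dims[0]].best_cost >= \
            res.dimensions[dims[1]].best_cost


class TestSearchSpace:
    def test_pool_of_42(self):
        assert search_space_size(42, 21) == 538_257_874_440
        assert search_space_size(42, 24) == 353_697_121_050

    def test_edge_cases(self):
        assert search_space_size(47, 0) == 1
        assert search_space_size(5, 5) == 1
        with pytest.raises(ValueError):
            search_space_size(5, 6)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 50), st.integers(0, 50))
    def test_pascals_rule(self, m, n):
        if n > m:
            return
        if 0 < n:
            assert search_space_size(m, n) == (
                search_space_size(m - 1, n - 1)
                + (search_space_size(m - 1, n) if n <= m - 1 else 0))
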