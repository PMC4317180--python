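"""Inspection allocation, the logistic surface, and the equilibrium solver."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from scipy.stats import norm

from policymix import (
    PolicyMix,
    ProfitModel,
    allocate_knapsack,
    allocate_logistic,
    fit_logistic,
    inspection_cost,
    optimal_deforestation,
    solve_equilibrium,
)
from policymix.enforcement import EnforcementPlan
from policymix.errors import ConfigurationError, FittingError

from conftest import cells_frame, random_profit_model


class TestInspectionCost:
    def test_arithmetic(self):
        cells = pd.DataFrame({"tc_first": [1000.0], "tc_within": [50.0],
                              "n_patches": [35.0]})
        assert inspection_cost(cells)[0] == pytest.approx(2750.0)

    def test_no_patches_costs_first_visit_only(self):
        cells = pd.DataFrame({"tc_first": [1234.0], "tc_within": [50.0],
                              "n_patches": [0.0]})
        assert inspection_cost(cells)[0] == pytest.approx(1234.0)


class TestKnapsack:
    def test_three_cell_example(self):
        # ratios 10, 5, 2: fund the first two fully, 5/100 of the third
        plan = allocate_knapsack([100.0, 50.0, 200.0], [10.0, 10.0, 100.0], 25.0)
        np.testing.assert_allclose(plan.p, [1.0, 1.0, 0.05])
        assert plan.objective == pytest.approx(160.0)
        assert plan.total_cost == pytest.approx(25.0)

    def test_slack_budget_funds_everything(self):
        plan = allocate_knapsack([10.0, 20.0], [5.0, 5.0], 100.0)
        np.testing.assert_allclose(plan.p, 1.0)

    def test_zero_budget(self):
        plan = allocate_knapsack([10.0, 20.0], [5.0, 5.0], 0.0)
        np.testing.assert_allclose(plan.p, 0.0)
        assert plan.objective == 0.0

    def test_zero_deforestation_never_inspected(self):
        plan = allocate_knapsack([0.0, 20.0], [5.0, 5.0], 100.0)
        assert plan.p[0] == 0.0

    def test_zero_cost_with_deforestation_rejected(self):
        with pytest.raises(ConfigurationError):
            allocate_knapsack([10.0], [0.0], 5.0)

    def test_budget_binds_when_rationed(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1, 100, 30)
        c = rng.uniform(1, 50, 30)
        B = 0.4 * c.sum()
        plan = allocate_knapsack(d, c, B)
        assert plan.total_cost == pytest.approx(B, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lp_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 13)
        d = rng.uniform(0, 500, n)
        c = rng.uniform(1, 100, n)
        B = rng.uniform(0, 1.1) * c.sum()
        plan = allocate_knapsack(d, c, B)
        lp = linprog(-d, A_ub=[c], b_ub=[B], bounds=[(0, 1)] * n)
        assert plan.objective == pytest.approx(-lp.fun, rel=1e-9, abs=1e-9)


def _separable_plan(rng, n=100):
    d = rng.uniform(10, 2000, n)
    c = rng.uniform(1000, 50_000, n)
    B = 0.4 * c.sum()
    return allocate_knapsack(d, c, B), d, c


class TestLogisticSurface:
    def test_fitted_signs(self):
        plan, d, c = _separable_plan(np.random.default_rng(1))
        coeffs = fit_logistic(plan, d, c)
        assert coeffs.b_deforestation > 0
        assert coeffs.b_cost > 0

    def test_degenerate_plan_rejected(self):
        plan = EnforcementPlan(p=np.ones(5), expected_cost=np.ones(5),
                               total_cost=5.0, objective=5.0)
        with pytest.raises(FittingError):
            fit_logistic(plan, np.ones(5), np.ones(5))

    def test_refit_on_own_predictions_is_stable(self):
        # a smooth (non-separated) plan is fitted by plain ML, for which the
        # fit is exactly stationary on its own predicted probabilities
        rng = np.random.default_rng(2)
        plan, d, c = _separable_plan(rng)
        coeffs = fit_logistic(plan, d, c)
        smooth = allocate_logistic(coeffs, d, c, 0.4 * c.sum())
        refit1 = fit_logistic(smooth, d, c)
        pred = EnforcementPlan(
            p=1 / (1 + np.exp(-refit1.linear_predictor(d, c))),
            expected_cost=np.zeros(len(d)), total_cost=0.0, objective=0.0)
        refit2 = fit_logistic(pred, d, c)
        assert refit2.b_deforestation == pytest.approx(
            refit1.b_deforestation, rel=0.01)
        assert refit2.b_cost == pytest.approx(refit1.b_cost, rel=0.01)

    def test_budget_binds_after_intercept_calibration(self):
        rng = np.random.default_rng(3)
        plan, d, c = _separable_plan(rng, n=10)
        coeffs = fit_logistic(plan, d, c)
        B = 0.5 * c.sum()
        out = allocate_logistic(coeffs, d, c, B)
        assert out.total_cost == pytest.approx(B, rel=1e-6)

    def test_zero_budget_gives_vanishing_probabilities(self):
        rng = np.random.default_rng(4)
        plan, d, c = _separable_plan(rng, n=10)
        coeffs = fit_logistic(plan, d, c)
        out = allocate_logistic(coeffs, d, c, 0.0)
        assert np.all(out.p <= 1e-9)

    def test_doubling_budget_weakly_raises_every_probability(self):
        rng = np.random.default_rng(5)
        plan, d, c = _separable_plan(rng, n=20)
        coeffs = fit_logistic(plan, d, c)
        p1 = allocate_logistic(coeffs, d, c, 0.2 * c.sum()).p
        p2 = allocate_logistic(coeffs, d, c, 0.4 * c.sum()).p
        assert np.all(p2 >= p1 - 1e-9)

    def test_excess_budget_warns_and_caps(self):
        rng = np.random.default_rng(6)
        plan, d, c = _separable_plan(rng, n=10)
        coeffs = fit_logistic(plan, d, c)
        with pytest.warns(UserWarning, match="exceeds"):
            out = allocate_logistic(coeffs, d, c, 10 * c.sum())
        assert np.all(out.p <= 1.0)


def repeated_play_frequencies(model, costs, policy, rounds=6000):
    """Independent oracle: long-run inspection frequencies of repeated play.

    Each round the agency allocates a fresh knapsack against current
    deforestation; land users expect the running historical frequency.
    """
    pbar = np.zeros(len(costs))
    for t in range(1, rounds + 1):
        d = optimal_deforestation(model, pbar, policy)
        a = allocate_knapsack(d, costs, policy.B)
        pbar += (a.p - pbar) / t
    return pbar


class TestEquilibrium:
    def test_zero_budget_short_circuit(self):
        rng = np.random.default_rng(7)
        model = random_profit_model(rng, n=5)
        cells = cells_frame(rng.uniform(1000, 5000, 5))
        state = solve_equilibrium(model, cells, PolicyMix(B=0.0, F=3000.0))
        assert state.converged and state.iterations <= 2
        np.testing.assert_allclose(state.p, 0.0)
        np.testing.assert_allclose(state.d_prime, model.d0)

    def test_saturated_budget_full_enforcement(self):
        rng = np.random.default_rng(8)
        model = random_profit_model(rng, n=5)
        costs = rng.uniform(1000, 5000, 5)
        cells = cells_frame(costs)
        policy = PolicyMix(B=float(costs.sum() * 2), F=2000.0)
        state = solve_equilibrium(model, cells, policy)
        assert state.converged
        np.testing.assert_allclose(state.p, 1.0)
        np.testing.assert_allclose(
            state.d_prime, optimal_deforestation(model, 1.0, policy))

    def test_naive_epa_targets_baseline(self):
        rng = np.random.default_rng(9)
        model = random_profit_model(rng, n=6)
        costs = rng.uniform(1000, 5000, 6)
        cells = cells_frame(costs)
        policy = PolicyMix(B=float(costs.sum() * 0.5), F=2000.0)
        state = solve_equilibrium(model, cells, policy, naive_epa=True)
        assert state.converged
        np.testing.assert_allclose(
            state.p, allocate_knapsack(model.d0, costs, policy.B).p, atol=1e-9)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_repeated_play_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_profit_model(rng, n=4)
        costs = rng.uniform(5000, 80_000, 4)
        policy = PolicyMix(B=float(rng.uniform(0.1, 0.9) * costs.sum()),
                           F=float(rng.uniform(500, 5000)))
        state = solve_equilibrium(model, cells_frame(costs), policy)
        pbar = repeated_play_frequencies(model, costs, policy)
        d_oracle = optimal_deforestation(model, pbar, policy)
        assert state.d_prime.sum() == pytest.approx(
            d_oracle.sum(), rel=0.01, abs=1.0)

    def test_stationarity_conditions_knapsack(self, small_synthetic, small_model):
        # at the stationary state there is a shadow ratio theta: fully funded
        # cells beat it, unfunded cells fall below it, and interior cells sit
        # exactly on it; the budget binds
        policy = PolicyMix(B=2e6, F=2000.0, PES=500.0)
        state = solve_equilibrium(small_model, small_synthetic.cells, policy)
        assert state.converged
        costs = inspection_cost(small_synthetic.cells)
        ratio = np.where(costs > 0, state.d_prime / costs, 0.0)
        interior = (state.p > 1e-9) & (state.p < 1 - 1e-9)
        assert interior.any()
        theta = ratio[interior].mean()
        np.testing.assert_allclose(ratio[interior], theta, rtol=1e-6)
        assert np.all(ratio[state.p >= 1 - 1e-9] >= theta - 1e-9)
        active = small_model.d0 > 0
        assert np.all(ratio[(state.p <= 1e-9) & active] <= theta + 1e-9)
        assert float(state.p @ costs) == pytest.approx(policy.B, rel=1e-6)

    def test_budget_feasible_on_random_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            n = int(rng.integers(2, 30))
            model = random_profit_model(rng, n=n)
            costs = rng.uniform(1000, 60_000, n)
            policy = PolicyMix(B=float(rng.uniform(0, 1.2) * costs.sum()),
                               F=float(rng.uniform(0, 5000)),
                               PES=float(rng.uniform(0, 2000)))
            state = solve_equilibrium(model, cells_frame(costs), policy)
            assert float(state.p @ costs) <= policy.B * (1 + 1e-6) + 1e-9
            assert np.all(state.d_prime <= model.d0 + 1e-9)

    def test_logistic_mode_fixed_point(self, small_synthetic, small_model):
        policy = PolicyMix(B=2e6, F=2000.0, PES=500.0,
                           enforcement_mode="logistic")
        state = solve_equilibrium(small_model, small_synthetic.cells, policy)
        assert state.converged
        costs = inspection_cost(small_synthetic.cells)
        assert float(state.p @ costs) == pytest.approx(policy.B, rel=1e-6)

    def test_total_deforestation_weakly_decreasing_in_budget(
            self, small_synthetic, small_model):
        totals = []
        for B in [0.0, 5e5, 2e6, 8e6, 3e7]:
            policy = PolicyMix(B=B, F=3000.0)
            state = solve_equilibrium(small_model, small_synthetic.cells, policy)
            totals.append(state.d_prime.sum())
        assert np.all(np.diff(totals) <= 1e-6)
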