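"""Probabilistic sensitivity analysis: sampling, reproducibility, CIs, CEAC."""

import math

import numpy as np
import pytest

from nbscea.cea import DOMINANT, expected_values, incremental
from nbscea.model_core import ChanceBranch, DecisionTree, Strategy
from nbscea.psa import (
    ParameterSpec,
    PSAResult,
    ceac,
    percentile_ci,
    proportion_cost_effective,
    run_psa,
    sample_parameters,
)

from conftest import make_survival_model


def toy_tree(p_sick=0.01, cost=1000.0):
    sick = make_survival_model(0.9, cost=cost, utility=0.7, cycle=1.0)
    sick.label = "sick"
    well = make_survival_model(0.99, cost=0.0, utility=0.0, cycle=1.0)
    well.label = "well"
    return DecisionTree(
        strategies=[
            Strategy("treat", [ChanceBranch(p_sick, sick, "sick"),
                               ChanceBranch(1 - p_sick, None, "unaffected")],
                     fixed_per_person_cost=2.0),
            Strategy("wait", [ChanceBranch(p_sick, well, "sick"),
                              ChanceBranch(1 - p_sick, None, "unaffected")]),
        ],
        discount_rate_annual=0.03,
        horizon_years=5.0,
    )


def cloud(iterations, seed=0):
    arr = np.asarray(iterations, dtype=float)
    return PSAResult(iterations=arr, seed=seed, n_iter=len(arr))


class TestSampleParameters:
    def test_fixed_returns_mean_always(self):
        draws = sample_parameters([ParameterSpec("x", "fixed", 5.0)], 3, seed=1)
        assert draws.tolist() == [[5.0], [5.0], [5.0]]

    def test_same_seed_identical_draws(self):
        specs = [
            ParameterSpec("a", "beta", 0.2, 0.05),
            ParameterSpec("b", "gamma", 100.0, 20.0),
            ParameterSpec("c", "lognormal", 50.0, 10.0),
            ParameterSpec("d", "uniform", 0.0, (0.0, 1.0)),
        ]
        assert np.array_equal(sample_parameters(specs, 50, 9), sample_parameters(specs, 50, 9))

    @pytest.mark.parametrize(
        "dist, mean, spread",
        [("beta", 0.2, 0.05), ("gamma", 100.0, 20.0), ("lognormal", 100.0, 20.0)],
    )
    def test_moment_matching_recovers_mean_and_spread(self, dist, mean, spread):
        n = 100_000
        draws = sample_parameters([ParameterSpec("x", dist, mean, spread)], n, seed=11)[:, 0]
        assert abs(draws.mean() - mean) <= 3.0 * spread / math.sqrt(n)
        assert draws.std() == pytest.approx(spread, rel=0.05)

    def test_infeasible_beta_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sample_parameters([ParameterSpec("x", "beta", 0.001, 0.5)], 1, seed=0)
        with pytest.raises(ValueError, match="mean in"):
            sample_parameters([ParameterSpec("x", "beta", 0.0, 0.1)], 1, seed=0)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="unknown distribution"):
            sample_parameters([ParameterSpec("x", "cauchy", 0.0, 1.0)], 1, seed=0)


class TestRunPsa:
    def test_degenerate_psa_reproduces_deterministic_result(self):
        tree = toy_tree()
        ev = expected_values(tree)
        det = incremental(ev["treat"], ev["wait"])
        specs = [
            ParameterSpec("strategies['treat'].fixed_per_person_cost", "fixed", 2.0),
            ParameterSpec(
                "strategies['treat'].branches['sick'].model.states['alive'].annual_cost",
                "fixed",
                1000.0,
            ),
        ]
        result = run_psa(tree, specs, 25, seed=5, intervention="treat", comparator="wait")
        assert np.allclose(result.delta_cost, det.delta_cost)
        assert np.allclose(result.delta_qaly, det.delta_qaly)
        assert np.allclose(result.delta_ly, det.delta_ly)

    def test_seed_reproducibility_bit_identical(self):
        tree = toy_tree()
        specs = [
            ParameterSpec("strategies['treat'].branches['sick'].probability", "beta", 0.01, 0.002),
            ParameterSpec(
                "strategies['treat'].branches['sick'].model.states['alive'].annual_cost",
                "gamma",
                1000.0,
                200.0,
            ),
        ]
        a = run_psa(tree, specs, 40, seed=123, intervention="treat", comparator="wait")
        b = run_psa(tree, specs, 40, seed=123, intervention="treat", comparator="wait")
        assert np.array_equal(a.iterations, b.iterations)

    def test_sampled_mean_tracks_generator_mean(self):
        """Linear parameter: the mean sampled delta matches the deterministic
        delta at the parameter's mean within Monte-Carlo error."""
        tree = toy_tree()
        spec = ParameterSpec("strategies['treat'].fixed_per_person_cost", "gamma", 2.0, 0.4)
        n = 400
        result = run_psa(tree, [spec], n, seed=17, intervention="treat", comparator="wait")
        ev = expected_values(tree)
        det = incremental(ev["treat"], ev["wait"])
        se = 0.4 / math.sqrt(n)
        assert abs(result.delta_cost.mean() - det.delta_cost) <= 3.0 * se

    def test_transition_row_resampling_keeps_rows_stochastic(self):
        tree = toy_tree()
        path = "strategies['treat'].branches['sick'].model.transition_matrix[0][1]"
        spec = ParameterSpec(path, "beta", 0.3, 0.15)
        result = run_psa(tree, [spec], 50, seed=2, intervention="treat", comparator="wait")
        assert result.n_iter == 50  # wide beta still yields valid models

    def test_diagonal_cell_rejected(self):
        tree = toy_tree()
        path = "strategies['treat'].branches['sick'].model.transition_matrix[0][0]"
        with pytest.raises(ValueError, match="diagonal"):
            run_psa(tree, [ParameterSpec(path, "beta", 0.9, 0.02)], 2, seed=0,
                    intervention="treat", comparator="wait")

    def test_unknown_strategy_rejected(self):
        with pytest.raises(KeyError):
            run_psa(toy_tree(), [], 1, seed=0, intervention="nope", comparator="wait")


class TestProportionCostEffective:
    def test_all_dominant_is_one(self):
        result = cloud([(-10.0, 0.001, 0.001)] * 5)
        assert proportion_cost_effective(result, 35_000.0) == 1.0

    def test_constructed_ninety_seven_percent(self):
        points = [(-1.0, 1e-4, 1e-4)] * 970 + [(1e6, -1e-3, -1e-3)] * 30
        assert proportion_cost_effective(cloud(points), 35_000.0) == pytest.approx(0.97)

    def test_infinite_wtp_counts_positive_qaly_gains(self):
        points = [(5.0, 1e-4, 0.0)] * 3 + [(-5.0, -1e-4, 0.0)] * 1
        assert proportion_cost_effective(cloud(points), math.inf) == pytest.approx(0.75)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([rng.normal(0, 50, 500), rng.normal(0, 1e-3, 500),
                               rng.normal(0, 1e-3, 500)])
        result = cloud(pts)
        wtp = 35_000.0
        expected = sum(1 for dc, dq, _ in pts if wtp * dq - dc > 0) / 500
        assert proportion_cost_effective(result, wtp) == pytest.approx(expected)


class TestPercentileCI:
    def test_degenerate_cloud_degenerate_interval(self):
        result = cloud([(-10.0, 0.001, 0.002)] * 50)
        ci = percentile_ci(result)
        assert ci["delta_cost"] == (-10.0, -10.0)
        assert ci["delta_qaly"] == (0.001, 0.001)
        assert ci["icer_qaly"] == (DOMINANT, DOMINANT)

    def test_percentiles_match_full_sort_oracle(self):
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.uniform(-100, 100, 201), rng.uniform(-1e-3, 1e-3, 201),
                               rng.uniform(-1e-3, 1e-3, 201)])
        ci = percentile_ci(cloud(pts))

        def sort_oracle(values, q):
            v = np.sort(values)
            rank = q / 100.0 * (len(v) - 1)
            lo, frac = int(math.floor(rank)), rank - math.floor(rank)
            hi = min(lo + 1, len(v) - 1)
            return v[lo] * (1 - frac) + v[hi] * frac

        for j, key in enumerate(["delta_cost", "delta_qaly", "delta_ly"]):
            assert ci[key][0] == pytest.approx(sort_oracle(pts[:, j], 2.5), rel=1e-12)
            assert ci[key][1] == pytest.approx(sort_oracle(pts[:, j], 97.5), rel=1e-12)

    def test_quadrant_straddling_cloud_labels_dominant_endpoint(self):
        rng = np.random.default_rng(10)
        n = 500
        dc = rng.normal(20.0, 120.0, n)  # crosses zero cost
        dq = rng.uniform(5e-5, 2e-3, n)  # always more effective
        result = cloud(np.column_stack([dc, dq, dq]))
        favourable, unfavourable = percentile_ci(result)["icer_qaly"]
        assert favourable == DOMINANT
        assert isinstance(unfavourable, float) and unfavourable > 0

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError, match="40"):
            percentile_ci(cloud([(0.0, 0.0, 0.0)] * 39))


class TestCeac:
    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(50, 100, 300), rng.uniform(1e-5, 2e-3, 300),
                               rng.uniform(1e-5, 2e-3, 300)])
        result = cloud(pts)
        curve = ceac(result, [0, 10_000, 20_000, 35_000, 50_000, 100_000])
        fractions = [f for _, f in curve]
        assert fractions == sorted(fractions)

    def test_equals_pointwise_evaluation(self):
        result = cloud([(-1.0, 1e-4, 1e-4)] * 7 + [(100.0, 1e-5, 1e-5)] * 3)
        curve = ceac(result, [0.0, 35_000.0])
        for wtp, frac in curve:
            assert frac == proportion_cost_effective(result, wtp)

    def test_empty_grid_empty_curve(self):
        assert ceac(cloud([(0.0, 1.0, 1.0)]), []) == []

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            ceac(cloud([(0.0, 1.0, 1.0)]), [10.0, 5.0])
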