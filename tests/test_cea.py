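"""Decision-tree expectation, ICER classification, scaling and NMB rules."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbscea.cea import (
    DOMINANT,
    DOMINATED,
    RATIO,
    IncrementalResult,
    expected_values,
    incremental,
    net_monetary_benefit,
    scale_to_cohort,
)
from nbscea.model_core import (
    ChanceBranch,
    DecisionTree,
    HealthState,
    MarkovModel,
    OneOffCost,
    Outcome,
    Strategy,
)

from conftest import make_single_alive_model, make_survival_model


def gene_therapy_model():
    """Zero running cost; a single 1.54e6 event at entry."""
    return MarkovModel(
        label="gene-therapy",
        cycle_length_years=1.0,
        states=[
            HealthState("alive", annual_utility=1.0),
            HealthState("death", is_absorbing=True, is_death=True),
        ],
        transition_matrix=[[1.0, 0.0], [0.0, 1.0]],
        initial_distribution=[1.0, 0.0],
        one_off_costs=[OneOffCost(0.0, 1.54e6)],
    )


class TestExpectedValues:
    def test_single_branch_equals_model_plus_fixed_cost(self):
        model = make_single_alive_model(cost=100.0)
        tree = DecisionTree(
            [Strategy("s", [ChanceBranch(1.0, model, "b")], fixed_per_person_cost=7.0)],
            discount_rate_annual=0.0,
            horizon_years=3.0,
        )
        out = expected_values(tree)["s"]
        assert out.discounted_cost == pytest.approx(307.0)
        assert out.yearly_undiscounted_costs[0] == pytest.approx(107.0)

    def test_split_identical_branches_is_convex_identity(self):
        m = make_survival_model(0.9, cost=50.0)
        single = DecisionTree(
            [Strategy("s", [ChanceBranch(1.0, m, "a")])], 0.03, 5.0
        )
        split = DecisionTree(
            [Strategy("s", [ChanceBranch(0.5, m, "a"), ChanceBranch(0.5, m, "b")])], 0.03, 5.0
        )
        a = expected_values(single)["s"]
        b = expected_values(split)["s"]
        assert a.discounted_cost == pytest.approx(b.discounted_cost, rel=1e-12)
        assert a.discounted_qaly == pytest.approx(b.discounted_qaly, rel=1e-12)

    def test_rare_incidence_expected_cost(self):
        """1/11,000 incidence of a 1.54e6 entry cost averages to 140 per newborn."""
        p = 1.0 / 11_000.0
        tree = DecisionTree(
            [
                Strategy(
                    "screen",
                    [
                        ChanceBranch(p, gene_therapy_model(), "sma"),
                        ChanceBranch(1.0 - p, None, "healthy"),
                    ],
                )
            ],
            discount_rate_annual=0.03,
            horizon_years=1.0,
        )
        out = expected_values(tree)["screen"]
        assert out.discounted_cost == pytest.approx(140.0, rel=1e-12)


class TestIncremental:
    def test_published_sixty_year_increment_is_dominant(self):
        """Cost saving of 86.00 with a 0.00095 QALY gain: dominant."""
        comparator = Outcome(discounted_cost=362.58, discounted_qaly=0.00077, discounted_ly=0.00130)
        intervention = Outcome(discounted_cost=276.58, discounted_qaly=0.00172, discounted_ly=0.00267)
        inc = incremental(intervention, comparator)
        assert inc.delta_cost == pytest.approx(-86.00)
        assert inc.delta_qaly == pytest.approx(0.00095)
        assert inc.label == DOMINANT
        assert inc.icer_qaly == DOMINANT and inc.icer_ly == DOMINANT

    def test_ratio_quadrant(self):
        inc = incremental(Outcome(discounted_cost=10.0, discounted_qaly=0.001), Outcome())
        assert inc.label == RATIO
        assert inc.icer_qaly == pytest.approx(10_000.0)

    def test_dominated_quadrant(self):
        inc = incremental(Outcome(discounted_cost=10.0, discounted_qaly=-0.001), Outcome())
        assert inc.label == DOMINATED

    def test_zero_effect_rules(self):
        assert incremental(Outcome(discounted_cost=5.0), Outcome()).label == DOMINATED
        assert incremental(Outcome(discounted_cost=-5.0), Outcome()).label == DOMINANT
        both_zero = incremental(Outcome(), Outcome())
        assert both_zero.label == RATIO and both_zero.icer_qaly == 0.0

    @given(
        c1=st.floats(-100, 100), q1=st.floats(-0.01, 0.01),
        c2=st.floats(-100, 100), q2=st.floats(-0.01, 0.01),
    )
    def test_antisymmetry(self, c1, q1, c2, q2):
        a = Outcome(discounted_cost=c1, discounted_qaly=q1)
        b = Outcome(discounted_cost=c2, discounted_qaly=q2)
        ab, ba = incremental(a, b), incremental(b, a)
        assert ab.delta_cost == pytest.approx(-ba.delta_cost)
        assert ab.delta_qaly == pytest.approx(-ba.delta_qaly)


class TestScaling:
    def test_per_100k_scaling_of_published_increments(self):
        inc = IncrementalResult(-86.00, 0.00095, 0.00137, DOMINANT, DOMINANT, DOMINANT)
        scaled = scale_to_cohort(inc, 100_000)
        assert scaled.delta_qaly == pytest.approx(95.0)
        assert scaled.delta_ly == pytest.approx(137.0)
        assert scaled.delta_cost == pytest.approx(-8.6e6)
        assert scaled.label == DOMINANT  # dominance is scale invariant

    def test_identity_at_n_one(self):
        inc = IncrementalResult(45.61, 9e-5, 9e-5, 506_778.0, 506_778.0, RATIO)
        assert scale_to_cohort(inc, 1) == inc

    def test_outcome_scaling_is_linear(self):
        out = Outcome(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, [1.0, 2.0])
        doubled = scale_to_cohort(out, 2)
        assert doubled.discounted_qaly == 4.0
        assert doubled.yearly_undiscounted_costs == [2.0, 4.0]

    def test_invalid_cohort_size(self):
        with pytest.raises(ValueError):
            scale_to_cohort(Outcome(), 0)


class TestNetMonetaryBenefit:
    def test_published_increment_nmb(self):
        inc = IncrementalResult(-86.0, 0.00095, 0.00137, DOMINANT, DOMINANT, DOMINANT)
        assert net_monetary_benefit(inc, 35_000.0) == pytest.approx(119.25)

    def test_zero_wtp_reduces_to_cost_saving(self):
        inc = IncrementalResult(-86.0, 0.00095, 0.0, DOMINANT, DOMINANT, DOMINANT)
        assert net_monetary_benefit(inc, 0.0) == pytest.approx(86.0)

    def test_all_zero(self):
        inc = IncrementalResult(0.0, 0.0, 0.0, 0.0, 0.0, RATIO)
        assert net_monetary_benefit(inc, 35_000.0) == 0.0

    @given(wtp=st.floats(0, 500_000))
    def test_dominant_always_positive_dominated_always_negative(self, wtp):
        dom = IncrementalResult(-10.0, 0.001, 0.001, DOMINANT, DOMINANT, DOMINANT)
        ded = IncrementalResult(10.0, -0.001, -0.001, DOMINATED, DOMINATED, DOMINATED)
        assert net_monetary_benefit(dom, wtp) > 0
        assert net_monetary_benefit(ded, wtp) < 0

    @given(dc=st.floats(1.0, 100.0), dq=st.floats(1e-4, 1e-2), wtp=st.floats(0, 1e6))
    def test_nmb_sign_matches_icer_rule_in_quadrant_one(self, dc, dq, wtp):
        """More costly, more effective: NMB > 0 iff ICER < WTP."""
        inc = incremental(Outcome(discounted_cost=dc, discounted_qaly=dq), Outcome())
        assert inc.label == RATIO
        nmb = net_monetary_benefit(inc, wtp)
        if nmb > 0:
            assert inc.icer_qaly < wtp
        elif nmb < 0:
            assert inc.icer_qaly > wtp
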