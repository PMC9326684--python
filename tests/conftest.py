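import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from nbscea.model_core import HealthState, MarkovModel, OneOffCost
from nbscea.synthetic_data import paperlike_fixture


@pytest.fixture(scope="session")
def fixture_set():
    """The calibrated SMA+SCID fixture, built once per session."""
    return paperlike_fixture(seed=1)


def make_single_alive_model(cost=100.0, utility=1.0, cycle=1.0, one_offs=()):
    """One alive state plus an unreachable death state."""
    return MarkovModel(
        label="single-alive",
        cycle_length_years=cycle,
        states=[
            HealthState("alive", annual_utility=utility, annual_cost=cost),
            HealthState("death", is_absorbing=True, is_death=True),
        ],
        transition_matrix=[[1.0, 0.0], [0.0, 1.0]],
        initial_distribution=[1.0, 0.0],
        one_off_costs=[OneOffCost(t, a) for t, a in one_offs],
    )


def make_survival_model(p_survive, cost=0.0, utility=1.0, cycle=1.0, one_offs=()):
    """Two states with per-cycle survival probability ``p_survive``."""
    return MarkovModel(
        label="survival",
        cycle_length_years=cycle,
        states=[
            HealthState("alive", annual_utility=utility, annual_cost=cost),
            HealthState("death", is_absorbing=True, is_death=True),
        ],
        transition_matrix=[[p_survive, 1.0 - p_survive], [0.0, 1.0]],
        initial_distribution=[1.0, 0.0],
        one_off_costs=[OneOffCost(t, a) for t, a in one_offs],
    )
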