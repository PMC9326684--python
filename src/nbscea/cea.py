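"""Decision-tree expectation, incremental cost-effectiveness and decision rules.

The comparison is pairwise (intervention vs a named comparator), as is usual
when a screening programme is weighed against current practice.  Dominance is
classified on the cost/effect quadrant: lower cost *and* more effect is
``dominant``, higher cost *and* less effect is ``dominated``; otherwise the
incremental cost-effectiveness ratio (ICER) Δcost/Δeffect is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .model_core import DecisionTree, Outcome, validate_tree
from .markov_engine import run_cohort

DOMINANT = "dominant"
DOMINATED = "dominated"
RATIO = "ratio"


@dataclass
class IncrementalResult:
    """Incremental outcome of intervention minus comparator.

    ``icer_qaly`` / ``icer_ly`` hold the ratio when one is meaningful, else
    the label string; ``label`` is the QALY-based classification.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_qaly: float | str
    icer_ly: float | str
    label: str


def _classify(delta_cost: float, delta_effect: float) -> tuple[str, float | str]:
    """Return (label, icer-or-label) for one effect dimension."""
    if delta_effect == 0.0:
        if delta_cost > 0.0:
            return DOMINATED, DOMINATED
        if delta_cost < 0.0:
            return DOMINANT, DOMINANT
        return RATIO, 0.0
    if delta_cost < 0.0 and delta_effect > 0.0:
        return DOMINANT, DOMINANT
    if delta_cost > 0.0 and delta_effect < 0.0:
        return DOMINATED, DOMINATED
    return RATIO, delta_cost / delta_effect


def expected_values(
    tree: DecisionTree,
    horizon_years: float | None = None,
    half_cycle_correction: bool = False,
) -> dict[str, Outcome]:
    """Per-person expected Outcome of every strategy.

    Each strategy outcome is its fixed per-person cost (charged at t=0, so
    discounted = undiscounted) plus the probability-weighted outcomes of its
    chance branches.  Branches with ``model=None`` contribute nothing.
    """
    report = validate_tree(tree)
    if not report.ok:
        raise ValueError("invalid tree:\n  - " + "\n  - ".join(report.violations))
    horizon = tree.horizon_years if horizon_years is None else horizon_years
    n_years = max(int(math.ceil(horizon - 1e-9)), 1)
    results: dict[str, Outcome] = {}
    for strat in tree.strategies:
        total = Outcome(yearly_undiscounted_costs=[0.0] * n_years)
        for branch in strat.branches:
            if branch.model is None or branch.probability == 0.0:
                continue
            _, out = run_cohort(
                branch.model, horizon, tree.discount_rate_annual, half_cycle_correction
            )
            total = total + out.scaled(branch.probability)
        fixed = strat.fixed_per_person_cost
        total.discounted_cost += fixed
        total.undiscounted_cost += fixed
        total.yearly_undiscounted_costs[0] += fixed
        results[strat.name] = total
    return results


def incremental(intervention: Outcome, comparator: Outcome) -> IncrementalResult:
    """Incremental result of intervention over comparator (same horizon/rate)."""
    dc = intervention.discounted_cost - comparator.discounted_cost
    dq = intervention.discounted_qaly - comparator.discounted_qaly
    dl = intervention.discounted_ly - comparator.discounted_ly
    label_q, icer_q = _classify(dc, dq)
    _, icer_l = _classify(dc, dl)
    return IncrementalResult(
        delta_cost=dc, delta_qaly=dq, delta_ly=dl, icer_qaly=icer_q, icer_ly=icer_l, label=label_q
    )


def scale_to_cohort(result, n: float):
    """Scale per-person values to a cohort of ``n`` (e.g., 100,000 newborns).

    Linear in all cost/QALY/LY fields; ICERs and dominance labels are scale
    invariant and carried through unchanged.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be > 0, got {n}")
    if isinstance(result, Outcome):
        return result.scaled(n)
    if isinstance(result, IncrementalResult):
        return replace(
            result,
            delta_cost=result.delta_cost * n,
            delta_qaly=result.delta_qaly * n,
            delta_ly=result.delta_ly * n,
        )
    raise TypeError(f"cannot scale a {type(result).__name__}")


def net_monetary_benefit(result: IncrementalResult, wtp: float) -> float:
    """NMB = wtp * ΔQALY - Δcost; positive means cost-effective at ``wtp``."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * result.delta_qaly - result.delta_cost


def tree_incremental(
    tree: DecisionTree,
    intervention: str,
    comparator: str,
    horizon_years: float | None = None,
) -> IncrementalResult:
    """Convenience wrapper: expected values then incremental comparison."""
    ev = expected_values(tree, horizon_years)
    return incremental(ev[intervention], ev[comparator])
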