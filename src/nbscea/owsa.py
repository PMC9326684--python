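"""One-way (deterministic) sensitivity analysis and tornado-diagram data.

Each parameter is pinned at a low and a high bound with everything else at
base case, the full tree is re-evaluated, and the swing of a chosen output is
recorded.  The default output metric is net monetary benefit (NMB) at
USD 35,000/QALY, which is total-ordered across quadrants; an ICER mode is
available for conventional tornado reporting, but a bound whose incremental
result is dominant or dominated has no meaningful ratio and is reported as
NaN there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .model_core import (
    DecisionTree,
    copy_tree,
    get_parameter,
    rebalance_residual_branches,
    set_parameter,
)
from .cea import RATIO, expected_values, incremental, net_monetary_benefit

DEFAULT_WTP = 35_000.0


@dataclass
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    output_at_low: float
    output_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.output_at_high - self.output_at_low)


def _evaluate(
    tree: DecisionTree,
    parameter: str,
    value: float,
    output: str,
    intervention: str,
    comparator: str,
    wtp: float,
) -> float:
    pinned = copy_tree(tree)
    set_parameter(pinned, parameter, value)
    if not rebalance_residual_branches(pinned):
        raise ValueError(
            f"pinning {parameter!r} at {value} pushed a strategy's modelled branch "
            "probabilities above 1"
        )
    ev = expected_values(pinned)
    inc = incremental(ev[intervention], ev[comparator])
    if output == "nmb":
        return net_monetary_benefit(inc, wtp)
    if output == "icer":
        return inc.icer_qaly if inc.label == RATIO else float("nan")
    raise ValueError(f"output must be 'icer' or 'nmb', got {output!r}")


def one_way(
    tree: DecisionTree,
    parameter: str,
    low: float,
    high: float,
    output: str = "nmb",
    intervention: str = "",
    comparator: str = "",
    wtp: float = DEFAULT_WTP,
) -> TornadoEntry:
    """Pin one parameter at each bound, re-evaluate, and record the swing.

    The tree passed in is never mutated: evaluations run on copies, so the
    base case survives every call.
    """
    if low > high:
        raise ValueError(f"low must be <= high, got ({low}, {high})")
    get_parameter(tree, parameter)  # raises PathError early if unresolvable
    at_low = _evaluate(tree, parameter, low, output, intervention, comparator, wtp)
    at_high = _evaluate(tree, parameter, high, output, intervention, comparator, wtp)
    return TornadoEntry(
        parameter=parameter,
        low_value=low,
        high_value=high,
        output_at_low=at_low,
        output_at_high=at_high,
    )


def default_ranges(
    tree: DecisionTree, parameters, fraction: float = 0.2
) -> dict[str, tuple[float, float]]:
    """±``fraction`` bounds around each parameter's base-case value.

    Bounds are clipped to the parameter's natural support: utilities to
    [-1, 1], probabilities to [0, 1].
    """
    ranges = {}
    for p in parameters:
        base = get_parameter(tree, p)
        low, high = base * (1.0 - fraction), base * (1.0 + fraction)
        if low > high:  # negative base value
            low, high = high, low
        if "annual_utility" in p:
            low, high = max(low, -1.0), min(high, 1.0)
        elif "probability" in p or "transition_matrix" in p:
            low, high = max(low, 0.0), min(high, 1.0)
        ranges[p] = (low, high)
    return ranges


def tornado(
    tree: DecisionTree,
    ranges: Mapping[str, tuple[float, float]],
    output: str = "nmb",
    intervention: str = "",
    comparator: str = "",
    wtp: float = DEFAULT_WTP,
) -> tuple[list[TornadoEntry], float]:
    """One entry per parameter, sorted by swing descending (ties broken by
    parameter name), plus the base-case output value."""
    if not ranges:
        raise ValueError("ranges must be nonempty")
    ev = expected_values(tree)
    inc = incremental(ev[intervention], ev[comparator])
    if output == "nmb":
        base = net_monetary_benefit(inc, wtp)
    elif output == "icer":
        base = inc.icer_qaly if inc.label == RATIO else float("nan")
    else:
        raise ValueError(f"output must be 'icer' or 'nmb', got {output!r}")
    entries = [
        one_way(tree, p, lo, hi, output, intervention, comparator, wtp)
        for p, (lo, hi) in ranges.items()
    ]
    entries.sort(key=lambda e: (-(e.swing if not math.isnan(e.swing) else -math.inf), e.parameter))
    return entries, base
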