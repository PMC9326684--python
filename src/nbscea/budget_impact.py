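"""Undiscounted multi-cohort budget-impact analysis.

A budget table holds, per cost component (screening, screened SMA cases,
clinical SMA cases, ...), the expected number of persons in a birth cohort
and the component's undiscounted cost in each programme year.  One new birth
cohort enters the programme every year ("staggered cohorts"), so the
programme total in year y is the cumulative sum of the single-cohort yearly
vector, and the 5-year programme grand total satisfies the identity

    sum_y cumsum(v)[y]  ==  sum_k (n_years - k + 1) * v[k]      (1-based k)

which is computed both ways and asserted equal to the cent.

All currency is handled in integer cents internally so the arithmetic of a
printed table can be reproduced bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

CENTS = 100


def to_cents(dollars: float) -> int:
    return int(round(dollars * CENTS))


def to_dollars(cents: int) -> float:
    return cents / CENTS


def _cents_vector(values: Sequence[float], already_cents: bool) -> list[int]:
    if already_cents:
        return [int(v) for v in values]
    return [to_cents(v) for v in values]


@dataclass
class BudgetComponent:
    """One cost line: label, expected person count (fractional counts such as
    8.5 screened SMA cases per 100,000 are normal) and undiscounted yearly
    costs in integer cents."""

    label: str
    n_persons: float
    yearly_costs_cents: list[int]

    @classmethod
    def from_dollars(cls, label: str, n_persons: float, yearly_dollars: Sequence[float]):
        return cls(label, n_persons, [to_cents(v) for v in yearly_dollars])

    @property
    def yearly_costs(self) -> list[float]:
        return [to_dollars(c) for c in self.yearly_costs_cents]

    @property
    def total_cents(self) -> int:
        return sum(self.yearly_costs_cents)


@dataclass
class BudgetTable:
    """A panel of components for one programme arm and one birth cohort.

    ``printed_yearly_totals_cents``, when present, carries the source table's
    own total row (used for bit-exact reproduction of a published table whose
    component cells contain rounding residue; see the fixture loader).
    """

    components: list[BudgetComponent]
    cohort_size: float
    program_label: str = ""
    printed_yearly_totals_cents: list[int] | None = None

    def component(self, label: str) -> BudgetComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no budget component labelled {label!r}")

    def canonical_yearly_totals_cents(self) -> list[int]:
        """The yearly-total vector fed to staggering: the printed total row
        when the table carries one, otherwise the component sums."""
        if self.printed_yearly_totals_cents is not None:
            return list(self.printed_yearly_totals_cents)
        return cohort_yearly_totals(self).yearly_totals_cents


@dataclass
class CohortCosts:
    """Recomputed totals of one budget table."""

    yearly_totals_cents: list[int]
    component_totals_cents: dict[str, int]
    grand_total_cents: int

    @property
    def yearly_totals(self) -> list[float]:
        return [to_dollars(c) for c in self.yearly_totals_cents]

    @property
    def grand_total(self) -> float:
        return to_dollars(self.grand_total_cents)


@dataclass
class StaggeredBudget:
    """Programme-level totals with one new cohort entering each year."""

    program_yearly_cents: list[int]
    grand_total_cents: int

    @property
    def program_yearly(self) -> list[float]:
        return [to_dollars(c) for c in self.program_yearly_cents]

    @property
    def grand_total(self) -> float:
        return to_dollars(self.grand_total_cents)


@dataclass
class NetBudget:
    yearly_differences_cents: list[int]
    total_difference_cents: int

    @property
    def yearly_differences(self) -> list[float]:
        return [to_dollars(c) for c in self.yearly_differences_cents]

    @property
    def total_difference(self) -> float:
        return to_dollars(self.total_difference_cents)

    @property
    def total_millions_1dp(self) -> float:
        """Total difference rounded to the nearest 0.1 million (narrative form)."""
        return round(self.total_difference / 1e6, 1)

    @property
    def total_millions(self) -> float:
        """Total difference rounded to the nearest million, in millions."""
        return float(round(self.total_difference / 1e6))


def cohort_yearly_totals(table: BudgetTable) -> CohortCosts:
    """Year totals across components, per-component 5-year totals, and the
    grand total — the grand total summed from the *yearly* totals so there is
    a single canonical summation order."""
    lengths = {len(c.yearly_costs_cents) for c in table.components}
    if len(lengths) > 1:
        raise ValueError(f"components have inconsistent year counts: {sorted(lengths)}")
    n_years = lengths.pop() if lengths else 0
    yearly = [
        sum(c.yearly_costs_cents[y] for c in table.components) for y in range(n_years)
    ]
    component_totals = {c.label: c.total_cents for c in table.components}
    return CohortCosts(
        yearly_totals_cents=yearly,
        component_totals_cents=component_totals,
        grand_total_cents=sum(yearly),
    )


def staggered_totals(cohort_yearly, n_years: int | None = None, cents: bool = False) -> StaggeredBudget:
    """Programme totals with one new cohort per year.

    The cohort entering in year c contributes ``v[y - c + 1]`` (1-based) in
    year y, so the programme total in year y is the cumulative sum of ``v``.
    The grand total is computed both as the sum of the cumulative sums and as
    ``sum_k (n_years - k + 1) * v[k]``; the two are asserted equal to the
    cent.
    """
    v = _cents_vector(cohort_yearly, cents)
    if n_years is None:
        n_years = len(v)
    if n_years > len(v):
        raise ValueError(f"n_years={n_years} exceeds the yearly vector length {len(v)}")
    program = []
    running = 0
    for y in range(n_years):
        running += v[y]
        program.append(running)
    grand = sum(program)
    grand_by_weights = sum((n_years - k) * v[k] for k in range(n_years))
    assert grand == grand_by_weights, (
        f"staggered-total identity violated: {grand} != {grand_by_weights}"
    )
    return StaggeredBudget(program_yearly_cents=program, grand_total_cents=grand)


def net_budget(future: StaggeredBudget, current: StaggeredBudget) -> NetBudget:
    """Per-year and total differences, future minus current."""
    if len(future.program_yearly_cents) != len(current.program_yearly_cents):
        raise ValueError(
            f"mismatched programme lengths: {len(future.program_yearly_cents)} vs "
            f"{len(current.program_yearly_cents)}"
        )
    diffs = [f - c for f, c in zip(future.program_yearly_cents, current.program_yearly_cents)]
    return NetBudget(yearly_differences_cents=diffs, total_difference_cents=sum(diffs))


def component_share(label: str, table: BudgetTable) -> tuple[float, int]:
    """A component's share of the cohort's multi-year grand total.

    Returns (fraction, percent rounded to the nearest integer).
    """
    component = table.component(label)  # KeyError on unknown label
    grand = sum(table.canonical_yearly_totals_cents())
    if grand == 0:
        raise ValueError("table grand total is zero; share undefined")
    fraction = component.total_cents / grand
    return fraction, int(round(fraction * 100.0))


def budget_table_from_strategy(
    tree, strategy_name: str, cohort_size: float, n_years: int
) -> BudgetTable:
    """Model-driven mode: build a budget table from the decision tree itself.

    Each branch contributes ``probability * cohort_size`` persons and its
    Markov model's undiscounted yearly cost profile scaled likewise; the
    strategy's fixed per-person cost becomes a separate screening line.  The
    same staggering ops then apply to model-driven and fixture tables alike.
    """
    from .markov_engine import run_cohort  # local import avoids a cycle

    strategy = tree.strategy(strategy_name)
    components: list[BudgetComponent] = []
    if strategy.fixed_per_person_cost:
        yearly = [strategy.fixed_per_person_cost * cohort_size] + [0.0] * (n_years - 1)
        components.append(BudgetComponent.from_dollars("Screening", cohort_size, yearly))
    for branch in strategy.branches:
        if branch.model is None:
            continue
        horizon = branch.model.cycle_length_years * round(
            n_years / branch.model.cycle_length_years
        )
        _, out = run_cohort(branch.model, horizon, 0.0)
        scale = branch.probability * cohort_size
        yearly = [c * scale for c in out.yearly_undiscounted_costs[:n_years]]
        yearly += [0.0] * (n_years - len(yearly))
        components.append(
            BudgetComponent.from_dollars(
                branch.label or branch.model.label, scale, yearly
            )
        )
    return BudgetTable(components=components, cohort_size=cohort_size, program_label=strategy_name)
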