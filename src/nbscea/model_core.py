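"""Domain types and the model-spec schema for decision-tree / Markov cost-effectiveness models.

The modelling unit is a :class:`DecisionTree`: two or more screening/treatment
strategies, each splitting a birth cohort over chance branches (disease
incidences) that lead into Markov cohort models.  State utilities and running
costs are specified *per year* and scaled by the cycle length internally, so
models with different cycle lengths (six-month SMA cycles, three-month SCID
cycles) share one configuration convention.

Outcomes are disease-attributable: a branch may carry ``model: null``, meaning
the people on it (e.g., unaffected newborns) accrue no cost, QALYs or
life-years.  Strategy-level expectations are therefore "per newborn screened"
in the sense used for rare-disease screening programmes.
"""

from __future__ import annotations

import copy
import hashlib
import re
from dataclasses import dataclass, field
from typing import Any, Iterator

import yaml

PROB_TOL = 1e-9  # tolerance on row / distribution sums


class ModelSpecError(ValueError):
    """A model-spec document failed to parse or validate."""


class PathError(KeyError):
    """A parameter path could not be resolved against a tree."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HealthState:
    """One Markov health state.

    ``annual_utility`` is the QALY weight accrued per year alive in the state
    (dimensionless, in [-1, 1]); ``annual_cost`` the running cost per year in
    the state (nominal currency units).  A death state must be absorbing and
    carries zero utility and zero cost.
    """

    id: str
    name: str = ""
    annual_utility: float = 0.0
    annual_cost: float = 0.0
    is_absorbing: bool = False
    is_death: bool = False


@dataclass
class OneOffCost:
    """A per-patient event cost charged at ``time_years`` to the fraction of
    the cohort alive (non-death occupancy) at that time — e.g., a single gene
    therapy infusion at entry, or an HSCT."""

    time_years: float
    amount: float
    label: str = ""


@dataclass
class MarkovModel:
    """A time-homogeneous Markov cohort model: the simulable unit.

    ``transition_matrix`` is row-stochastic per cycle (row i -> column j,
    ordered as ``states``); the matrix is constant over time.
    """

    label: str
    cycle_length_years: float
    states: list[HealthState]
    transition_matrix: list[list[float]]
    initial_distribution: list[float]
    one_off_costs: list[OneOffCost] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state_id: str) -> int:
        for i, s in enumerate(self.states):
            if s.id == state_id:
                return i
        raise KeyError(f"no state with id {state_id!r} in model {self.label!r}")

    def death_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if s.is_death]


@dataclass
class Outcome:
    """Accumulated per-person totals from one cohort run (or an expectation
    over branches): discounted and undiscounted cost / QALY / LY, plus the
    undiscounted cost profile by calendar year (year 0 = first year)."""

    discounted_cost: float = 0.0
    discounted_qaly: float = 0.0
    discounted_ly: float = 0.0
    undiscounted_cost: float = 0.0
    undiscounted_qaly: float = 0.0
    undiscounted_ly: float = 0.0
    yearly_undiscounted_costs: list[float] = field(default_factory=list)

    def scaled(self, factor: float) -> "Outcome":
        return Outcome(
            self.discounted_cost * factor,
            self.discounted_qaly * factor,
            self.discounted_ly * factor,
            self.undiscounted_cost * factor,
            self.undiscounted_qaly * factor,
            self.undiscounted_ly * factor,
            [c * factor for c in self.yearly_undiscounted_costs],
        )

    def __add__(self, other: "Outcome") -> "Outcome":
        n = max(len(self.yearly_undiscounted_costs), len(other.yearly_undiscounted_costs))
        yearly = [0.0] * n
        for src in (self.yearly_undiscounted_costs, other.yearly_undiscounted_costs):
            for i, c in enumerate(src):
                yearly[i] += c
        return Outcome(
            self.discounted_cost + other.discounted_cost,
            self.discounted_qaly + other.discounted_qaly,
            self.discounted_ly + other.discounted_ly,
            self.undiscounted_cost + other.undiscounted_cost,
            self.undiscounted_qaly + other.undiscounted_qaly,
            self.undiscounted_ly + other.undiscounted_ly,
            yearly,
        )


@dataclass
class ChanceBranch:
    """A chance branch of a strategy: probability (e.g., disease incidence)
    and the Markov model the people on the branch enter.  ``model`` may be
    ``None`` for a zero-outcome branch (unaffected newborns)."""

    probability: float
    model: MarkovModel | None
    label: str = ""


@dataclass
class Strategy:
    """A screening/treatment strategy: chance branches plus a fixed per-person
    cost charged at t=0 to everyone entering the strategy (the screening
    test)."""

    name: str
    branches: list[ChanceBranch]
    fixed_per_person_cost: float = 0.0


@dataclass
class DecisionTree:
    """Strategies, the annual discount rate and the time horizon."""

    strategies: list[Strategy]
    discount_rate_annual: float = 0.03
    horizon_years: float = 60.0

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def models(self) -> Iterator[MarkovModel]:
        for s in self.strategies:
            for b in s.branches:
                if b.model is not None:
                    yield b.model

    def config_hash(self) -> str:
        """SHA-256 of the canonical serialized form (used for sidecars and
        for asserting that sensitivity analyses restore the base case)."""
        return hashlib.sha256(dumps_spec(self).encode()).hexdigest()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == valid
        return self.ok


def validate_model(model: MarkovModel) -> ValidationReport:
    """Check every structural invariant of a MarkovModel; report, don't raise.

    Pure: never mutates its input, identical calls give identical reports.
    """
    v: list[str] = []
    n = model.n_states
    lbl = model.label

    if model.cycle_length_years <= 0:
        v.append(f"{lbl}: cycle_length_years must be positive")
    if len(model.transition_matrix) != n:
        v.append(f"{lbl}: transition matrix has {len(model.transition_matrix)} rows for {n} states")
    for i, row in enumerate(model.transition_matrix):
        if len(row) != n:
            v.append(f"{lbl}: transition row {i} has {len(row)} entries for {n} states")
            continue
        if any(p < -PROB_TOL or p > 1 + PROB_TOL for p in row):
            v.append(f"{lbl}: transition row {i} has entries outside [0, 1]")
        if abs(sum(row) - 1.0) > PROB_TOL:
            v.append(f"{lbl}: transition row {i} sums to {sum(row)!r}, not 1")
    if len(model.initial_distribution) != n:
        v.append(f"{lbl}: initial distribution length {len(model.initial_distribution)} != {n}")
    else:
        if abs(sum(model.initial_distribution) - 1.0) > PROB_TOL:
            v.append(f"{lbl}: initial distribution sums to {sum(model.initial_distribution)!r}, not 1")
        if any(p < -PROB_TOL for p in model.initial_distribution):
            v.append(f"{lbl}: initial distribution has negative entries")

    for i, s in enumerate(model.states):
        if not -1.0 <= s.annual_utility <= 1.0:
            v.append(f"{lbl}: state {s.id!r} utility {s.annual_utility} outside [-1, 1]")
        if s.is_death and not s.is_absorbing:
            v.append(f"{lbl}: death state {s.id!r} must be absorbing")
        if s.is_death and (s.annual_utility != 0 or s.annual_cost != 0):
            v.append(f"{lbl}: death state {s.id!r} must have zero utility and zero cost")
        if s.is_absorbing and i < len(model.transition_matrix) and len(model.transition_matrix[i]) == n:
            row = model.transition_matrix[i]
            if any(abs(p - (1.0 if j == i else 0.0)) > PROB_TOL for j, p in enumerate(row)):
                v.append(f"{lbl}: absorbing state {s.id!r} row is not an identity row")

    for ev in model.one_off_costs:
        if ev.time_years < 0:
            v.append(f"{lbl}: one-off cost {ev.label!r} at negative time {ev.time_years}")

    return ValidationReport(v)


def validate_tree(tree: DecisionTree) -> ValidationReport:
    v: list[str] = []
    if tree.discount_rate_annual < 0:
        v.append("discount_rate_annual must be >= 0")
    if tree.horizon_years <= 0:
        v.append("horizon_years must be > 0")
    if not tree.strategies:
        v.append("tree has no strategies")
    for s in tree.strategies:
        if s.fixed_per_person_cost < 0:
            v.append(f"strategy {s.name!r}: fixed_per_person_cost must be >= 0")
        total = sum(b.probability for b in s.branches)
        if abs(total - 1.0) > PROB_TOL:
            v.append(f"strategy {s.name!r}: branch probabilities sum to {total!r}, not 1")
        for b in s.branches:
            if not 0.0 <= b.probability <= 1.0:
                v.append(f"strategy {s.name!r}, branch {b.label!r}: probability outside [0, 1]")
            if b.model is not None:
                cyc = b.model.cycle_length_years
                if cyc > 0:
                    k = tree.horizon_years / cyc
                    if abs(k - round(k)) > 1e-9:
                        v.append(
                            f"horizon {tree.horizon_years} y is not an integer multiple of "
                            f"cycle length {cyc} y (model {b.model.label!r})"
                        )
                v.extend(validate_model(b.model).violations)
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# model-spec schema (YAML / JSON documents)
# ---------------------------------------------------------------------------

_TREE_KEYS = {"discount_rate_annual", "horizon_years", "strategies"}
_STRATEGY_KEYS = {"name", "fixed_per_person_cost", "branches"}
_BRANCH_KEYS = {"probability", "model", "label"}
_MODEL_KEYS = {
    "label",
    "cycle_length_years",
    "states",
    "transition_matrix",
    "initial_distribution",
    "one_off_costs",
}
_STATE_KEYS = {"id", "name", "annual_utility", "annual_cost", "is_absorbing", "is_death"}
_ONEOFF_KEYS = {"time_years", "amount", "label"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    if not isinstance(mapping, dict):
        raise ModelSpecError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ModelSpecError(f"{context}: unknown key(s) {sorted(unknown)} (allowed: {sorted(allowed)})")


def _state_from_dict(d: dict, context: str) -> HealthState:
    _check_keys(d, _STATE_KEYS, context)
    if "id" not in d:
        raise ModelSpecError(f"{context}: state missing required key 'id'")
    return HealthState(
        id=str(d["id"]),
        name=str(d.get("name", "")),
        annual_utility=float(d.get("annual_utility", 0.0)),
        annual_cost=float(d.get("annual_cost", 0.0)),
        is_absorbing=bool(d.get("is_absorbing", False)),
        is_death=bool(d.get("is_death", False)),
    )


def _model_from_dict(d: dict, context: str) -> MarkovModel:
    _check_keys(d, _MODEL_KEYS, context)
    for key in ("cycle_length_years", "states", "transition_matrix", "initial_distribution"):
        if key not in d:
            raise ModelSpecError(f"{context}: model missing required key {key!r}")
    states = [_state_from_dict(s, f"{context}.states[{i}]") for i, s in enumerate(d["states"])]
    return MarkovModel(
        label=str(d.get("label", "")),
        cycle_length_years=float(d["cycle_length_years"]),
        states=states,
        transition_matrix=[[float(p) for p in row] for row in d["transition_matrix"]],
        initial_distribution=[float(p) for p in d["initial_distribution"]],
        one_off_costs=[
            OneOffCost(
                time_years=float(_checked(e, _ONEOFF_KEYS, f"{context}.one_off_costs[{i}]")["time_years"]),
                amount=float(e["amount"]),
                label=str(e.get("label", "")),
            )
            for i, e in enumerate(d.get("one_off_costs") or [])
        ],
    )


def _checked(d: dict, allowed: set[str], context: str) -> dict:
    _check_keys(d, allowed, context)
    return d


def tree_from_dict(doc: dict) -> DecisionTree:
    """Build a DecisionTree from a plain mapping, rejecting unknown keys."""
    _check_keys(doc, _TREE_KEYS, "top level")
    if "strategies" not in doc:
        raise ModelSpecError("top level: missing required key 'strategies'")
    strategies = []
    for i, sd in enumerate(doc["strategies"]):
        ctx = f"strategies[{i}]"
        _check_keys(sd, _STRATEGY_KEYS, ctx)
        if "name" not in sd or "branches" not in sd:
            raise ModelSpecError(f"{ctx}: strategy requires 'name' and 'branches'")
        branches = []
        for j, bd in enumerate(sd["branches"]):
            bctx = f"{ctx}.branches[{j}]"
            _check_keys(bd, _BRANCH_KEYS, bctx)
            if "probability" not in bd or "model" not in bd:
                raise ModelSpecError(f"{bctx}: branch requires 'probability' and 'model'")
            model = None if bd["model"] is None else _model_from_dict(bd["model"], f"{bctx}.model")
            branches.append(
                ChanceBranch(probability=float(bd["probability"]), model=model, label=str(bd.get("label", "")))
            )
        strategies.append(
            Strategy(
                name=str(sd["name"]),
                branches=branches,
                fixed_per_person_cost=float(sd.get("fixed_per_person_cost", 0.0)),
            )
        )
    return DecisionTree(
        strategies=strategies,
        discount_rate_annual=float(doc.get("discount_rate_annual", 0.03)),
        horizon_years=float(doc.get("horizon_years", 60.0)),
    )


def tree_to_dict(tree: DecisionTree) -> dict:
    def state_d(s: HealthState) -> dict:
        return {
            "id": s.id,
            "name": s.name,
            "annual_utility": s.annual_utility,
            "annual_cost": s.annual_cost,
            "is_absorbing": s.is_absorbing,
            "is_death": s.is_death,
        }

    def model_d(m: MarkovModel | None) -> dict | None:
        if m is None:
            return None
        return {
            "label": m.label,
            "cycle_length_years": m.cycle_length_years,
            "states": [state_d(s) for s in m.states],
            "transition_matrix": [[float(p) for p in row] for row in m.transition_matrix],
            "initial_distribution": [float(p) for p in m.initial_distribution],
            "one_off_costs": [
                {"time_years": e.time_years, "amount": e.amount, "label": e.label} for e in m.one_off_costs
            ],
        }

    return {
        "discount_rate_annual": tree.discount_rate_annual,
        "horizon_years": tree.horizon_years,
        "strategies": [
            {
                "name": s.name,
                "fixed_per_person_cost": s.fixed_per_person_cost,
                "branches": [
                    {"probability": b.probability, "label": b.label, "model": model_d(b.model)}
                    for b in s.branches
                ],
            }
            for s in tree.strategies
        ],
    }


def loads_spec(text: str) -> DecisionTree:
    """Parse a YAML/JSON model-spec document and return a validated tree."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # report the line of the problem
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ModelSpecError(f"cannot parse model spec{where}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelSpecError("model spec must be a mapping at the top level")
    tree = tree_from_dict(doc)
    report = validate_tree(tree)
    if not report.ok:
        raise ModelSpecError("invalid model spec:\n  - " + "\n  - ".join(report.violations))
    return tree


def load_spec(path) -> DecisionTree:
    with open(path, "r", encoding="utf-8") as fh:
        return loads_spec(fh.read())


def dumps_spec(tree: DecisionTree) -> str:
    return yaml.safe_dump(tree_to_dict(tree), sort_keys=True, default_flow_style=None)


def write_spec(tree: DecisionTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_spec(tree))


# ---------------------------------------------------------------------------
# parameter paths (shared by the PSA and one-way SA layers)
# ---------------------------------------------------------------------------
#
# Grammar: dot-separated attribute names, each optionally indexed, e.g.
#   strategies['Future NBS'].branches['screened_sma'].model.states['presym'].annual_cost
#   strategies[0].branches[1].probability
#   strategies[0].branches[0].model.transition_matrix[2][5]
# String indices match an element's `name`, `label` or `id` field.

_TOKEN_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)((?:\[[^\]]+\])*)$")
_INDEX_RE = re.compile(r"\[([^\]]+)\]")


def _parse_index(raw: str):
    raw = raw.strip()
    if len(raw) >= 2 and raw[0] in "'\"" and raw[-1] == raw[0]:
        return raw[1:-1]
    try:
        return int(raw)
    except ValueError:
        raise PathError(f"bad index {raw!r}: must be an integer or a quoted name")


def _parse_path(path: str) -> list[tuple[str, Any]]:
    steps: list[tuple[str, Any]] = []
    for token in path.split("."):
        m = _TOKEN_RE.match(token.strip())
        if not m:
            raise PathError(f"cannot parse path segment {token!r} in {path!r}")
        steps.append(("attr", m.group(1)))
        for raw in _INDEX_RE.findall(m.group(2)):
            steps.append(("item", _parse_index(raw)))
    return steps


def _resolve_key(container, key, path: str):
    """Turn a string index into a positional one by matching name/label/id."""
    if isinstance(key, str):
        for i, element in enumerate(container):
            for attr in ("name", "label", "id"):
                if getattr(element, attr, None) == key:
                    return i
        raise PathError(f"no element named {key!r} along {path!r}")
    return key


def _step_into(obj, kind: str, key, path: str):
    if kind == "attr":
        if not hasattr(obj, key):
            raise PathError(f"cannot resolve attribute {key!r} along {path!r}")
        return getattr(obj, key)
    idx = _resolve_key(obj, key, path)
    try:
        return obj[idx]
    except (IndexError, TypeError) as exc:
        raise PathError(f"cannot index with {key!r} along {path!r}") from exc


def _locate(root, path: str):
    steps = _parse_path(path)
    obj = root
    for kind, key in steps[:-1]:
        obj = _step_into(obj, kind, key, path)
    return obj, steps[-1]


def get_parameter(root, path: str) -> float:
    parent, (kind, key) = _locate(root, path)
    return _step_into(parent, kind, key, path)


def set_parameter(root, path: str, value: float) -> None:
    """Set a scalar parameter in place (callers copy the tree first when the
    base case must survive)."""
    parent, (kind, key) = _locate(root, path)
    if kind == "attr":
        if not hasattr(parent, key):
            raise PathError(f"cannot resolve attribute {key!r} along {path!r}")
        setattr(parent, key, value)
    else:
        idx = _resolve_key(parent, key, path)
        try:
            parent[idx] = value
        except (IndexError, TypeError) as exc:
            raise PathError(f"cannot index with {key!r} along {path!r}") from exc


def copy_tree(tree: DecisionTree) -> DecisionTree:
    return copy.deepcopy(tree)


def rebalance_residual_branches(tree: DecisionTree) -> bool:
    """Reset each strategy's zero-outcome (``model=None``) branch to the
    probability remainder of its modelled siblings.

    Sensitivity analyses vary incidence probabilities directly; the residual
    branch (unaffected newborns) absorbs the complement so branch
    probabilities keep summing to one.  Returns False when a remainder went
    negative (the caller rejects that draw); strategies without a residual
    branch are left untouched.
    """
    ok = True
    for strategy in tree.strategies:
        residuals = [b for b in strategy.branches if b.model is None]
        if len(residuals) != 1:
            continue
        remainder = 1.0 - sum(b.probability for b in strategy.branches if b.model is not None)
        if remainder < -PROB_TOL:
            ok = False
        residuals[0].probability = remainder
    return ok
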