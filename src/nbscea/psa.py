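"""Probabilistic sensitivity analysis (PSA).

Parameters are given sampling distributions (beta for probabilities and
utilities, gamma for costs — the standard HTA choices for bounded and
nonnegative quantities), the decision tree is rebuilt and re-evaluated for
every Monte-Carlo draw, and the resulting cloud of incremental (Δcost, ΔQALY,
ΔLY) points supports cost-effectiveness planes, percentile confidence
intervals, the proportion cost-effective at a willingness-to-pay threshold,
and the cost-effectiveness acceptability curve (CEAC).

Distributions are parameterized by method of moments from (mean, spread).
Sampled transition probabilities target off-diagonal cells; the diagonal is
recomputed as the remainder, and draws that push the remainder negative are
rejected and resampled (counted on the result, never silently clamped).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import (
    DecisionTree,
    copy_tree,
    get_parameter,
    rebalance_residual_branches,
    set_parameter,
)
from .cea import DOMINANT, DOMINATED, IncrementalResult, expected_values, incremental

_MAX_RESAMPLE = 1000


@dataclass
class ParameterSpec:
    """One uncertain parameter: a path into the model spec plus a sampling
    distribution.

    ``spread`` is a standard error for beta/gamma/lognormal, the (low, high)
    pair for uniform, and ignored for fixed.
    """

    name: str
    distribution: str  # beta | gamma | lognormal | uniform | fixed
    mean: float
    spread: float | tuple[float, float] | None = None


@dataclass
class PSAResult:
    """The iteration cloud: one (Δcost, ΔQALY, ΔLY) row per draw."""

    iterations: np.ndarray  # (n_iter, 3)
    seed: int
    n_iter: int
    n_resampled: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return self.iterations[:, 0]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.iterations[:, 1]

    @property
    def delta_ly(self) -> np.ndarray:
        return self.iterations[:, 2]


def _beta_params(mean: float, se: float) -> tuple[float, float]:
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta requires mean in (0, 1), got {mean}")
    if se <= 0 or se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"beta moment matching infeasible: need 0 < se^2 < mean(1-mean), got mean={mean}, se={se}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def _gamma_params(mean: float, se: float) -> tuple[float, float]:
    if mean <= 0 or se <= 0:
        raise ValueError(f"gamma requires positive mean and se, got mean={mean}, se={se}")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def _lognormal_params(mean: float, se: float) -> tuple[float, float]:
    if mean <= 0 or se <= 0:
        raise ValueError(f"lognormal requires positive mean and se, got mean={mean}, se={se}")
    sigma2 = math.log(1.0 + (se / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _draw(spec: ParameterSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    dist = spec.distribution
    if dist == "fixed":
        return np.full(size, spec.mean)
    if dist == "uniform":
        if not (isinstance(spec.spread, (tuple, list)) and len(spec.spread) == 2):
            raise ValueError(f"uniform spread must be a (low, high) pair, got {spec.spread!r}")
        low, high = spec.spread
        if low > high:
            raise ValueError(f"uniform requires low <= high, got ({low}, {high})")
        return rng.uniform(low, high, size)
    if spec.spread is None:
        raise ValueError(f"distribution {dist!r} requires a spread (standard error)")
    se = float(spec.spread)
    if dist == "beta":
        a, b = _beta_params(spec.mean, se)
        return rng.beta(a, b, size)
    if dist == "gamma":
        shape, scale = _gamma_params(spec.mean, se)
        return rng.gamma(shape, scale, size)
    if dist == "lognormal":
        mu, sigma = _lognormal_params(spec.mean, se)
        return rng.lognormal(mu, sigma, size)
    raise ValueError(f"unknown distribution {dist!r}")


def sample_parameters(
    specs: Sequence[ParameterSpec], n_iter: int, seed: int
) -> np.ndarray:
    """Draw an ``(n_iter, n_params)`` matrix, reproducible given ``seed``."""
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_iter, len(specs)))
    for j, spec in enumerate(specs):
        draws[:, j] = _draw(spec, rng, n_iter)
    return draws


_MATRIX_CELL_RE = re.compile(r"^(?P<model>.*transition_matrix)\[(?P<row>\d+)\]\[(?P<col>\d+)\]$")


def _matrix_rows_touched(specs: Sequence[ParameterSpec]) -> list[tuple[str, int, int]]:
    """(matrix path, row, col) for every spec that samples a transition cell."""
    touched = []
    for spec in specs:
        m = _MATRIX_CELL_RE.match(spec.name.strip())
        if m:
            row, col = int(m.group("row")), int(m.group("col"))
            if row == col:
                raise ValueError(
                    f"sampled transition cell {spec.name!r} is on the diagonal; sample "
                    "off-diagonal cells — the diagonal is recomputed as the remainder"
                )
            touched.append((m.group("model"), row, col))
    return touched


def _rebalance_rows(tree: DecisionTree, touched) -> bool:
    """Reset diagonals of sampled rows to the off-diagonal remainder.

    Returns False when a remainder went negative (caller resamples).
    """
    for matrix_path, row in {(p, r) for p, r, _ in touched}:
        row_list = get_parameter(tree, f"{matrix_path}[{row}]")
        off = sum(p for j, p in enumerate(row_list) if j != row)
        if off > 1.0 + 1e-12:
            return False
        row_list[row] = 1.0 - off
    return True


def run_psa(
    tree: DecisionTree,
    specs: Sequence[ParameterSpec],
    n_iter: int,
    seed: int,
    intervention: str,
    comparator: str,
) -> PSAResult:
    """Rebuild and re-evaluate the tree per draw; collect incremental deltas."""
    tree.strategy(intervention)  # raise early on bad names
    tree.strategy(comparator)
    rng = np.random.default_rng(seed)
    iterations = np.empty((n_iter, 3))
    n_resampled = 0
    touched = _matrix_rows_touched(specs)
    for it in range(n_iter):
        for attempt in range(_MAX_RESAMPLE):
            draw = np.array([_draw(s, rng, 1)[0] for s in specs])
            candidate = copy_tree(tree)
            for spec, value in zip(specs, draw):
                set_parameter(candidate, spec.name, float(value))
            if _rebalance_rows(candidate, touched) and rebalance_residual_branches(candidate):
                break
            n_resampled += 1
        else:
            raise RuntimeError(
                f"iteration {it}: {_MAX_RESAMPLE} consecutive draws left a transition "
                "row with a negative diagonal remainder; distributions are too wide"
            )
        ev = expected_values(candidate)
        inc = incremental(ev[intervention], ev[comparator])
        iterations[it] = (inc.delta_cost, inc.delta_qaly, inc.delta_ly)
    return PSAResult(iterations=iterations, seed=seed, n_iter=n_iter, n_resampled=n_resampled)


def proportion_cost_effective(result: PSAResult, wtp: float) -> float:
    """Fraction of iterations with positive net monetary benefit at ``wtp``.

    ``wtp * ΔQALY - Δcost > 0`` automatically counts the win-win quadrant
    (more health, cost saving) at every threshold.
    """
    if result.n_iter == 0:
        raise ValueError("PSA result is empty")
    if math.isinf(wtp):  # documented limit: fraction with positive QALY gain
        return float(np.mean(result.delta_qaly > 0))
    nmb = wtp * result.delta_qaly - result.delta_cost
    return float(np.mean(nmb > 0))


def _endpoint_icer(dc: float, dq: float) -> float | str:
    if dc < 0 and dq > 0:
        return DOMINANT
    if dc > 0 and dq < 0:
        return DOMINATED
    if dq == 0:
        return DOMINANT if dc < 0 else DOMINATED if dc > 0 else 0.0
    return dc / dq


def percentile_ci(
    result: PSAResult, level: float = 0.95, wtp: float = 35_000.0
) -> dict:
    """Percentile confidence intervals of the incremental deltas, plus an ICER
    interval.

    Delta intervals are plain 2.5/97.5 percentiles.  Because raw cost/effect
    ratios are not monotone across quadrants, the ICER interval is taken from
    the iterations ranked by net monetary benefit at the reporting ``wtp``:
    the favourable endpoint (high NMB) is reported first, and an endpoint in
    the win-win quadrant is reported as the label ``"dominant"`` rather than
    as a negative ratio.
    """
    n = result.n_iter
    if n < 40:
        raise ValueError(f"need at least 40 iterations for a 95% percentile CI, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    lo_pct = 100.0 * (1.0 - level) / 2.0
    hi_pct = 100.0 - lo_pct
    out = {}
    for key, values in (
        ("delta_cost", result.delta_cost),
        ("delta_qaly", result.delta_qaly),
        ("delta_ly", result.delta_ly),
    ):
        lo, hi = np.percentile(values, [lo_pct, hi_pct])
        out[key] = (float(lo), float(hi))

    nmb = wtp * result.delta_qaly - result.delta_cost
    order = np.argsort(nmb, kind="stable")
    k_lo = int(math.floor(lo_pct / 100.0 * (n - 1)))
    k_hi = int(math.ceil(hi_pct / 100.0 * (n - 1)))
    worst = result.iterations[order[k_lo]]
    best = result.iterations[order[k_hi]]
    out["icer_qaly"] = (
        _endpoint_icer(best[0], best[1]),
        _endpoint_icer(worst[0], worst[1]),
    )
    return out


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over an ascending WTP grid."""
    grid = list(wtp_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("wtp_grid must be sorted ascending")
    return [(float(w), proportion_cost_effective(result, w)) for w in grid]
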