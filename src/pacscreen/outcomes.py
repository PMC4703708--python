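"""Life-expectancy outcomes, parameter sweeps, and threshold location.

The primary outcome is undiscounted life expectancy past age 20, computed from
the alive-occupancy trajectory with a half-cycle (trapezoid) correction, and
reported as *net days* gained versus no screening (365.25 days/year).
One-way sweeps vary a single test, management, or strategy parameter over a
grid; thresholds are located by linear interpolation between the bracketing
grid points where net benefit changes sign (zero-crossing versus no screening)
or where two strategies' difference changes sign (crossover).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .natural_history import CohortTrace, NaturalHistoryParams, evolve
from .screening import ManagementPolicy, ScreeningStrategy, TestPerformance

__all__ = [
    "EvalContext",
    "StrategyComparison",
    "SweepCurve",
    "ThresholdReport",
    "life_expectancy",
    "net_days",
    "compare_strategies",
    "sweep_one_way",
    "find_zero_crossing",
    "find_crossover",
    "locate_threshold",
    "optimal_start_age",
    "sweep_two_way",
]

DAYS_PER_YEAR = 365.25

#: legal ranges for sweepable parameters
_PARAM_RANGES = {
    "sensitivity": (0.0, 1.0),
    "specificity": (0.0, 1.0),
    "surgical_mortality": (0.0, 1.0),
    "start_age": (20.0, 100.0),
    "interval_years": (1.0 / 12.0, 80.0),
}


def life_expectancy(trace: CohortTrace, cycles_per_year: int | None = None) -> float:
    """Life expectancy past age 20 in years, trapezoid half-cycle corrected."""
    cpy = cycles_per_year or trace.cycles_per_year
    alive = trace.alive
    le = (alive[:-1] + alive[1:]).sum() / 2.0 / cpy
    return float(le)


@dataclass
class EvalContext:
    """A fully specified model context: natural history, mortality, test and
    management.  Strategies are evaluated against this shared context so that
    net-benefit comparisons are like-for-like."""

    params: NaturalHistoryParams
    mortality: object
    test: TestPerformance
    policy: ManagementPolicy
    cycles_per_year: int = 12
    label: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def run(self, strategy: ScreeningStrategy) -> CohortTrace:
        key = (strategy.mode, strategy.start_age, strategy.stop_age, strategy.interval_years)
        if key not in self._cache:
            self._cache[key] = evolve(
                self.params,
                self.mortality,
                strategy=strategy,
                test=self.test,
                policy=self.policy,
                cycles_per_year=self.cycles_per_year,
            )
        return self._cache[key]

    def with_(self, **kwargs) -> "EvalContext":
        ctx = replace(self, **kwargs)
        ctx._cache = {}
        return ctx


@dataclass(frozen=True)
class StrategyComparison:
    strategy: ScreeningStrategy
    life_expectancy_years: float
    net_days: float


@dataclass
class SweepCurve:
    """Net days versus a single swept parameter, per strategy."""

    parameter: str
    grid: np.ndarray
    net_days: dict[str, np.ndarray]
    context_label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("sweep grid must be strictly increasing")
        for lab, v in self.net_days.items():
            if len(v) != len(g):
                raise ValueError(f"curve {lab!r} length does not match grid")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": self.parameter, "value": x, "strategy": lab, "net_days": y}
            for lab, ys in self.net_days.items()
            for x, y in zip(self.grid, ys)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdReport:
    value: float
    kind: str  # "zero-crossing" | "crossover"
    bracket: tuple[float, float]
    interpolation: str = "linear"
    degenerate: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not (lo - 1e-12 <= self.value <= hi + 1e-12):
            raise ValueError("threshold must lie within its bracket")


def net_days(
    context: EvalContext,
    strategy: ScreeningStrategy,
    baseline: ScreeningStrategy | None = None,
) -> float:
    """Life-expectancy days gained by ``strategy`` versus no screening.

    Exactly zero for the no-screening strategy and for an inert test
    (sensitivity 0, specificity 1), for which the screened engine path
    reproduces the unscreened occupancy bitwise.
    """
    baseline = baseline or ScreeningStrategy.none()
    le_b = life_expectancy(context.run(baseline))
    le_s = life_expectancy(context.run(strategy))
    return (le_s - le_b) * DAYS_PER_YEAR


def compare_strategies(
    context: EvalContext, strategies: dict[str, ScreeningStrategy]
) -> pd.DataFrame:
    """One row per strategy with life expectancy and net days versus no screening."""
    le_b = life_expectancy(context.run(ScreeningStrategy.none()))
    rows = []
    for lab, strat in strategies.items():
        le = life_expectancy(context.run(strat))
        rows.append(
            {
                "strategy": lab,
                "life_expectancy_years": le,
                "net_days": (le - le_b) * DAYS_PER_YEAR if strat.mode != "none" else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _apply_parameter(
    context: EvalContext, strategy: ScreeningStrategy, name: str, value: float
):
    """Return (context, strategy) with the swept parameter set to ``value``."""
    if name == "sensitivity":
        return context.with_(test=replace(context.test, sensitivity=value)), strategy
    if name == "specificity":
        return context.with_(test=replace(context.test, specificity=value)), strategy
    if name == "surgical_mortality":
        return context.with_(policy=replace(context.policy, surgical_mortality=value)), strategy
    if name == "start_age":
        if strategy.mode == "one_time":
            return context, replace(strategy, start_age=value, stop_age=value)
        return context, replace(strategy, start_age=value)
    if name == "interval_years":
        return context, replace(strategy, interval_years=value)
    raise ValueError(f"unknown sweep parameter {name!r}")


def sweep_one_way(
    context: EvalContext,
    parameter: str,
    grid,
    strategies: dict[str, ScreeningStrategy],
) -> SweepCurve:
    """Evaluate net days for each strategy at every grid value of one parameter.

    The context is restored between points: each evaluation perturbs only the
    swept parameter.  Test/management sweeps share a single no-screening
    baseline (the baseline does not depend on them).
    """
    grid = np.asarray(grid, dtype=float)
    if parameter not in _PARAM_RANGES:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    lo, hi = _PARAM_RANGES[parameter]
    if np.any((grid < lo - 1e-9) | (grid > hi + 1e-9)):
        raise ValueError(f"grid for {parameter!r} must lie within [{lo}, {hi}]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    grid = np.clip(grid, lo, hi)  # absorb float-arithmetic overshoot

    curves = {lab: np.empty(len(grid)) for lab in strategies}
    for j, x in enumerate(grid):
        for lab, strat in strategies.items():
            ctx_j, strat_j = _apply_parameter(context, strat, parameter, float(x))
            # reuse the parent context cache for the baseline arm
            base_trace = context.run(ScreeningStrategy.none())
            le_b = life_expectancy(base_trace)
            le_s = life_expectancy(ctx_j.run(strat_j))
            curves[lab][j] = (le_s - le_b) * DAYS_PER_YEAR
    return SweepCurve(parameter, grid, curves, context_label=context.label)


def _sign_change_thresholds(grid: np.ndarray, y: np.ndarray, kind: str) -> list[ThresholdReport]:
    reports: list[ThresholdReport] = []
    if np.allclose(y, 0.0, atol=1e-12):
        return [
            ThresholdReport(
                value=float(grid[0]),
                kind=kind,
                bracket=(float(grid[0]), float(grid[-1])),
                degenerate=True,
            )
        ]
    for i in range(len(grid) - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 == 0.0:
            reports.append(
                ThresholdReport(float(grid[i]), kind, (float(grid[i]), float(grid[i])))
            )
        elif y0 * y1 < 0:
            x = grid[i] + y0 * (grid[i + 1] - grid[i]) / (y0 - y1)
            reports.append(
                ThresholdReport(float(x), kind, (float(grid[i]), float(grid[i + 1])))
            )
    if len(y) and y[-1] == 0.0 and not np.allclose(y, 0.0, atol=1e-12):
        reports.append(
            ThresholdReport(float(grid[-1]), kind, (float(grid[-1]), float(grid[-1])))
        )
    return reports


def find_zero_crossing(curve: SweepCurve, strategy: str) -> list[ThresholdReport]:
    """All parameter values where a strategy's net benefit changes sign.

    Linear interpolation between the bracketing grid points; empty list if the
    curve never changes sign.
    """
    if len(curve.grid) < 2:
        raise ValueError("zero-crossing search needs at least 2 grid points")
    return _sign_change_thresholds(curve.grid, np.asarray(curve.net_days[strategy]), "zero-crossing")


def find_crossover(
    curve_a: SweepCurve, curve_b: SweepCurve, strategy_a: str | None = None,
    strategy_b: str | None = None,
) -> list[ThresholdReport]:
    """Parameter values where strategy A stops beating strategy B.

    Accepts either two single-strategy curves or one curve passed twice with
    the two strategy labels.  An identically-zero difference is reported as a
    single degenerate threshold.
    """
    strategy_a = strategy_a or next(iter(curve_a.net_days))
    strategy_b = strategy_b or next(iter(curve_b.net_days))
    if not np.array_equal(curve_a.grid, curve_b.grid):
        raise ValueError("crossover requires identical grids")
    diff = np.asarray(curve_a.net_days[strategy_a]) - np.asarray(curve_b.net_days[strategy_b])
    return _sign_change_thresholds(curve_a.grid, diff, "crossover")


def locate_threshold(
    context: EvalContext,
    parameter: str,
    strategy: ScreeningStrategy,
    lo: float,
    hi: float,
    coarse_step: float,
    refine_step: float,
    versus: ScreeningStrategy | None = None,
) -> list[ThresholdReport]:
    """Coarse sweep, then a refined sweep inside each sign-change bracket.

    With ``versus`` set, locates crossover thresholds of strategy minus
    ``versus``; otherwise zero-crossings versus no screening.
    """

    def evaluate(grid: np.ndarray) -> np.ndarray:
        strategies = {"a": strategy} if versus is None else {"a": strategy, "b": versus}
        curve = sweep_one_way(context, parameter, grid, strategies)
        y = np.asarray(curve.net_days["a"])
        if versus is not None:
            y = y - np.asarray(curve.net_days["b"])
        return y

    kind = "zero-crossing" if versus is None else "crossover"
    coarse = np.round(np.arange(lo, hi + coarse_step / 2, coarse_step), 12)
    y = evaluate(coarse)
    reports = []
    for rep in _sign_change_thresholds(coarse, y, kind):
        if rep.degenerate or rep.bracket[0] == rep.bracket[1]:
            reports.append(rep)
            continue
        b0, b1 = rep.bracket
        fine = np.round(np.arange(b0, b1 + refine_step / 2, refine_step), 12)
        if len(fine) < 2:
            reports.append(rep)
            continue
        reports.extend(_sign_change_thresholds(fine, evaluate(fine), kind))
    return reports


def optimal_start_age(
    context: EvalContext,
    mode: str,
    ages=range(30, 71),
    stop_age: float = 80.0,
    interval_years: float = 1.0,
) -> tuple[int, float]:
    """Start age maximizing net days on an integer-year grid (ties go younger)."""
    best_age, best_nd = None, -np.inf
    baseline = context.run(ScreeningStrategy.none())
    le_b = life_expectancy(baseline)
    for a in ages:
        if mode == "one_time":
            strat = ScreeningStrategy.one_time(float(a))
        else:
            strat = ScreeningStrategy(
                mode="interval",
                start_age=float(a),
                stop_age=max(float(a), stop_age),
                interval_years=interval_years,
            )
        nd = (life_expectancy(context.run(strat)) - le_b) * DAYS_PER_YEAR
        if nd > best_nd:  # strict: first (youngest) age wins ties
            best_age, best_nd = int(a), float(nd)
    return best_age, best_nd


def sweep_two_way(
    context: EvalContext,
    surgical_mortality_grid,
    specificity_grid,
    strategies: dict[str, ScreeningStrategy],
) -> pd.DataFrame:
    """Winner map over a surgical-mortality x specificity grid.

    Each cell holds the label of the strategy with maximal net days;
    no screening (label ``"none"``, net days 0) is always a contender.
    """
    sm_grid = np.asarray(surgical_mortality_grid, dtype=float)
    sp_grid = np.asarray(specificity_grid, dtype=float)
    winners = np.empty((len(sm_grid), len(sp_grid)), dtype=object)
    for i, sm in enumerate(sm_grid):
        for j, sp in enumerate(sp_grid):
            ctx = context.with_(
                policy=replace(context.policy, surgical_mortality=float(sm)),
                test=replace(context.test, specificity=float(sp)),
            )
            best_lab, best_nd = "none", 0.0
            for lab, strat in strategies.items():
                nd = net_days(ctx, strat)
                if nd > best_nd:
                    best_lab, best_nd = lab, nd
            winners[i, j] = best_lab
    return pd.DataFrame(winners, index=sm_grid, columns=sp_grid)
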