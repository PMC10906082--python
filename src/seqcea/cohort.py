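"""Six-state semi-Markov cohort engine for treatment sequencing.

States: four successive treatment lines, best supportive care (BSC), death.
Progression risk depends on time since entering the current line, so each
living state is stratified into tunnel strata indexed by cycles-in-state.
Within a cycle, background (all-cause) mortality is applied first and the
progression probability is scaled by the surviving fraction; in BSC the
per-cycle death probability is the larger of the BSC overall-survival hazard
and background mortality, so BSC patients never die more slowly than the
general population.

Costs are charged at the beginning of each cycle (no half-cycle correction)
and both costs and utilities are discounted with the same annual factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ParametricSurvival, transition_probability

__all__ = [
    "AdverseEvent",
    "LineSpec",
    "BSCSpec",
    "StrategyDefinition",
    "LifeTable",
    "ModelSettings",
    "CohortTrace",
    "monthly_mortality",
    "cycle_transition",
    "run_cohort",
    "accumulate",
]


@dataclass(frozen=True)
class AdverseEvent:
    """A grade >=3 adverse event charged once, on entry into the line."""

    name: str
    incidence: float
    cost: float
    disutility: float  # QALY decrement, >= 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"incidence of {self.name!r} must lie in [0, 1]")
        if self.cost < 0 or self.disutility < 0:
            raise ValueError(f"cost/disutility of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class LineSpec:
    """One treatment line: PFS law, utility, per-cycle cost, AE profile."""

    name: str
    pfs_model: ParametricSurvival
    utility: float
    cycle_cost: float
    ae_profile: tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError(f"utility of line {self.name!r} must lie in [0, 1]")
        if self.cycle_cost < 0:
            raise ValueError(f"cycle cost of line {self.name!r} must be >= 0")
        object.__setattr__(self, "ae_profile", tuple(self.ae_profile))


@dataclass(frozen=True)
class BSCSpec:
    """Best supportive care: overall-survival law governs death."""

    os_model: ParametricSurvival
    utility: float
    cycle_cost: float
    ae_profile: tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError("BSC utility must lie in [0, 1]")
        if self.cycle_cost < 0:
            raise ValueError("BSC cycle cost must be >= 0")
        object.__setattr__(self, "ae_profile", tuple(self.ae_profile))


@dataclass(frozen=True)
class StrategyDefinition:
    """An ordered sequence of four active treatment lines, then BSC, then death."""

    label: str
    lines: tuple[LineSpec, ...]
    bsc: BSCSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "lines", tuple(self.lines))
        if len(self.lines) != 4:
            raise ValueError("a strategy must define exactly 4 active lines")


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality probability by single year of age."""

    ages: np.ndarray
    annual_mortality: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.annual_mortality, dtype=float)
        if len(ages) != len(qx):
            raise ValueError("ages and probabilities must have equal length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("mortality probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "annual_mortality", qx)

    def annual_at(self, age: float) -> float:
        """Annual mortality for the year of age containing ``age``; ages past
        the table end are treated as certain death within the year."""
        a = int(math.floor(age))
        if a < self.ages[0]:
            raise ValueError(f"age {age} is below the life-table start {self.ages[0]}")
        if a > self.ages[-1]:
            return 1.0
        return float(self.annual_mortality[a - self.ages[0]])


@dataclass(frozen=True)
class ModelSettings:
    """Cycle length, discounting, horizon and start-age configuration."""

    cycle_length_months: float = 1.0
    annual_discount_rate: float = 0.03
    start_age: float = 58.0
    age_cap: float = 100.0
    wtp: float = 150_000.0
    horizon_months: float | None = None
    death_tol: float = 1e-6
    ae_timing: str = "line_entry"  # or "model_start"

    def __post_init__(self) -> None:
        if self.cycle_length_months <= 0:
            raise ValueError("cycle length must be positive")
        if self.ae_timing not in ("line_entry", "model_start"):
            raise ValueError("ae_timing must be 'line_entry' or 'model_start'")


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and new-entrant fractions for one strategy.

    ``occupancy`` rows (indexed by cycle) hold the start-of-cycle occupancy
    of line1..line4, bsc and death; ``entries`` holds the fraction entering
    each state at that cycle (stratum with zero cycles-in-state).
    """

    occupancy: pd.DataFrame
    entries: pd.DataFrame
    truncated: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.occupancy)


STATE_NAMES = ("line1", "line2", "line3", "line4", "bsc", "death")


def monthly_mortality(lt: LifeTable, age: float) -> float:
    """Convert the annual life-table probability at ``age`` to monthly:
    ``1 - (1 - q_annual)**(1/12)``."""
    q = lt.annual_at(age)
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


def cycle_transition(
    line: LineSpec,
    cycles_in_state: int,
    lt: LifeTable,
    age: float,
    cycle_length: float = 1.0,
) -> tuple[float, float, float]:
    """(p_stay, p_progress, p_die) for one cycle in an active line.

    Background death is applied first; the raw progression probability from
    the PFS law is scaled by the surviving fraction (competing-risk
    convention, documented here and nowhere else).
    """
    if cycles_in_state < 0:
        raise ValueError("cycles_in_state must be >= 0")
    p_die = 1.0 - (1.0 - lt.annual_at(age)) ** (cycle_length / 12.0)
    raw = transition_probability(
        line.pfs_model, (cycles_in_state + 1) * cycle_length, cycle_length
    )
    p_progress = raw * (1.0 - p_die)
    p_stay = 1.0 - p_progress - p_die
    return (p_stay, p_progress, p_die)


def _tp_array(model: ParametricSurvival, n: int, u: float) -> np.ndarray:
    """Vector of per-cycle transition probabilities for strata k=0..n-1."""
    k = np.arange(n, dtype=float)
    ls = model.log_survival((k + 1.0) * u)
    ls_prev = model.log_survival(k * u)
    with np.errstate(invalid="ignore"):
        p = -np.expm1(ls - ls_prev)
    p = np.where(np.isfinite(ls_prev), p, 1.0)
    return np.clip(p, 0.0, 1.0)


def run_cohort(
    strategy: StrategyDefinition, settings: ModelSettings, lt: LifeTable
) -> CohortTrace:
    """Propagate the cohort until (almost) everyone has died.

    The cohort starts 100% in line 1 with zero cycles-in-state.  The run
    stops when death occupancy exceeds ``1 - death_tol``, at the configured
    horizon, or at the age cap (default 100 years), whichever comes first;
    stopping with a living cohort logs a warning.
    """
    u = settings.cycle_length_months
    max_cycles = int(math.ceil((settings.age_cap - settings.start_age) * 12.0 / u))
    if settings.horizon_months is not None:
        max_cycles = min(max_cycles, int(math.ceil(settings.horizon_months / u)))
    living = list(STATE_NAMES[:5])
    models = {
        "line1": strategy.lines[0].pfs_model,
        "line2": strategy.lines[1].pfs_model,
        "line3": strategy.lines[2].pfs_model,
        "line4": strategy.lines[3].pfs_model,
        "bsc": strategy.bsc.os_model,
    }
    tp = {s: _tp_array(m, max_cycles + 1, u) for s, m in models.items()}
    nxt = {"line1": "line2", "line2": "line3", "line3": "line4", "line4": "bsc"}

    occ = {s: np.zeros(max_cycles + 2) for s in living}
    occ["line1"][0] = 1.0
    dead = 0.0
    occ_rows: list[list[float]] = []
    ent_rows: list[list[float]] = []
    truncated = False
    for c in range(max_cycles + 1):
        totals = {s: float(occ[s][: c + 1].sum()) for s in living}
        occ_rows.append([totals[s] for s in living] + [dead])
        ent_rows.append([float(occ[s][0]) for s in living] + [0.0])
        if dead >= 1.0 - settings.death_tol:
            break
        if c == max_cycles:
            truncated = True
            break
        age = settings.start_age + c * u / 12.0
        q_m = 1.0 - (1.0 - lt.annual_at(age)) ** (u / 12.0)
        new_occ = {s: np.zeros(max_cycles + 2) for s in living}
        inflow = {s: 0.0 for s in living}
        for s in living:
            v = occ[s][: c + 1]
            if not v.any():
                continue
            if s == "bsc":
                p_die = np.maximum(tp[s][: c + 1], q_m)
                stay = 1.0 - p_die
                new_occ[s][1 : c + 2] += v * stay
                dead += float((v * p_die).sum())
            else:
                p_prog = tp[s][: c + 1] * (1.0 - q_m)
                stay = 1.0 - q_m - p_prog
                new_occ[s][1 : c + 2] += v * stay
                inflow[nxt[s]] += float((v * p_prog).sum())
                dead += float(v.sum()) * q_m
        for s, amount in inflow.items():
            new_occ[s][0] += amount
        occ = new_occ
    if truncated and dead < 1.0 - settings.death_tol:
        warnings.warn(
            f"horizon reached with {1.0 - dead:.3e} of the cohort still alive "
            f"for strategy {strategy.label!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    columns = list(STATE_NAMES)
    occupancy = pd.DataFrame(occ_rows, columns=columns)
    entries = pd.DataFrame(ent_rows, columns=columns)
    occupancy.index.name = entries.index.name = "cycle"
    return CohortTrace(occupancy=occupancy, entries=entries, truncated=truncated)


def _ae_totals(spec: LineSpec | BSCSpec) -> tuple[float, float]:
    cost = sum(ae.incidence * ae.cost for ae in spec.ae_profile)
    disutil = sum(ae.incidence * ae.disutility for ae in spec.ae_profile)
    return cost, disutil


def accumulate(
    trace: CohortTrace, strategy: StrategyDefinition, settings: ModelSettings
) -> tuple[float, float]:
    """Discounted total cost ($) and QALYs for a cohort trace.

    Costs and utilities accrue at the beginning of each cycle with discount
    factor ``(1 + r)**(-months/12)`` and no half-cycle correction.  Adverse
    events are charged once, weighted by incidence: by default to the
    fraction entering each line at that cycle; with ``ae_timing ==
    "model_start"`` the full expected AE burden of every line is charged at
    cycle 0 instead.
    """
    u = settings.cycle_length_months
    r = settings.annual_discount_rate
    cycles = trace.occupancy.index.to_numpy(dtype=float)
    disc = (1.0 + r) ** (-(cycles * u) / 12.0)
    specs: dict[str, LineSpec | BSCSpec] = {
        f"line{i + 1}": line for i, line in enumerate(strategy.lines)
    }
    specs["bsc"] = strategy.bsc
    total_cost = 0.0
    total_qalys = 0.0
    for state, spec in specs.items():
        w = float((trace.occupancy[state].to_numpy() * disc).sum())
        total_cost += w * spec.cycle_cost
        total_qalys += w * spec.utility * (u / 12.0)
        if settings.ae_timing == "line_entry":
            ae_cost, ae_dis = _ae_totals(spec)
            if ae_cost or ae_dis:
                we = float((trace.entries[state].to_numpy() * disc).sum())
                total_cost += we * ae_cost
                total_qalys -= we * ae_dis
    if settings.ae_timing == "model_start":
        for spec in specs.values():
            ae_cost, ae_dis = _ae_totals(spec)
            total_cost += ae_cost
            total_qalys -= ae_dis
    return total_cost, total_qalys
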