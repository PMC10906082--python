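"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the model at the low and high end of each
parameter's range with everything else held at base.  Probabilistic analysis
draws every uncertain parameter simultaneously — gamma distributions
moment-matched to (base, SE) for costs, beta for utilities and incidences,
with SE defaulting to 20% of base — one draw per parameter per iteration,
shared by both strategies.  Survival parameters are held fixed by default;
the acceptability curve reports, at each willingness-to-pay, the fraction of
iterations in which each strategy attains the maximal net monetary benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as cfgmod
from .cohort import accumulate, run_cohort
from .econ import icer, nmb

__all__ = [
    "ParamRange",
    "PSAResult",
    "default_ranges",
    "one_way_dsa",
    "draw_psa_params",
    "run_psa",
    "ceac",
    "ce_scatter",
    "probability_cost_effective",
]


@dataclass(frozen=True)
class ParamRange:
    """Uncertainty specification for one configuration parameter.

    ``path`` is a dotted path into the model configuration; ``dist`` chooses
    the PSA distribution ("gamma" for costs, "beta" for probabilities and
    utilities, "fixed" to exclude); ``se`` defaults to 20% of base.
    """

    path: str
    base: float
    low: float
    high: float
    dist: str = "gamma"
    se: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"range for {self.path!r} must satisfy low <= base <= high"
            )
        if self.dist not in ("gamma", "beta", "fixed"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.dist == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"beta-distributed {self.path!r} must lie in [0, 1]")
        if self.se is None:
            object.__setattr__(self, "se", 0.2 * self.base)


@dataclass
class PSAResult:
    """Monte-Carlo samples of (cost, QALYs) per strategy per iteration."""

    n_iter: int
    results: pd.DataFrame  # columns: iteration, strategy, cost, qalys
    seed: int
    n_skipped: int = 0

    @property
    def strategies(self) -> list[str]:
        return list(dict.fromkeys(self.results["strategy"]))


def default_ranges(
    cfg: dict,
    relative_range: float | None = None,
    se_fraction: float | None = None,
) -> list[ParamRange]:
    """Generate the standard one-way/PSA ranges from a configuration.

    Every cost parameter gets a gamma range of +/- ``relative_range`` (default
    20%); utilities and AE incidences get beta ranges.  Drugs listed in
    ``sensitivity.tki_decrease_only`` only vary downward (high = base),
    reflecting that an established TKI's list price will not rise.
    """
    sens = cfg.get("sensitivity", {})
    rr = relative_range if relative_range is not None else sens.get("relative_range", 0.2)
    sf = se_fraction if se_fraction is not None else sens.get("se_fraction", 0.2)
    decrease_only = set(sens.get("tki_decrease_only", []))

    ranges: list[ParamRange] = []

    def add(path: str, base: float, dist: str, cap: bool = False) -> None:
        base = float(base)
        if base == 0.0:
            return
        low = base * (1.0 - rr)
        high = base if cap else base * (1.0 + rr)
        if dist == "beta":
            low, high = max(low, 0.0), min(high, 1.0)
        ranges.append(
            ParamRange(path=path, base=base, low=low, high=high, dist=dist, se=sf * base)
        )

    for drug, entry in cfg.get("drugs", {}).items():
        cap = drug in decrease_only
        if "cycle_cost" in entry:
            add(f"drugs.{drug}.cycle_cost", entry["cycle_cost"], "gamma", cap)
        else:
            for i, item in enumerate(entry.get("schedule", [])):
                add(
                    f"drugs.{drug}.schedule.{i}.unit_price",
                    item["unit_price"],
                    "gamma",
                    cap,
                )
    fu = cfg.get("followup", {})
    for key in ("monthly_cost", "imaging_cost_per_scan"):
        if key in fu:
            add(f"followup.{key}", fu[key], "gamma")
    for name, value in cfg.get("utilities", {}).items():
        add(f"utilities.{name}", value, "beta")
    for drug, aes in cfg.get("adverse_events", {}).items():
        for i, ae in enumerate(aes):
            stem = f"adverse_events.{drug}.{i}"
            add(f"{stem}.incidence", ae["incidence"], "beta")
            add(f"{stem}.cost", ae["cost"], "gamma")
            add(f"{stem}.disutility", ae["disutility"], "gamma")
    return ranges


def _icer_value(cfg: dict) -> float:
    out = cfgmod.base_case(cfg)
    return out.icer if out.icer is not None else float("nan")


def one_way_dsa(cfg: dict, ranges: list[ParamRange]) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high, sorted by spread."""
    rows = []
    for r in ranges:
        cfgmod.get_path(cfg, r.path)  # raises KeyError naming unresolved paths
        low_cfg = cfgmod.copy_config(cfg)
        cfgmod.set_path(low_cfg, r.path, r.low)
        high_cfg = cfgmod.copy_config(cfg)
        cfgmod.set_path(high_cfg, r.path, r.high)
        icer_low = _icer_value(low_cfg)
        icer_high = _icer_value(high_cfg)
        rows.append(
            {
                "parameter": r.path,
                "base": r.base,
                "low": r.low,
                "high": r.high,
                "icer_low": icer_low,
                "icer_high": icer_high,
                "spread": abs(icer_high - icer_low),
            }
        )
    table = pd.DataFrame(rows).sort_values("spread", ascending=False)
    return table.reset_index(drop=True)


def _gamma_draw(rng: np.random.Generator, base: float, se: float) -> float:
    shape = (base / se) ** 2
    scale = se**2 / base
    return float(rng.gamma(shape, scale))


def _beta_draw(
    rng: np.random.Generator, base: float, se: float, low: float, high: float, path: str
) -> float:
    v = se**2
    if v >= base * (1.0 - base) or base <= 0.0 or base >= 1.0:
        warnings.warn(
            f"beta moment-matching infeasible for {path!r} "
            f"(base={base}, se={se}); falling back to uniform on the range",
            RuntimeWarning,
            stacklevel=3,
        )
        return float(rng.uniform(low, high))
    nu = base * (1.0 - base) / v - 1.0
    return float(rng.beta(base * nu, (1.0 - base) * nu))


def draw_psa_params(
    ranges: list[ParamRange], seed: int, iteration: int
) -> dict[str, float]:
    """One reproducible joint parameter draw for a PSA iteration."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, iteration]))
    draws: dict[str, float] = {}
    for r in ranges:
        if r.dist == "fixed" or r.se == 0.0:
            draws[r.path] = r.base
        elif r.dist == "gamma":
            draws[r.path] = _gamma_draw(rng, r.base, r.se)
        else:
            draws[r.path] = _beta_draw(rng, r.base, r.se, r.low, r.high, r.path)
    return draws


def run_psa(
    cfg: dict, ranges: list[ParamRange], n_iter: int, seed: int
) -> PSAResult:
    """Monte-Carlo PSA: draw parameters, run both strategies, record totals.

    When no varied parameter touches the survival section the cohort traces
    are computed once from the base configuration and only the cost/utility
    accumulation is repeated per iteration (transitions are unaffected by
    price and utility draws).  Failing iterations are skipped and counted.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    touches_survival = any(
        r.path.startswith("survival") and r.dist != "fixed" for r in ranges
    )
    traces = None
    if not touches_survival:
        strategies, settings, lt = cfgmod.build_model(cfg)
        traces = {s.label: run_cohort(s, settings, lt) for s in strategies}
    rows = []
    n_skipped = 0
    for it in range(n_iter):
        draws = draw_psa_params(ranges, seed, it)
        cfg_i = cfgmod.copy_config(cfg)
        for path, value in draws.items():
            cfgmod.set_path(cfg_i, path, value)
        try:
            if traces is not None:
                strategies_i, settings_i, _ = cfgmod.build_model(cfg_i)
                results = {
                    s.label: accumulate(traces[s.label], s, settings_i)
                    for s in strategies_i
                }
            else:
                results = cfgmod.evaluate(cfg_i)
        except (ValueError, KeyError) as exc:
            n_skipped += 1
            warnings.warn(
                f"PSA iteration {it} skipped: {exc}", RuntimeWarning, stacklevel=2
            )
            continue
        for label, (cost, qalys) in results.items():
            rows.append(
                {"iteration": it, "strategy": label, "cost": cost, "qalys": qalys}
            )
    return PSAResult(
        n_iter=n_iter,
        results=pd.DataFrame(rows),
        seed=seed,
        n_skipped=n_skipped,
    )


def _wide(psa: PSAResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    cost = psa.results.pivot(index="iteration", columns="strategy", values="cost")
    qalys = psa.results.pivot(index="iteration", columns="strategy", values="qalys")
    return cost, qalys


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each willingness-to-pay the probability a strategy is cost-effective
    is the fraction of iterations in which it attains the maximal net
    monetary benefit; exact ties are split equally.
    """
    if len(psa.results) == 0:
        raise ValueError("PSA result is empty")
    cost, qalys = _wide(psa)
    rows = []
    for wtp in np.asarray(wtp_grid, dtype=float):
        nmb_tbl = qalys * wtp - cost
        best = nmb_tbl.max(axis=1)
        winners = nmb_tbl.eq(best, axis=0)
        share = winners.div(winners.sum(axis=1), axis=0)
        probs = share.mean(axis=0)
        for strategy, p in probs.items():
            rows.append({"wtp": wtp, "strategy": strategy, "probability": float(p)})
    return pd.DataFrame(rows)


def probability_cost_effective(psa: PSAResult, wtp: float, strategy: str) -> float:
    """Probability (fraction of iterations) that ``strategy`` is optimal."""
    table = ceac(psa, [wtp])
    return float(table.loc[table["strategy"] == strategy, "probability"].iloc[0])


def ce_scatter(
    psa: PSAResult, strategy_a: str | None = None, strategy_b: str | None = None
) -> pd.DataFrame:
    """Per-iteration incremental (delta_cost, delta_qalys) of A versus B."""
    if len(psa.results) == 0:
        raise ValueError("PSA result is empty")
    cost, qalys = _wide(psa)
    labels = list(cost.columns)
    a = strategy_a or labels[0]
    b = strategy_b or labels[1]
    return pd.DataFrame(
        {
            "iteration": cost.index,
            "delta_cost": (cost[a] - cost[b]).to_numpy(),
            "delta_qalys": (qalys[a] - qalys[b]).to_numpy(),
        }
    ).reset_index(drop=True)
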