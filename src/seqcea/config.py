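"""Structured model configuration: load, validate, and build runnable models.

The configuration is a plain nested dict (YAML on disk) with top-level keys
``settings``, ``patient``, ``followup``, ``utilities``, ``drugs``,
``adverse_events``, ``survival``, ``strategies``, ``comparison``,
``sensitivity`` and ``life_table``.  Utilities attach to the line *position*
(first line 0.71, second 0.67, third 0.59, fourth and BSC 0.46 in the base
case); costs and adverse-event profiles attach to the *drug*; survival laws
are named entries referenced by each strategy line, so any family may be
assigned per line.

Parameter paths used by the sensitivity module are dotted strings into this
structure, e.g. ``drugs.brigatinib.cycle_cost`` or ``utilities.line2``;
integer tokens index into lists.
"""

from __future__ import annotations

import copy
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import econ
from .cohort import (
    AdverseEvent,
    BSCSpec,
    LifeTable,
    LineSpec,
    ModelSettings,
    StrategyDefinition,
    accumulate,
    run_cohort,
)
from .econ import DrugSchedule, EconOutcome, PatientProfile, icer
from .survival import ParametricSurvival

__all__ = [
    "load_config",
    "save_config",
    "get_path",
    "set_path",
    "validate_config",
    "build_model",
    "evaluate",
    "base_case",
    "base_case_table",
]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _tokens(path: str) -> list[str]:
    return path.split(".")


def get_path(cfg: dict, path: str) -> Any:
    """Resolve a dotted parameter path; raises KeyError naming the path."""
    node: Any = cfg
    for tok in _tokens(path):
        try:
            node = node[int(tok)] if isinstance(node, list) else node[tok]
        except (KeyError, IndexError, TypeError) as exc:
            raise KeyError(f"cannot resolve parameter path {path!r}") from exc
    return node


def set_path(cfg: dict, path: str, value: Any) -> None:
    toks = _tokens(path)
    node: Any = cfg
    for tok in toks[:-1]:
        try:
            node = node[int(tok)] if isinstance(node, list) else node[tok]
        except (KeyError, IndexError, TypeError) as exc:
            raise KeyError(f"cannot resolve parameter path {path!r}") from exc
    last = toks[-1]
    try:
        if isinstance(node, list):
            node[int(last)] = value
        else:
            if last not in node:
                raise KeyError(last)
            node[last] = value
    except (KeyError, IndexError, TypeError) as exc:
        raise KeyError(f"cannot resolve parameter path {path!r}") from exc


def _settings(cfg: dict) -> ModelSettings:
    s = cfg.get("settings", {})
    return ModelSettings(
        cycle_length_months=s.get("cycle_length_months", 1.0),
        annual_discount_rate=s.get("annual_discount_rate", 0.03),
        start_age=s.get("start_age", 58.0),
        age_cap=s.get("age_cap", 100.0),
        wtp=s.get("wtp", 150_000.0),
        horizon_months=s.get("horizon_months"),
        ae_timing=s.get("ae_timing", "line_entry"),
    )


def _patient(cfg: dict) -> PatientProfile:
    p = cfg.get("patient", {})
    return PatientProfile(
        bsa=p.get("bsa", 1.72),
        weight=p.get("weight", 65.0),
        crcl=p.get("crcl", 70.0),
    )


def _life_table(cfg: dict) -> LifeTable:
    rows = cfg["life_table"]["rows"]
    arr = np.asarray(rows, dtype=float)
    return LifeTable(ages=arr[:, 0].astype(int), annual_mortality=arr[:, 1])


def _survival_model(cfg: dict, name: str) -> ParametricSurvival:
    entry = cfg["survival"][name]
    return ParametricSurvival(family=entry["family"], params=dict(entry["params"]))


def _drug_acquisition_cost(cfg: dict, drug: str) -> float:
    """Per-cycle acquisition (+ administration) cost for one drug."""
    entry = cfg["drugs"][drug]
    if "cycle_cost" in entry:
        return float(entry["cycle_cost"])
    patient = _patient(cfg)
    schedules = [
        DrugSchedule(
            drug=item.get("name", drug),
            rule=item["rule"],
            dose=float(item["dose"]),
            admins_per_cycle=float(item["admins_per_cycle"]),
            unit_price=float(item["unit_price"]),
            admin_fee=float(item.get("admin_fee", 0.0)),
        )
        for item in entry["schedule"]
    ]
    return econ.cycle_cost(schedules, patient)


def _line_cycle_cost(cfg: dict, drug: str) -> float:
    """Drug acquisition + follow-up + amortized imaging, inflation-adjusted."""
    fu = cfg.get("followup", {})
    raw = (
        _drug_acquisition_cost(cfg, drug)
        + float(fu.get("monthly_cost", 0.0))
        + float(fu.get("imaging_cost_per_scan", 0.0)) / 3.0
    )
    return econ.adjust_inflation(raw, float(cfg.get("inflation_ratio", 1.0)))


def _ae_profile(cfg: dict, drug: str) -> tuple[AdverseEvent, ...]:
    ratio = float(cfg.get("inflation_ratio", 1.0))
    return tuple(
        AdverseEvent(
            name=ae["name"],
            incidence=float(ae["incidence"]),
            cost=econ.adjust_inflation(float(ae["cost"]), ratio),
            disutility=float(ae["disutility"]),
        )
        for ae in cfg.get("adverse_events", {}).get(drug, [])
    )


def build_model(cfg: dict) -> tuple[list[StrategyDefinition], ModelSettings, LifeTable]:
    """Instantiate strategies, settings and the life table from a config."""
    settings = _settings(cfg)
    lt = _life_table(cfg)
    utilities = cfg["utilities"]
    strategies = []
    for label, sdef in cfg["strategies"].items():
        lines = []
        for i, line in enumerate(sdef["lines"]):
            drug = line["drug"]
            lines.append(
                LineSpec(
                    name=drug,
                    pfs_model=_survival_model(cfg, line["survival"]),
                    utility=float(utilities[f"line{i + 1}"]),
                    cycle_cost=_line_cycle_cost(cfg, drug),
                    ae_profile=_ae_profile(cfg, drug),
                )
            )
        bsc = BSCSpec(
            os_model=_survival_model(cfg, sdef.get("bsc_survival", "bsc_os")),
            utility=float(utilities["bsc"]),
            cycle_cost=_line_cycle_cost(cfg, sdef.get("bsc_drug", "best_supportive_care")),
        )
        strategies.append(StrategyDefinition(label=label, lines=tuple(lines), bsc=bsc))
    return strategies, settings, lt


def validate_config(cfg: dict) -> None:
    """Raise ValueError/KeyError on a malformed configuration."""
    for key in ("settings", "utilities", "drugs", "survival", "strategies", "life_table"):
        if key not in cfg:
            raise ValueError(f"configuration is missing required section {key!r}")
    for name, value in cfg["utilities"].items():
        if not 0.0 <= float(value) <= 1.0:
            raise ValueError(f"utility {name!r} must lie in [0, 1]")
    for label, sdef in cfg["strategies"].items():
        if len(sdef["lines"]) != 4:
            raise ValueError(f"strategy {label!r} must define exactly 4 lines")
    build_model(cfg)  # instantiation performs the remaining checks


def evaluate(cfg: dict) -> dict[str, tuple[float, float]]:
    """Run every strategy: discounted (total cost, total QALYs) per label."""
    strategies, settings, lt = build_model(cfg)
    out = {}
    for strat in strategies:
        trace = run_cohort(strat, settings, lt)
        out[strat.label] = accumulate(trace, strat, settings)
    return out


def _comparison_labels(cfg: dict) -> tuple[str, str]:
    comp = cfg.get("comparison", {})
    labels = list(cfg["strategies"])
    return (
        comp.get("intervention", labels[0]),
        comp.get("comparator", labels[1]),
    )


def base_case(cfg: dict) -> EconOutcome:
    """Incremental economics of the configured intervention vs comparator."""
    results = evaluate(cfg)
    a, b = _comparison_labels(cfg)
    return icer(results[a], results[b], label_a=a, label_b=b)


def base_case_table(cfg: dict) -> pd.DataFrame:
    """Base-case results shaped like a standard CEA results table."""
    out = base_case(cfg)
    rows = [
        {
            "arm": out.label_a,
            "cost": out.cost_a,
            "delta_cost": None,
            "qalys": out.qalys_a,
            "delta_qalys": None,
            "icer": None,
            "dominance": None,
        },
        {
            "arm": out.label_b,
            "cost": out.cost_b,
            "delta_cost": out.cost_b - out.cost_a,
            "qalys": out.qalys_b,
            "delta_qalys": out.qalys_b - out.qalys_a,
            "icer": (out.cost_b - out.cost_a) / (out.qalys_b - out.qalys_a)
            if out.delta_qalys != 0
            else None,
            "dominance": (
                {"dominated": "dominant", "dominant": "dominated"}.get(out.dominance)
            ),
        },
    ]
    return pd.DataFrame(rows)


def copy_config(cfg: dict) -> dict:
    return copy.deepcopy(cfg)
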