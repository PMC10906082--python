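"""Drug dosing, per-cycle cost construction, and incremental economics.

Doses follow the reference patient (body surface area 1.72 m², weight 65 kg,
creatinine clearance 70 mL/min); carboplatin uses the Calvert formula
``dose = AUC * (CrCl + 25)``.  Monthly cycle costs combine drug acquisition,
administration fees, monthly follow-up (labs + office visit) and quarterly
tumour imaging amortized over three monthly cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PatientProfile",
    "DrugSchedule",
    "EconOutcome",
    "dose_per_administration",
    "cycle_cost",
    "adjust_inflation",
    "icer",
    "nmb",
]

DOSING_RULES = ("flat", "per_bsa", "per_weight", "carboplatin_auc")


@dataclass(frozen=True)
class PatientProfile:
    bsa: float = 1.72  # m^2
    weight: float = 65.0  # kg
    crcl: float = 70.0  # mL/min

    def __post_init__(self) -> None:
        if self.bsa <= 0 or self.weight <= 0 or self.crcl <= 0:
            raise ValueError("patient measurements must be positive")


@dataclass(frozen=True)
class DrugSchedule:
    """Dosing rule and pricing for one agent within a monthly cycle.

    ``dose`` is interpreted per the rule: mg (flat, per administration),
    mg/m² (per_bsa), mg/kg (per_weight), or target AUC (carboplatin_auc).
    For continuous oral dosing use rule "flat" with one administration per
    day of the cycle and a zero administration fee.
    """

    drug: str
    rule: str
    dose: float
    admins_per_cycle: float
    unit_price: float  # $ per mg (or per unit dispensed)
    admin_fee: float = 0.0  # $ per administration

    def __post_init__(self) -> None:
        if self.rule not in DOSING_RULES:
            raise ValueError(
                f"unknown dosing rule {self.rule!r}; choose one of {DOSING_RULES}"
            )
        if min(self.dose, self.admins_per_cycle, self.unit_price, self.admin_fee) < 0:
            raise ValueError(f"schedule for {self.drug!r} has negative quantities")


@dataclass(frozen=True)
class EconOutcome:
    """Incremental comparison of strategy A against comparator B.

    ``icer`` is the signed quotient delta_cost/delta_qalys whenever
    delta_qalys != 0; it is reported alongside the dominance label rather
    than suppressed, because a dominated comparison still prints a (negative)
    ratio.  ``dominance`` describes A relative to B.
    """

    label_a: str
    label_b: str
    cost_a: float
    qalys_a: float
    cost_b: float
    qalys_b: float
    delta_cost: float
    delta_qalys: float
    icer: float | None
    dominance: str | None  # "dominant", "dominated", or None

    @property
    def dominated_strategy(self) -> str | None:
        if self.dominance == "dominated":
            return self.label_a
        if self.dominance == "dominant":
            return self.label_b
        return None


def dose_per_administration(schedule: DrugSchedule, patient: PatientProfile) -> float:
    """Absolute dose in mg delivered per administration."""
    if schedule.rule == "flat":
        return schedule.dose
    if schedule.rule == "per_bsa":
        return schedule.dose * patient.bsa
    if schedule.rule == "per_weight":
        return schedule.dose * patient.weight
    if schedule.rule == "carboplatin_auc":
        return schedule.dose * (patient.crcl + 25.0)
    raise ValueError(schedule.rule)


def cycle_cost(
    schedules: list[DrugSchedule],
    patient: PatientProfile,
    followup_monthly: float = 0.0,
    imaging_per_scan: float = 0.0,
    inflation_ratio: float = 1.0,
) -> float:
    """Total $ per monthly cycle for a treatment line.

    Drug acquisition + administration fees + monthly follow-up + one third
    of the quarterly imaging charge, all inflated by ``inflation_ratio``.
    """
    total = 0.0
    for s in schedules:
        dose = dose_per_administration(s, patient)
        total += (dose * s.unit_price + s.admin_fee) * s.admins_per_cycle
    total += followup_monthly + imaging_per_scan / 3.0
    return adjust_inflation(total, inflation_ratio)


def adjust_inflation(cost: float, index_ratio: float) -> float:
    """Scale a historical cost by a consumer-price-index ratio."""
    if index_ratio <= 0:
        raise ValueError("inflation index ratio must be positive")
    return cost * index_ratio


def icer(
    outcome_a: tuple[float, float],
    outcome_b: tuple[float, float],
    label_a: str = "A",
    label_b: str = "B",
) -> EconOutcome:
    """Incremental cost-effectiveness of A versus B.

    A is *dominated* when it costs more and yields fewer QALYs, *dominant*
    in the mirror case.  With equal QALYs no ICER is defined and dominance
    is decided on cost alone.
    """
    cost_a, qalys_a = outcome_a
    cost_b, qalys_b = outcome_b
    d_cost = cost_a - cost_b
    d_q = qalys_a - qalys_b
    ratio = d_cost / d_q if d_q != 0 else None
    if d_q < 0 and d_cost > 0:
        dominance = "dominated"
    elif d_q > 0 and d_cost < 0:
        dominance = "dominant"
    elif d_q == 0 and d_cost != 0:
        dominance = "dominant" if d_cost < 0 else "dominated"
    else:
        dominance = None
    return EconOutcome(
        label_a=label_a,
        label_b=label_b,
        cost_a=cost_a,
        qalys_a=qalys_a,
        cost_b=cost_b,
        qalys_b=qalys_b,
        delta_cost=d_cost,
        delta_qalys=d_q,
        icer=ratio,
        dominance=dominance,
    )


def nmb(outcome: tuple[float, float], wtp: float) -> float:
    """Net monetary benefit ``qalys * wtp - cost``; the decision rule behind
    cost-effectiveness acceptability curves."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    cost, qalys = outcome
    return qalys * wtp - cost
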