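"""Three-state partitioned-survival model with cost/QALY accrual.

State occupancy is read directly off the two survival curves each cycle:

    PFS(t)   = min(S_PFS(t), S_OS(t))      (clamped if the curves cross)
    PD(t)    = S_OS(t) - PFS(t)
    death(t) = 1 - S_OS(t)

The model runs on 1-month cycles over a fixed horizon (default 60 cycles,
5 years).  Progression-free members accrue drug acquisition,
hospitalization and follow-up costs and the PFS utility; progressed
members accrue a flat best-supportive-care cost and the PD utility; death
accrues nothing.  Expected adverse-event management cost (incidence x
unit cost over grade >=3 events) is charged once at model entry.  Costs
and QALYs are discounted at an annual rate compounded per cycle.

Dosing is body-size based: trastuzumab deruxtecan at 5.4 mg/kg per
3-week administration (whole-vial wastage by default), chemotherapy as a
usage-weighted mix of five single agents dosed per m^2 of body surface
area.  A 3-week administration converts to a monthly cost via the factor
(365.25/12)/21.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parametric_survival import SurvivalCurve, survival_at

__all__ = [
    "EconomicSettings",
    "UtilityInputs",
    "AgentCost",
    "CostInputs",
    "AEProfile",
    "StateTrace",
    "EconResult",
    "ICERResult",
    "MissingCostError",
    "DAYS_PER_MONTH",
    "state_occupancy",
    "discount_factor",
    "cycle_drug_cost",
    "ae_expected_cost",
    "accrue",
    "run_arm",
    "compute_icer",
]

DAYS_PER_MONTH = 365.25 / 12.0


class MissingCostError(ValueError):
    """A required unit cost is absent from the configuration."""


@dataclass(frozen=True)
class EconomicSettings:
    """Cycle length is fixed at 1 month; horizon in cycles (60 = 5 years)."""

    horizon_cycles: int = 60
    annual_discount: float = 0.05
    wtp_per_qaly: float = 35_796.83
    exchange_rate_cny_per_usd: float = 6.7863
    half_cycle_correction: bool = False

    def __post_init__(self):
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if not 0.0 <= self.annual_discount <= 1.0:
            raise ValueError("annual_discount must be in [0, 1]")


@dataclass(frozen=True)
class UtilityInputs:
    """Annual health-state utilities; death is anchored at 0."""

    u_pfs: float = 0.843
    u_pd: float = 0.60
    u_death: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.u_pd <= self.u_pfs <= 1.0) or self.u_death != 0.0:
            raise ValueError("require 0 <= u_pd <= u_pfs <= 1 and u_death = 0")


@dataclass(frozen=True)
class AgentCost:
    """Dosing and pricing of one chemotherapy agent.

    ``unit_cost`` is USD per package unit of ``unit_size_mg``;
    ``dose_mg_per_m2`` is per administration, ``admins_per_21d`` per
    3-week cycle.  ``wastage``: 'whole' bills full vials (ceil), 'round'
    the nearest unit (oral tablets), 'exact' fractional units.
    """

    unit_cost: float | None
    unit_size_mg: float
    dose_mg_per_m2: float
    admins_per_21d: float
    wastage: str = "whole"

    def per_admin_cost(self, bsa: float) -> float:
        if self.unit_cost is None:
            raise MissingCostError("unit cost not set")
        dose_mg = self.dose_mg_per_m2 * bsa
        units = dose_mg / self.unit_size_mg
        if self.wastage == "whole":
            units = math.ceil(units - 1e-9)
        elif self.wastage == "round":
            units = round(units)
        elif self.wastage != "exact":
            raise ValueError(f"unknown wastage policy {self.wastage!r}")
        return units * self.unit_cost


def _default_agents() -> dict[str, AgentCost]:
    # Dosing schedules are standard single-agent regimens for metastatic
    # breast cancer; capecitabine 1250 mg/m2 twice daily, days 1-14 of 21.
    # Eribulin and gemcitabine unit costs are not part of the published
    # input table and must be supplied by configuration.
    return {
        "capecitabine": AgentCost(12.11, 500.0, 1250.0, 28.0, "round"),
        "eribulin": AgentCost(None, 1.0, 1.4, 2.0, "whole"),
        "gemcitabine": AgentCost(None, 1000.0, 1250.0, 2.0, "whole"),
        "paclitaxel": AgentCost(37.79, 30.0, 175.0, 1.0, "whole"),
        "nab-paclitaxel": AgentCost(114.94, 100.0, 260.0, 1.0, "whole"),
    }


def _default_weights() -> dict[str, float]:
    return {"capecitabine": 0.201, "eribulin": 0.511, "gemcitabine": 0.103,
            "paclitaxel": 0.082, "nab-paclitaxel": 0.103}


@dataclass(frozen=True)
class CostInputs:
    """All unit costs in 2022 USD; dosing on a 55 kg / 1.72 m^2 reference
    patient."""

    tdxd_per_100mg: float = 2_431.37
    tdxd_dose_mg_per_kg: float = 5.4
    tdxd_q_days: float = 21.0
    tdxd_wastage: str = "whole"
    hospitalization_per_cycle: float = 57.43
    followup_per_cycle: float = 48.00
    pd_cost_per_cycle: float = 1_886.67
    body_weight_kg: float = 55.0
    bsa_m2: float = 1.72
    agents: dict[str, AgentCost] = field(default_factory=_default_agents)
    regimen_weights: dict[str, float] = field(default_factory=_default_weights)

    def __post_init__(self):
        for name, value in (("tdxd_per_100mg", self.tdxd_per_100mg),
                            ("hospitalization_per_cycle", self.hospitalization_per_cycle),
                            ("followup_per_cycle", self.followup_per_cycle),
                            ("pd_cost_per_cycle", self.pd_cost_per_cycle)):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        wsum = sum(self.regimen_weights.values())
        if abs(wsum - 1.0) > 1e-2 + 1e-9:
            raise ValueError(f"regimen weights must sum to 1 (got {wsum:.4f})")
        if abs(wsum - 1.0) > 1e-9:
            # small published rounding slack is renormalized away
            object.__setattr__(self, "regimen_weights",
                               {k: v / wsum for k, v in self.regimen_weights.items()})


#: the ten grade >=3 adverse events costed in the model
AE_EVENTS = ("neutropenia", "anemia", "thrombocytopenia", "leukopenia",
             "nausea", "vomiting", "diarrhea",
             "increased_aminotransferase", "fatigue", "decreased_appetite")

_AE_COSTS = {"neutropenia": 547.50, "anemia": 607.06, "thrombocytopenia": 193.50,
             "leukopenia": 104.95, "nausea": 39.60, "vomiting": 39.60,
             "diarrhea": 44.30, "increased_aminotransferase": 68.30,
             "fatigue": 131.78, "decreased_appetite": 115.40}

_AE_INCIDENCE = {
    "tdxd": {"neutropenia": 0.137, "anemia": 0.081, "thrombocytopenia": 0.051,
             "leukopenia": 0.065, "nausea": 0.046, "vomiting": 0.013,
             "diarrhea": 0.011, "increased_aminotransferase": 0.032,
             "fatigue": 0.075, "decreased_appetite": 0.024},
    "chemo": {"neutropenia": 0.407, "anemia": 0.047, "thrombocytopenia": 0.006,
              "leukopenia": 0.192, "nausea": 0.0, "vomiting": 0.0,
              "diarrhea": 0.017, "increased_aminotransferase": 0.081,
              "fatigue": 0.047, "decreased_appetite": 0.012},
}


@dataclass(frozen=True)
class AEProfile:
    """Grade >=3 adverse-event incidences per arm and management unit costs."""

    costs: dict[str, float] = field(default_factory=lambda: dict(_AE_COSTS))
    incidence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(v) for a, v in _AE_INCIDENCE.items()})

    def __post_init__(self):
        for event, c in self.costs.items():
            if c < 0:
                raise ValueError(f"AE cost for {event} must be >= 0")
        for arm, inc in self.incidence.items():
            for event, p in inc.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"AE incidence {arm}/{event} must be in [0,1]")


@dataclass(frozen=True)
class StateTrace:
    """Membership probabilities and discount factors at cycle starts 0..H."""

    cycles: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    discount: np.ndarray
    n_clamped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cycle": self.cycles, "pfs": self.pfs, "pd": self.pd,
                             "dead": self.dead, "discount": self.discount})


@dataclass(frozen=True)
class EconResult:
    cost_pfs: float
    cost_pd: float
    qaly_pfs: float
    qaly_pd: float

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_pd

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_pd


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: float          # NaN when undefined by dominance/indeterminacy
    label: str           # 'icer' | 'dominant' | 'dominated' | 'indeterminate'


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Per-cycle discount factor (1 + r)^(-cycle/12) for monthly cycles."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle / 12.0))


def state_occupancy(os_curve: SurvivalCurve, pfs_curve: SurvivalCurve,
                    settings: EconomicSettings) -> StateTrace:
    """Partition the two survival curves into PFS/PD/death occupancies."""
    cycles = np.arange(settings.horizon_cycles + 1)
    t = cycles.astype(float)  # 1-month cycles: time in months == cycle index
    s_os = survival_at(os_curve, t)
    s_pfs = survival_at(pfs_curve, t)
    clamped = int(np.sum(s_pfs > s_os + 1e-12))
    pfs = np.minimum(s_pfs, s_os)
    pd_ = s_os - pfs
    dead = 1.0 - s_os
    df = (1.0 + settings.annual_discount) ** (-t / 12.0)
    return StateTrace(cycles=cycles, pfs=pfs, pd=pd_, dead=dead,
                      discount=df, n_clamped=clamped)


def cycle_drug_cost(arm: str, costs: CostInputs) -> float:
    """Monthly drug-acquisition cost while progression-free, USD/cycle."""
    if arm == "tdxd":
        dose_mg = costs.tdxd_dose_mg_per_kg * costs.body_weight_kg
        units = dose_mg / 100.0
        if costs.tdxd_wastage == "whole":
            units = math.ceil(units - 1e-9)
        elif costs.tdxd_wastage != "exact":
            raise ValueError(f"unknown wastage policy {costs.tdxd_wastage!r}")
        per_admin = units * costs.tdxd_per_100mg
        return per_admin * DAYS_PER_MONTH / costs.tdxd_q_days
    if arm == "chemo":
        missing = [n for n, a in costs.agents.items()
                   if costs.regimen_weights.get(n, 0) > 0 and a.unit_cost is None]
        if missing:
            raise MissingCostError(
                "missing unit cost for chemotherapy agent(s): " + ", ".join(sorted(missing)))
        monthly = 0.0
        for name, w in costs.regimen_weights.items():
            agent = costs.agents[name]
            per_21d = agent.per_admin_cost(costs.bsa_m2) * agent.admins_per_21d
            monthly += w * per_21d * DAYS_PER_MONTH / 21.0
        return monthly
    raise ValueError(f"unknown arm {arm!r}; expected 'tdxd' or 'chemo'")


def ae_expected_cost(arm: str, ae: AEProfile) -> float:
    """One-off expected adverse-event management cost for *arm*."""
    if arm not in ae.incidence:
        raise ValueError(f"no AE incidences for arm {arm!r}")
    inc = ae.incidence[arm]
    return float(sum(inc.get(e, 0.0) * ae.costs.get(e, 0.0) for e in inc))


def accrue(trace: StateTrace, arm: str, costs: CostInputs,
           utilities: UtilityInputs, ae: AEProfile,
           settings: EconomicSettings) -> EconResult:
    """Discounted cost and QALY totals for one strategy.

    Membership is taken at cycle start over cycles 0..H-1 (no half-cycle
    correction by default; with the option on, the entry and terminal
    points carry half weight).  Utilities are annual, so a month in a
    state contributes utility/12 QALYs before discounting.
    """
    H = len(trace.cycles) - 1
    w = np.ones(H + 1)
    if settings.half_cycle_correction:
        w[0] = w[H] = 0.5
    else:
        w[H] = 0.0
    drug = cycle_drug_cost(arm, costs)
    pfs_cost_cycle = drug + costs.hospitalization_per_cycle + costs.followup_per_cycle
    dfw = trace.discount * w
    cost_pfs = float(np.sum(trace.pfs * pfs_cost_cycle * dfw))
    cost_pd = float(np.sum(trace.pd * costs.pd_cost_per_cycle * dfw))
    cost_pfs += ae_expected_cost(arm, ae)  # charged once at model entry
    qaly_pfs = float(np.sum(trace.pfs * utilities.u_pfs / 12.0 * dfw))
    qaly_pd = float(np.sum(trace.pd * utilities.u_pd / 12.0 * dfw))
    return EconResult(cost_pfs=cost_pfs, cost_pd=cost_pd,
                      qaly_pfs=qaly_pfs, qaly_pd=qaly_pd)


def run_arm(os_curve: SurvivalCurve, pfs_curve: SurvivalCurve, arm: str,
            settings: EconomicSettings, costs: CostInputs,
            utilities: UtilityInputs, ae: AEProfile) -> EconResult:
    """Occupancy plus accrual for one strategy in one call."""
    trace = state_occupancy(os_curve, pfs_curve, settings)
    return accrue(trace, arm, costs, utilities, ae, settings)


def compute_icer(intervention: EconResult, comparator: EconResult) -> ICERResult:
    """Incremental cost-effectiveness of *intervention* vs *comparator*.

    Returns the ratio when incremental QALYs are non-zero, otherwise a
    dominance or indeterminacy label with a NaN ratio — never an exception.
    """
    dc = intervention.cost_total - comparator.cost_total
    dq = intervention.qaly_total - comparator.qaly_total
    if dq == 0.0:
        if dc > 0:
            return ICERResult(dc, dq, float("nan"), "dominated")
        if dc < 0:
            return ICERResult(dc, dq, float("nan"), "dominant")
        return ICERResult(dc, dq, float("nan"), "indeterminate")
    if dq > 0 and dc <= 0:
        return ICERResult(dc, dq, float("nan"), "dominant")
    if dq < 0 and dc >= 0:
        return ICERResult(dc, dq, float("nan"), "dominated")
    return ICERResult(dc, dq, dc / dq, "icer")
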