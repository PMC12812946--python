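"""Cost and QALY accrual over a partitioned-survival trace.

The analysis takes the healthcare-system perspective and counts direct
medical costs only: regimen drugs while progression-free
(treat-to-progression), a single representative post-progression regimen,
routine laboratory / imaging / hospitalization / supportive-care /
follow-up items in both alive states, and one-off burdens for grade >= 3
treatment-emergent adverse events.  Utilities weight state occupancy into
QALYs; all flows are discounted with the trace's cycle-midpoint factors.

Monetary amounts are in USD per 28-day cycle; the CNY exchange rate is
carried as metadata only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from psmcea.psm_engine import StateTrace

__all__ = [
    "AdverseEvent",
    "EconomicInputs",
    "ArmResult",
    "CEResult",
    "default_inputs",
    "state_cost_per_cycle",
    "ae_burden",
    "accrue",
    "incremental",
    "TREATMENT",
    "CONTROL",
]

TREATMENT = "treatment"
CONTROL = "control"


@dataclass
class AdverseEvent:
    """One grade >= 3 treatment-emergent adverse event.

    ``cost`` is the management cost (USD), ``disutility`` the utility
    decrement while the event lasts, ``incidence`` maps arm label to the
    per-trial probability of experiencing the event.
    """

    name: str
    cost: float
    disutility: float
    incidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cost < 0 or self.disutility < 0:
            raise ValueError(f"AE {self.name}: cost and disutility must be >= 0")
        for arm, p in self.incidence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"AE {self.name}: incidence[{arm}] outside [0, 1]")


@dataclass
class EconomicInputs:
    """Cost, utility and threshold inputs for both arms.

    ``pfs_drugs`` maps arm label to the drugs costed during the
    progression-free state; ``pd_drugs`` lists the post-progression
    regimen (applied to both arms).  ``ae_mode`` is ``"one_off"`` (AE cost
    and QALY loss applied once at model entry, weighted by incidence) or
    ``"per_cycle"`` (AE cost added to the PFS state cost every cycle).
    """

    drug_cost_per_cycle: dict[str, float]
    other_cost_per_cycle: dict[str, float]
    utilities: dict[str, float]
    ae_profile: list[AdverseEvent] = field(default_factory=list)
    pfs_drugs: dict[str, list[str]] = field(default_factory=dict)
    pd_drugs: list[str] = field(default_factory=lambda: ["everolimus"])
    wtp: float = 40271.0
    exchange_rate_cny_per_usd: float = 7.1329
    ae_mode: str = "one_off"
    ae_duration_cycles: float = 1.0

    def __post_init__(self) -> None:
        for name, c in {**self.drug_cost_per_cycle, **self.other_cost_per_cycle}.items():
            if c < 0:
                raise ValueError(f"cost {name!r} must be >= 0")
        for state, u in self.utilities.items():
            if not 0 <= u <= 1:
                raise ValueError(f"utility {state!r} must lie in [0, 1]")
        if self.wtp <= 0:
            raise ValueError("wtp must be positive")
        if self.ae_mode not in ("one_off", "per_cycle"):
            raise ValueError("ae_mode must be 'one_off' or 'per_cycle'")

    def copy(self) -> "EconomicInputs":
        return copy.deepcopy(self)


# Placeholder grade>=3 TEAE incidences (synthetic): per-arm rates are not
# part of the printed cost/utility inputs, so these are order-of-magnitude
# stand-ins for a PI3K-inhibitor combination vs the doublet; override them
# in config for any substantive use.  AE costs and disutilities below are
# the printed per-event values.
_DEFAULT_AES = [
    ("neutropenia", 28.04, 0.130, 0.80, 0.78),
    ("thrombocytopenia", 42.06, 0.030, 0.14, 0.04),
    ("stomatitis", 10.51, 0.220, 0.06, 0.00),
    ("anemia", 21.03, 0.070, 0.06, 0.02),
    ("hyperglycemia", 13.33, 0.006, 0.06, 0.00),
    ("leukopenia", 28.04, 0.130, 0.27, 0.24),
    ("diarrhea", 11.22, 0.103, 0.00, 0.00),
]


def default_inputs() -> EconomicInputs:
    """Base-case inputs: USD per 28-day cycle, literature utilities."""
    return EconomicInputs(
        drug_cost_per_cycle={
            "inavolisib": 4065.70,
            "palbociclib": 419.60,
            "fulvestrant": 646.59,
            "everolimus": 459.28,
        },
        other_cost_per_cycle={
            "laboratory": 59.89,
            "radiological": 152.95,
            "hospitalization": 90.71,
            "supportive_care": 140.20,
            "follow_up": 11.64,
        },
        utilities={"pfs": 0.837, "pd": 0.443},
        ae_profile=[
            AdverseEvent(n, c, d, {TREATMENT: pt, CONTROL: pc})
            for n, c, d, pt, pc in _DEFAULT_AES
        ],
        pfs_drugs={
            TREATMENT: ["inavolisib", "palbociclib", "fulvestrant"],
            CONTROL: ["palbociclib", "fulvestrant"],
        },
    )


def state_cost_per_cycle(arm: str, state: str, inputs: EconomicInputs) -> float:
    """Per-cycle cost of one health state for one arm.

    Progression-free: the arm's regimen drugs plus every routine item.
    Progressed: the post-progression regimen plus every routine item.
    """
    other = sum(inputs.other_cost_per_cycle.values())
    if state == "pfs":
        drugs = inputs.pfs_drugs.get(arm)
        if drugs is None:
            raise ValueError(f"unknown arm {arm!r}")
        return sum(inputs.drug_cost_per_cycle[d] for d in drugs) + other
    if state == "pd":
        return sum(inputs.drug_cost_per_cycle[d] for d in inputs.pd_drugs) + other
    raise ValueError(f"unknown state {state!r} (expected 'pfs' or 'pd')")


def ae_burden(
    arm: str, inputs: EconomicInputs, cycle_years: float = 28.0 / 365.25
) -> tuple[float, float]:
    """Incidence-weighted one-off adverse-event cost and QALY loss.

    QALY loss per event = disutility x assumed duration
    (``ae_duration_cycles`` cycles, expressed in years).  Both components
    are applied at model entry (discount factor 1).
    """
    dur_years = inputs.ae_duration_cycles * cycle_years
    cost = 0.0
    qaly_loss = 0.0
    for ae in inputs.ae_profile:
        p = ae.incidence.get(arm, 0.0)
        cost += p * ae.cost
        qaly_loss += p * ae.disutility * dur_years
    return cost, qaly_loss


@dataclass
class ArmResult:
    """Discounted totals for one strategy."""

    arm: str
    total_cost: float
    total_qaly: float
    life_years: float = float("nan")


@dataclass
class CEResult:
    """Incremental cost-effectiveness summary (treatment vs control)."""

    treatment: ArmResult
    control: ArmResult
    delta_cost: float
    delta_qaly: float
    icer: float | None
    nmb: float
    wtp: float
    dominance: str = ""  # "", "dominant", "dominated"

    def as_dict(self) -> dict:
        return {
            "cost_treatment": self.treatment.total_cost,
            "cost_control": self.control.total_cost,
            "qaly_treatment": self.treatment.total_qaly,
            "qaly_control": self.control.total_qaly,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "dominance": self.dominance,
        }


def accrue(
    trace: StateTrace,
    arm: str,
    inputs: EconomicInputs,
    discount_annual: float | None = None,
) -> ArmResult:
    """Discounted cost and QALY totals for one arm over its trace.

    Per cycle: cost ``df * (pfs_bar * c_PFS + pd_bar * c_PD)`` (unit costs
    are per cycle) and QALYs ``df * (pfs_bar * u_PFS + pd_bar * u_PD) *
    cycle_years``; adverse-event burden enters per ``inputs.ae_mode``.
    ``discount_annual`` overrides the rate baked into the trace
    (sensitivity analyses re-discount without rebuilding occupancy).
    """
    df = trace.df if discount_annual is None else trace.discount_factors(discount_annual)
    c_pfs = state_cost_per_cycle(arm, "pfs", inputs)
    c_pd = state_cost_per_cycle(arm, "pd", inputs)
    ae_cost, ae_qaly = ae_burden(arm, inputs, cycle_years=trace.cycle_years)
    if inputs.ae_mode == "per_cycle":
        cost = float(np.sum(df * (trace.pfs_bar * (c_pfs + ae_cost) + trace.pd_bar * c_pd)))
        qaly_ae = ae_qaly  # disutility still a one-off entry adjustment
    else:
        cost = float(np.sum(df * (trace.pfs_bar * c_pfs + trace.pd_bar * c_pd))) + ae_cost
        qaly_ae = ae_qaly
    u_pfs = inputs.utilities["pfs"]
    u_pd = inputs.utilities["pd"]
    qaly = (
        float(np.sum(df * (trace.pfs_bar * u_pfs + trace.pd_bar * u_pd)) * trace.cycle_years)
        - qaly_ae
    )
    ly = float(np.sum(df * (trace.pfs_bar + trace.pd_bar)) * trace.cycle_years)
    return ArmResult(arm=arm, total_cost=cost, total_qaly=qaly, life_years=ly)


def incremental(res_trt: ArmResult, res_ctl: ArmResult, wtp: float) -> CEResult:
    """Incremental cost, QALYs, ICER, NMB and dominance labelling."""
    dc = res_trt.total_cost - res_ctl.total_cost
    de = res_trt.total_qaly - res_ctl.total_qaly
    icer = dc / de if de != 0 else None
    nmb = wtp * de - dc
    dominance = ""
    if de > 0 and dc < 0:
        dominance = "dominant"
    elif de < 0 and dc > 0:
        dominance = "dominated"
    return CEResult(
        treatment=res_trt,
        control=res_ctl,
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        nmb=nmb,
        wtp=wtp,
        dominance=dominance,
    )
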