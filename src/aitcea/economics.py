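"""Economic outcomes: costs, QALYs, discounting, and incremental comparison.

Costs and QALYs are accrued per annual cycle against the half-cycle-corrected
occupancies and discounted at ``(1+r)^-(t-1)`` — the first model year is
undiscounted. Cost components mirror the payer's ledger: specialist visits,
injection/control, first-year diagnostics, drug acquisition, symptomatic
co-medication, asthma care, and (societal perspective only) productivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArmSpec, CostParams, EconSettings, ModelConfig, UtilityParams, annual_drug_cost
from .markov import (
    ALIVE_STATES,
    ASTHMA_STATES,
    ON_EFFECT_STATES,
    ON_TREATMENT_STATES,
    CohortTrace,
    State,
    run_cohort,
)

__all__ = [
    "CostBreakdown",
    "ArmResult",
    "IncrementalResult",
    "discount_factor",
    "cycle_utility",
    "accumulate_costs",
    "accumulate_qalys",
    "run_arm",
    "run_all_arms",
    "compare",
    "COST_COMPONENTS",
]

COST_COMPONENTS = (
    "visits",
    "injection_control",
    "diagnostics",
    "treatment",
    "other_drugs",
    "asthma",
    "productivity",
)

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def discount_factor(cycle: int, rate: float) -> float:
    """Discount weight for an annual cycle: ``(1+rate)^-(cycle-1)``.

    Cycle 1 is undiscounted; `rate` is the annual discount rate applied to
    both costs and effects.
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** -(cycle - 1)


@dataclass
class CostBreakdown:
    """Per-component costs (EUR per model entrant), discounted and undiscounted."""

    undiscounted: dict[str, float] = field(default_factory=dict)
    discounted: dict[str, float] = field(default_factory=dict)

    @property
    def total_undiscounted(self) -> float:
        return sum(self.undiscounted.values())

    @property
    def total_discounted(self) -> float:
        return sum(self.discounted.values())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "component": list(COST_COMPONENTS),
                "undiscounted": [self.undiscounted.get(c, 0.0) for c in COST_COMPONENTS],
                "discounted": [self.discounted.get(c, 0.0) for c in COST_COMPONENTS],
            }
        )
        return df


@dataclass
class ArmResult:
    """Costs and QALYs of one arm under one configuration."""

    arm_key: str
    qalys_discounted: float
    qalys_undiscounted: float
    costs: CostBreakdown
    trace: CohortTrace


@dataclass
class IncrementalResult:
    """Pairwise incremental outcome (reference minus comparator)."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | str
    wtp: float
    nmb: float

    def nmb_at(self, wtp: float) -> float:
        return wtp * self.delta_qaly - self.delta_cost


def _rtss_for_state(state: State, arm: ArmSpec, off_effect_rtss: float) -> float:
    if state in (State.ON, State.COMPLETED, State.ON_ASTHMA, State.COMPLETED_ASTHMA):
        return arm.rtss
    return off_effect_rtss


def cycle_utility(
    state: State,
    arm: ArmSpec,
    u: UtilityParams,
    off_effect_rtss: float = 4.47,
) -> float:
    """Annual utility of occupying ``state`` for one year.

    In the default RSUI-proxy mode the symptom burden applies only during the
    pollen season: ``u_baseline - (season/12)*k*RTSS``, with the off-effect
    (discontinued or never-treated) symptom score applied outside the on-effect
    states, and an additive asthma decrement. In EQ-5D mode (scenario 4) flat
    year-round utilities replace the seasonal map. Negative utilities are
    clamped to zero.
    """
    if state == State.DEAD:
        return 0.0
    asthma = state in ASTHMA_STATES
    if u.utility_mode == "eq5d":
        base = u.eq5d_ait if state in ON_EFFECT_STATES else u.eq5d_symptomatic
        value = base - (u.asthma_decrement if asthma else 0.0)
    else:
        rtss = _rtss_for_state(state, arm, off_effect_rtss)
        value = (
            u.u_baseline
            - (u.season_months / 12.0) * u.k_rtss_slope * rtss
            - (u.asthma_decrement if asthma else 0.0)
        )
    if value < 0:
        import warnings

        warnings.warn(f"utility for state {state.name} clamped to 0 (was {value:.4f})")
        return 0.0
    return value


def _discount_weights(horizon: int, rate: float) -> np.ndarray:
    return np.array([discount_factor(t, rate) for t in range(1, horizon + 1)])


def accumulate_costs(
    trace: CohortTrace,
    arm: ArmSpec,
    costs: CostParams,
    settings: EconSettings,
    season_months: float,
) -> CostBreakdown:
    """Accrue per-component costs against mid-cycle occupancies.

    Component rules per cycle:

    - treatment: on-treatment share x annual drug acquisition cost;
    - visits: on-treatment share x per-arm visit count, all other alive
      patients (incl. completed) at the off-treatment rate;
    - injection/control: on-treatment share x injections/year, plus a single
      supervised first dose in cycle 1 where the product requires it;
    - diagnostics: booked once in cycle 1 for the full entering cohort in
      arms with a first-year diagnostic work-up;
    - other drugs: seasonal co-medication (loratadine + budesonide) at the
      on-effect rate while the treatment effect persists, off-effect rate
      otherwise;
    - asthma: asthmatic alive share x annual asthma cost;
    - productivity (societal perspective only): off-effect share x calibrated
      per-season saving forgone relative to treated patients.
    """
    horizon = trace.horizon
    d = _discount_weights(horizon, settings.discount_rate)

    on_trt = trace.share(ON_TREATMENT_STATES)
    on_eff = trace.share(ON_EFFECT_STATES)
    alive = trace.share(ALIVE_STATES)
    asthma = trace.share(ASTHMA_STATES)
    off_trt = alive - on_trt
    off_eff = alive - on_eff

    drug = annual_drug_cost(arm, season_months)
    per_cycle: dict[str, np.ndarray] = {}

    per_cycle["treatment"] = on_trt * drug
    per_cycle["visits"] = (
        on_trt * arm.visits_per_treatment_year * costs.c_specialist_visit
        + off_trt * costs.visits_per_year_off_treatment * costs.c_specialist_visit
    )
    inj = on_trt * arm.injections_per_treatment_year * costs.c_injection
    if arm.supervised_first_dose:
        inj = inj.copy()
        inj[0] += on_trt[0] * costs.c_injection
    per_cycle["injection_control"] = inj
    diag = np.zeros(horizon)
    if arm.diagnostic_in_year1:
        diag[0] = costs.c_diagnostics
    per_cycle["diagnostics"] = diag
    per_cycle["other_drugs"] = on_eff * (
        costs.c_loratadine_ait + costs.c_budesonide_ait
    ) + off_eff * (costs.c_loratadine_sympt + costs.c_budesonide_sympt)
    per_cycle["asthma"] = asthma * costs.c_asthma_annual
    if settings.perspective == "societal":
        per_cycle["productivity"] = off_eff * costs.productivity_saving_per_season
    else:
        per_cycle["productivity"] = np.zeros(horizon)

    breakdown = CostBreakdown()
    for comp, series in per_cycle.items():
        breakdown.undiscounted[comp] = float(series.sum())
        breakdown.discounted[comp] = float((series * d).sum())
    return breakdown


def accumulate_qalys(
    trace: CohortTrace,
    arm: ArmSpec,
    u: UtilityParams,
    settings: EconSettings,
    off_effect_rtss: float = 4.47,
) -> tuple[float, float]:
    """(discounted, undiscounted) QALYs over the horizon."""
    horizon = trace.horizon
    d = _discount_weights(horizon, settings.discount_rate)
    utilities = np.array(
        [cycle_utility(s, arm, u, off_effect_rtss=off_effect_rtss) for s in State]
    )
    per_cycle = trace.occupancy_mid @ utilities
    return float((per_cycle * d).sum()), float(per_cycle.sum())


def run_arm(config: ModelConfig, arm_key: str) -> ArmResult:
    """Run the cohort model for one arm and value costs and QALYs."""
    arm = config.arms[arm_key]
    trace = run_cohort(arm, config.clinical, config.settings, arm_key=arm_key)
    off_rtss = config.arms["symptomatic"].rtss
    costs = accumulate_costs(
        trace, arm, config.costs, config.settings, config.utility.season_months
    )
    q_disc, q_undisc = accumulate_qalys(
        trace, arm, config.utility, config.settings, off_effect_rtss=off_rtss
    )
    return ArmResult(
        arm_key=arm_key,
        qalys_discounted=q_disc,
        qalys_undiscounted=q_undisc,
        costs=costs,
        trace=trace,
    )


def run_all_arms(config: ModelConfig) -> dict[str, ArmResult]:
    return {key: run_arm(config, key) for key in config.arms}


def _icer(delta_cost: float, delta_qaly: float) -> float | str:
    if delta_qaly == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    return delta_cost / delta_qaly


def compare(
    reference: ArmResult,
    comparator: ArmResult,
    wtp: float = 20000.0,
    discounted: bool = True,
) -> IncrementalResult:
    """Incremental comparison (reference minus comparator) with ICER and NMB."""
    if discounted:
        dc = reference.costs.total_discounted - comparator.costs.total_discounted
        dq = reference.qalys_discounted - comparator.qalys_discounted
    else:
        dc = reference.costs.total_undiscounted - comparator.costs.total_undiscounted
        dq = reference.qalys_undiscounted - comparator.qalys_undiscounted
    return IncrementalResult(
        reference=reference.arm_key,
        comparator=comparator.arm_key,
        delta_cost=dc,
        delta_qaly=dq,
        icer=_icer(dc, dq),
        wtp=wtp,
        nmb=wtp * dq - dc,
    )
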