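"""Markov cohort engine: annual-cycle state transitions and half-cycle traces.

The state space crosses a treatment regime (on treatment during the 3-year
course, completed treatment, discontinued, or symptomatic-only) with a chronic
asthma flag, plus a single absorbing dead state. Within a cycle, events
compose multiplicatively in the order death -> discontinuation -> asthma
onset. Discontinuation applies in treatment years 1-2 only; patients still on
treatment at the end of year 3 are relabelled "completed" at the cycle
boundary, so year-3 state time still counts as on-treatment.

All state-time accruals downstream use the half-cycle-corrected mid-cycle
occupancy, the average of cycle-start and cycle-end occupancy, approximating
events spread uniformly over the year.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .config import ArmSpec, ClinicalParams, EconSettings, SYMPTOMATIC

__all__ = [
    "State",
    "CohortTrace",
    "transition_matrix",
    "run_cohort",
    "effect_person_years",
    "N_STATES",
]


class State(IntEnum):
    """Cohort health states: regime x asthma, plus absorbing death."""

    ON = 0
    COMPLETED = 1
    DISCONTINUED = 2
    SYMPTOMATIC = 3
    ON_ASTHMA = 4
    COMPLETED_ASTHMA = 5
    DISCONTINUED_ASTHMA = 6
    SYMPTOMATIC_ASTHMA = 7
    DEAD = 8


N_STATES = len(State)

# State groupings used throughout costing and utility valuation.
ON_TREATMENT_STATES = (State.ON, State.ON_ASTHMA)
ON_EFFECT_STATES = (State.ON, State.COMPLETED, State.ON_ASTHMA, State.COMPLETED_ASTHMA)
OFF_EFFECT_STATES = (
    State.DISCONTINUED,
    State.SYMPTOMATIC,
    State.DISCONTINUED_ASTHMA,
    State.SYMPTOMATIC_ASTHMA,
)
ASTHMA_STATES = (
    State.ON_ASTHMA,
    State.COMPLETED_ASTHMA,
    State.DISCONTINUED_ASTHMA,
    State.SYMPTOMATIC_ASTHMA,
)
ALIVE_STATES = tuple(s for s in State if s != State.DEAD)


@dataclass(frozen=True)
class CohortTrace:
    """Start-of-cycle and mid-cycle state occupancies over the model horizon.

    ``occupancy_start[t-1, s]`` is the proportion of the cohort in state ``s``
    at the start of cycle ``t`` (1-based); ``occupancy_mid`` is the
    half-cycle-corrected occupancy used for all accruals.
    """

    occupancy_start: np.ndarray  # (horizon, N_STATES)
    occupancy_mid: np.ndarray  # (horizon, N_STATES)

    @property
    def horizon(self) -> int:
        return self.occupancy_start.shape[0]

    def share(self, states: tuple[State, ...], mid: bool = True) -> np.ndarray:
        """Per-cycle occupancy summed over a group of states."""
        occ = self.occupancy_mid if mid else self.occupancy_start
        return occ[:, list(states)].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, start_occupancy, mid_occupancy) table."""
        rows = []
        for t in range(self.horizon):
            for s in State:
                rows.append(
                    {
                        "cycle": t + 1,
                        "state": s.name.lower(),
                        "start_occupancy": self.occupancy_start[t, s],
                        "mid_occupancy": self.occupancy_mid[t, s],
                    }
                )
        return pd.DataFrame(rows)


def _discontinuation_prob(arm: ArmSpec, cycle: int, treatment_years: int) -> float:
    """Annual probability of stopping treatment during `cycle` (1-based).

    Discontinuation is observed in treatment years 1 and 2 only; year-3
    patients complete the course.
    """
    if cycle == 1:
        return arm.disc_y1
    if cycle == 2:
        return arm.disc_y2
    return 0.0


def _dynamics_matrix(
    arm: ArmSpec, clinical: ClinicalParams, cycle: int, treatment_years: int
) -> np.ndarray:
    """Within-cycle transition matrix (death -> discontinuation -> asthma).

    Does not include the end-of-treatment relabel; see
    :func:`_relabel_matrix`. Patients discontinuing within the cycle are
    exposed to the off-treatment asthma risk for that same cycle.
    """
    pd_all = clinical.p_death_all
    pd_asthma = clinical.p_death_asthma
    p_a_on = clinical.p_asthma_symptomatic * clinical.rr_asthma_ait
    p_a_off = clinical.p_asthma_symptomatic
    disc = _discontinuation_prob(arm, cycle, treatment_years)

    for name, p in (("death", pd_all), ("asthma-death", pd_asthma), ("asthma", p_a_on)):
        if not 0 <= p <= 1:
            raise ValueError(f"composed {name} probability {p} outside [0, 1]")

    M = np.zeros((N_STATES, N_STATES))
    s = 1.0 - pd_all  # survival without asthma
    sa = 1.0 - pd_asthma  # survival with asthma

    M[State.ON, State.DEAD] = pd_all
    M[State.ON, State.ON] = s * (1 - disc) * (1 - p_a_on)
    M[State.ON, State.ON_ASTHMA] = s * (1 - disc) * p_a_on
    M[State.ON, State.DISCONTINUED] = s * disc * (1 - p_a_off)
    M[State.ON, State.DISCONTINUED_ASTHMA] = s * disc * p_a_off

    M[State.COMPLETED, State.DEAD] = pd_all
    M[State.COMPLETED, State.COMPLETED] = s * (1 - p_a_on)
    M[State.COMPLETED, State.COMPLETED_ASTHMA] = s * p_a_on

    for src, dst_asthma in (
        (State.DISCONTINUED, State.DISCONTINUED_ASTHMA),
        (State.SYMPTOMATIC, State.SYMPTOMATIC_ASTHMA),
    ):
        M[src, State.DEAD] = pd_all
        M[src, src] = s * (1 - p_a_off)
        M[src, dst_asthma] = s * p_a_off

    M[State.ON_ASTHMA, State.DEAD] = pd_asthma
    M[State.ON_ASTHMA, State.ON_ASTHMA] = sa * (1 - disc)
    M[State.ON_ASTHMA, State.DISCONTINUED_ASTHMA] = sa * disc

    for src in (State.COMPLETED_ASTHMA, State.DISCONTINUED_ASTHMA, State.SYMPTOMATIC_ASTHMA):
        M[src, State.DEAD] = pd_asthma
        M[src, src] = sa

    M[State.DEAD, State.DEAD] = 1.0
    return M


def _relabel_matrix(cycle: int, treatment_years: int) -> np.ndarray:
    """Cycle-boundary relabel: completing the course moves ON -> COMPLETED."""
    R = np.eye(N_STATES)
    if cycle == treatment_years:
        R[State.ON, State.ON] = 0.0
        R[State.ON, State.COMPLETED] = 1.0
        R[State.ON_ASTHMA, State.ON_ASTHMA] = 0.0
        R[State.ON_ASTHMA, State.COMPLETED_ASTHMA] = 1.0
    return R


def transition_matrix(
    arm: ArmSpec,
    clinical: ClinicalParams,
    cycle: int,
    treatment_years: int = 3,
    horizon_years: int = 9,
) -> np.ndarray:
    """Full annual transition matrix for ``cycle`` (start of cycle t to start of t+1).

    Includes the end-of-treatment relabel at the year-3 boundary; rows sum
    to one.
    """
    if not 1 <= cycle <= horizon_years:
        raise ValueError(f"cycle must be in 1..{horizon_years}, got {cycle}")
    M = _dynamics_matrix(arm, clinical, cycle, treatment_years) @ _relabel_matrix(
        cycle, treatment_years
    )
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows do not sum to 1")
    return M


def run_cohort(
    arm: ArmSpec,
    clinical: ClinicalParams,
    settings: EconSettings,
    arm_key: str | None = None,
) -> CohortTrace:
    """Propagate the cohort over the horizon and return the half-cycle trace.

    The cohort starts fully in the on-treatment state for AIT arms, or in the
    symptomatic-only state when the arm carries no treatment course (no
    discontinuation, no acquisition cost), e.g. the symptomatic comparator.
    """
    horizon = settings.horizon_years
    ty = settings.treatment_years

    is_symptomatic_only = (
        arm_key == SYMPTOMATIC
        if arm_key is not None
        else (
            arm.disc_y1 == 0
            and arm.disc_y2 == 0
            and arm.drug_cost_per_month == 0
            and not arm.fixed_annual_drug_cost
            and not arm.diagnostic_in_year1
        )
    )

    start = np.zeros((horizon, N_STATES))
    mid = np.zeros((horizon, N_STATES))
    x = np.zeros(N_STATES)
    x[State.SYMPTOMATIC if is_symptomatic_only else State.ON] = 1.0

    for t in range(1, horizon + 1):
        D = _dynamics_matrix(arm, clinical, t, ty)
        end = x @ D
        start[t - 1] = x
        mid[t - 1] = 0.5 * (x + end)
        x = end @ _relabel_matrix(t, ty)

    return CohortTrace(occupancy_start=start, occupancy_mid=mid)


def effect_person_years(
    trace: CohortTrace, discount_rate: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle on-effect and off-effect person-years (mid-cycle occupancy).

    On-effect pools on-treatment and completed-treatment states (the treatment
    effect is carried into the post-treatment years); off-effect pools
    discontinued and symptomatic-only states. With ``discount_rate`` set, each
    cycle is weighted by the model's discount convention (year 1 undiscounted).
    """
    on = trace.share(ON_EFFECT_STATES)
    off = trace.share(OFF_EFFECT_STATES)
    if discount_rate is not None:
        t = np.arange(1, trace.horizon + 1)
        d = (1.0 + discount_rate) ** -(t - 1)
        on = on * d
        off = off * d
    return on, off
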