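"""Discounted cost, life-year and QALY accrual along a cohort trace, and ICER.

Costs follow the societal perspective by default: direct medical costs
(statins, CAC tests, first-year and follow-up event care) plus direct
non-medical costs borne by patients; the provider perspective drops the
non-medical block. Rewards accrue for the state occupied during each annual
cycle; the first year is undiscounted and later cycles are discounted at
the configured annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    COMBINED_STATES,
    MI_STATES,
    STROKE_STATES,
    Cell,
    MarkovTrace,
    State,
    Tunnel,
    _treatment_for,
)
from .parameters import ParameterSet

__all__ = [
    "ArmResult",
    "ICERResult",
    "discount_factor",
    "accrue_cycle",
    "evaluate_arm",
    "compute_icer",
]


def discount_factor(cycle_index: int, rate: float) -> float:
    """(1 + rate)^(-t): the first year (cycle 0) is undiscounted."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return float((1.0 + rate) ** (-cycle_index))


def _statin_cost(cell: Cell, arm: str, params: ParameterSet) -> float:
    c = params.costs
    if cell.state is State.DEAD:
        return 0.0
    if cell.state is not State.NO_CVD:
        # everyone post-event is on high potency
        return c.statin_high_annual if params.options.post_event_statin_cost else 0.0
    treatment = _treatment_for(cell.category, arm)
    if treatment == "none":
        return 0.0
    price = (
        c.statin_high_annual if treatment == "high_potency" else c.statin_moderate_annual
    )
    if params.options.statin_cost_scaled_by_adherence:
        price *= params.adherence_for(arm, cell.category)
    return price


def _event_cost(cell: Cell, params: ParameterSet) -> float:
    """Event-care cost for one cell-year: first-year (incident or recurrent)
    costs for tunnel phases, follow-up costs otherwise; combined states add
    the other condition's follow-up to the incident event's first-year cost."""
    c = params.costs
    societal = params.perspective == "societal"
    nm = lambda v: v if societal else 0.0  # noqa: E731

    st, tu = cell.state, cell.tunnel
    if st in (State.NO_CVD, State.DEAD):
        return 0.0
    if st is State.POST_MI:
        if tu is Tunnel.FY:
            return c.mi_first_year + nm(c.nonmed_mi_first_year)
        return c.mi_followup_annual + nm(c.nonmed_mi_followup)
    if st is State.POST_REC_MI:
        if tu is Tunnel.FY:
            return c.mi_recurrent_first_year + nm(c.nonmed_mi_first_year)
        return c.mi_followup_annual + nm(c.nonmed_mi_followup)
    if st is State.POST_STROKE:
        if tu is Tunnel.FY:
            return c.stroke_first_year + nm(c.nonmed_stroke_first_year)
        return c.stroke_followup_annual + nm(c.nonmed_stroke_followup)
    if st is State.POST_REC_STROKE:
        if tu is Tunnel.FY:
            return c.stroke_recurrent_first_year + nm(c.nonmed_stroke_first_year)
        return c.stroke_followup_annual + nm(c.nonmed_stroke_followup)

    # combined MI-and-stroke states
    followup_both = (
        c.mi_followup_annual
        + c.stroke_followup_annual
        + nm(c.nonmed_mi_followup + c.nonmed_stroke_followup)
    )
    if tu is Tunnel.NONE:
        return followup_both
    recurrent = st is State.POST_REC_MI_STROKE
    if tu is Tunnel.FY_MI:
        mi_fy = c.mi_recurrent_first_year if recurrent else c.mi_first_year
        return (
            mi_fy
            + c.stroke_followup_annual
            + nm(c.nonmed_mi_first_year + c.nonmed_stroke_followup)
        )
    stroke_fy = c.stroke_recurrent_first_year if recurrent else c.stroke_first_year
    return (
        stroke_fy
        + c.mi_followup_annual
        + nm(c.nonmed_stroke_first_year + c.nonmed_mi_followup)
    )


def _utility(cell: Cell, age: float, params: ParameterSet) -> float:
    u = params.utilities
    st = cell.state
    if st is State.DEAD:
        return 0.0
    if st is State.NO_CVD:
        return u.no_cvd(age)
    if st in MI_STATES:
        return u.post_mi
    if st in STROKE_STATES:
        return u.post_stroke
    return u.post_mi_and_stroke


def _disutility(cell: Cell, params: ParameterSet) -> float:
    """One-off recurrence disutility applied to tunnel mass. First events
    (entry into post-MI / post-stroke) carry none; recurrences carry the
    event-specific decrement; any event on top of a prior event carries the
    with-prior-event decrement."""
    u = params.utilities
    if not cell.in_tunnel:
        return 0.0
    if cell.state is State.POST_REC_MI:
        return u.disutil_recurrent_mi
    if cell.state is State.POST_REC_STROKE:
        return u.disutil_recurrent_stroke
    if cell.state in COMBINED_STATES:
        return u.disutil_recurrent_with_prior_event
    return 0.0


def _reward_vectors(cells: list[Cell], arm: str, params: ParameterSet):
    cost_vec = np.array(
        [_statin_cost(c, arm, params) + _event_cost(c, params) for c in cells]
    )
    disutil_vec = np.array([_disutility(c, params) for c in cells])
    alive_vec = np.array([c.state is not State.DEAD for c in cells], dtype=float)
    return cost_vec, disutil_vec, alive_vec


def accrue_cycle(
    occupancy: np.ndarray,
    cells: list[Cell],
    arm: str,
    age: float,
    test_mass: float,
    params: ParameterSet,
) -> tuple[float, float, float]:
    """Undiscounted (cost, qaly, life-years) for one cycle's occupancy row."""
    cost_vec, disutil_vec, alive_vec = _reward_vectors(cells, arm, params)
    util_vec = np.array([_utility(c, age, params) for c in cells])
    cost = float(occupancy @ cost_vec) + test_mass * params.costs.cac_test
    qaly = float(occupancy @ (util_vec - disutil_vec))
    ly = float(occupancy @ alive_vec)
    return cost, qaly, ly


@dataclass
class ArmResult:
    """Discounted totals and per-cycle ledger for one strategy arm."""

    arm: str
    total_cost: float
    life_years: float
    qalys: float
    ledger: pd.DataFrame

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs exceed life-years")


def evaluate_arm(trace: MarkovTrace, params: ParameterSet | None = None) -> ArmResult:
    """Discounted sums of per-cycle rewards over the whole horizon."""
    params = params or trace.params
    cost_vec, disutil_vec, alive_vec = _reward_vectors(trace.cells, trace.arm, params)
    n_cycles = trace.n_cycles
    occ = trace.occupancy

    cost = np.empty(n_cycles)
    qaly = np.empty(n_cycles)
    ly = np.empty(n_cycles)
    for t in range(n_cycles):
        age = trace.ages[t]
        util_vec = np.array([_utility(c, age, params) for c in trace.cells])
        row = occ[t]
        if params.options.half_cycle_correction:
            row = 0.5 * (occ[t] + occ[t + 1])
        cost[t] = row @ cost_vec + trace.test_mass[t] * params.costs.cac_test
        qaly[t] = row @ (util_vec - disutil_vec)
        ly[t] = row @ alive_vec

    df = np.array([discount_factor(t, params.discount_rate) for t in range(n_cycles)])
    ledger = pd.DataFrame(
        {
            "cycle": np.arange(n_cycles),
            "age": trace.ages,
            "discount": df,
            "cost": cost,
            "qaly": qaly,
            "life_years": ly,
        }
    )
    return ArmResult(
        arm=trace.arm,
        total_cost=float(cost @ df),
        life_years=float(ly @ df),
        qalys=float(qaly @ df),
        ledger=ledger,
    )


@dataclass
class ICERResult:
    """Incremental comparison of a comparator arm against a reference arm."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    verdict: str
    wtp_threshold: float

    @property
    def net_monetary_benefit(self) -> float:
        return self.wtp_threshold * self.delta_qaly - self.delta_cost


def compute_icer(
    reference: ArmResult, comparator: ArmResult, wtp: float
) -> ICERResult:
    """Delta cost / delta QALY with dominance classification.

    dominant: cheaper and more effective; dominated: costlier and less
    effective; otherwise the ICER is compared with the willingness-to-pay
    threshold via net monetary benefit. A zero QALY difference leaves the
    ICER undefined and the verdict follows the cost sign.
    """
    dc = comparator.total_cost - reference.total_cost
    dq = comparator.qalys - reference.qalys
    if dc < 0 and dq > 0:
        return ICERResult(dc, dq, dc / dq, "dominant", wtp)
    if dc > 0 and dq < 0:
        return ICERResult(dc, dq, dc / dq, "dominated", wtp)
    if dq == 0:
        verdict = "cost_effective" if dc <= 0 else "not_cost_effective"
        return ICERResult(dc, dq, None, verdict, wtp)
    icer = dc / dq
    nmb = wtp * dq - dc
    verdict = "cost_effective" if nmb >= 0 else "not_cost_effective"
    return ICERResult(dc, dq, icer, verdict, wtp)
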