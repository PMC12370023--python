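"""Decision-tree stratification and annual-cycle Markov cohort simulation.

The cohort is a vector of fractional occupancies over cells
``(health state, tunnel phase, risk category)``. Eight health states are
modelled: No CVD, post (recurrent) non-fatal MI, post (recurrent) non-fatal
stroke, post (recurrent) MI-and-stroke, and Dead. Tunnel phases mark the
cycle immediately after an acute event, when first-year risks, costs and
recurrence disutilities apply; the combined states carry the incident event
(MI vs stroke) in their tunnel phase so first-year costing can distinguish
it.

Conventions (see docs/methods.md): annual cycles from age 40 to 75; events
at cycle end; rewards accrue for the state occupied during the cycle; the
background life-table mortality is added marginally to every alive cell;
after any CVD event the cohort is on a high-potency statin. The CAC=0
stratum of the screening arm is reassessed every ``rescreen_interval`` years
from age 45, converting to CAC 1-99 / CAC >= 100 by the attained-age band of
the progression table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .parameters import (
    ARMS,
    CATEGORIES,
    TREATMENT_BY_POSITION,
    EventIncidences,
    ParameterSet,
    StatinEffect,
    ValidationError,
)

__all__ = [
    "State",
    "Tunnel",
    "Cell",
    "TransitionEvents",
    "MarkovTrace",
    "MassConservationError",
    "build_cells",
    "stratify_initial",
    "rate_to_probability",
    "apply_statin_effect",
    "build_transitions",
    "rescreen_cac_zero",
    "run_markov",
]

MASS_TOL = 1e-9


class State(str, Enum):
    NO_CVD = "no_cvd"
    POST_MI = "post_mi"
    POST_REC_MI = "post_recurrent_mi"
    POST_STROKE = "post_stroke"
    POST_REC_STROKE = "post_recurrent_stroke"
    POST_MI_STROKE = "post_mi_stroke"
    POST_REC_MI_STROKE = "post_recurrent_mi_stroke"
    DEAD = "dead"


class Tunnel(str, Enum):
    NONE = "none"          # beyond the first post-event year (or No CVD)
    FY = "first_year"      # first year after the event
    FY_MI = "first_year_mi"          # combined state entered via an MI
    FY_STROKE = "first_year_stroke"  # combined state entered via a stroke

SINGLE_EVENT_STATES = (State.POST_MI, State.POST_REC_MI, State.POST_STROKE,
                       State.POST_REC_STROKE)
COMBINED_STATES = (State.POST_MI_STROKE, State.POST_REC_MI_STROKE)
MI_STATES = (State.POST_MI, State.POST_REC_MI)
STROKE_STATES = (State.POST_STROKE, State.POST_REC_STROKE)


@dataclass(frozen=True)
class Cell:
    state: State
    tunnel: Tunnel
    category: str | None  # None only for DEAD

    @property
    def in_tunnel(self) -> bool:
        return self.tunnel is not Tunnel.NONE


def build_cells(arm: str) -> list[Cell]:
    """Enumerate the occupancy cells for one strategy arm (Dead is last)."""
    cats = CATEGORIES[arm]
    cells: list[Cell] = [Cell(State.NO_CVD, Tunnel.NONE, c) for c in cats]
    for state in SINGLE_EVENT_STATES:
        for tunnel in (Tunnel.FY, Tunnel.NONE):
            cells.extend(Cell(state, tunnel, c) for c in cats)
    for state in COMBINED_STATES:
        for tunnel in (Tunnel.FY_MI, Tunnel.FY_STROKE, Tunnel.NONE):
            cells.extend(Cell(state, tunnel, c) for c in cats)
    cells.append(Cell(State.DEAD, Tunnel.NONE, None))
    return cells


@dataclass
class TransitionEvents:
    """Marginal per-cycle event probabilities for one (state, stratum, age)."""

    p_mi: float
    p_stroke: float
    p_cvd_death: float
    p_background_death: float
    p_stay: float

    def validate(self) -> None:
        total = (self.p_mi + self.p_stroke + self.p_cvd_death
                 + self.p_background_death + self.p_stay)
        for name in ("p_mi", "p_stroke", "p_cvd_death", "p_background_death", "p_stay"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"{name}={v} outside [0,1]")
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"transition probabilities sum to {total}, not 1")


class MassConservationError(RuntimeError):
    """Total cohort mass drifted beyond tolerance during the simulation."""


def rate_to_probability(rate: float, duration: float = 1.0) -> float:
    """Convert a per person-year rate to a per-cycle probability, 1 - exp(-r*t)."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    return -math.expm1(-rate * duration)


def apply_statin_effect(
    base: EventIncidences, effect: StatinEffect | None, adherence: float = 1.0
) -> EventIncidences:
    """Scale first-event rates by the cohort-effective relative risk.

    The adherent fraction experiences the full relative risk, the rest none:
    effective RR = adherence * rr + (1 - adherence). ``effect=None`` (no
    statin) returns the base incidences unchanged.
    """
    if not 0 <= adherence <= 1:
        raise ValueError(f"adherence must be in [0,1], got {adherence}")
    if effect is None:
        return EventIncidences(base.mi, base.stroke, base.cvd_death)
    blend = lambda rr: adherence * rr + (1.0 - adherence)  # noqa: E731
    return EventIncidences(
        mi=base.mi * blend(effect.rr_mi),
        stroke=base.stroke * blend(effect.rr_stroke),
        cvd_death=base.cvd_death * blend(effect.rr_cvd_death),
    )


def _first_event_incidences(arm: str, category: str, params: ParameterSet) -> EventIncidences:
    """Stratum incidences for the No-CVD state: the screening arm uses its
    CAC stratum, the current-practice arm the overall no-statin incidences
    for every LDL category."""
    if arm == "cac_screening":
        return params.incidence[category]
    return params.incidence["no_statin_overall"]


def _treatment_for(category: str, arm: str) -> str:
    idx = CATEGORIES[arm].index(category)
    return TREATMENT_BY_POSITION[idx]


_POTENCY_KEY = {"high_potency": "high", "moderate_potency": "moderate"}


def _statin_effect_for(treatment: str, params: ParameterSet) -> StatinEffect | None:
    if treatment == "none":
        return None
    return params.statin_effect[_POTENCY_KEY[treatment]]


def _combined_probs(params: ParameterSet):
    """Post MI-and-stroke probabilities: element-wise maximum of the two
    single-event profiles, the MI component driving recurrence and the
    stroke component the other-event channel."""
    mi = params.post_event["post_mi"]
    st = params.post_event["post_stroke"]
    p_mi_event = max(mi.recurrent_same, st.other_event)
    p_stroke_event = max(mi.other_event, st.recurrent_same)
    p_death = max(mi.cvd_death, st.cvd_death)
    return p_mi_event, p_stroke_event, p_death


def _scaled_rr(p_mi: float, p_stroke: float, p_death: float,
               effect: StatinEffect) -> tuple[float, float, float]:
    return (p_mi * effect.rr_mi, p_stroke * effect.rr_stroke,
            p_death * effect.rr_cvd_death)


def build_transitions(
    state: State,
    tunnel: Tunnel,
    category: str,
    age: float,
    params: ParameterSet,
    arm: str,
) -> TransitionEvents:
    """Marginal event probabilities for one occupancy cell at one age.

    The residual is assigned to ``p_stay``; if the marginal probabilities
    exceed 1 they are scaled proportionally (which never triggers at the
    base-case magnitudes).
    """
    if not params.start_age <= age <= params.end_age:
        raise ValidationError(f"age {age} outside model horizon")
    if state is State.DEAD:
        return TransitionEvents(0.0, 0.0, 0.0, 0.0, 1.0)

    q = params.life_table.prob(age)
    high = params.statin_effect["high"]

    if state is State.NO_CVD:
        base = _first_event_incidences(arm, category, params)
        eff = _statin_effect_for(_treatment_for(category, arm), params)
        if arm == "current_practice" and not params.options.cp_first_event_rr:
            eff = None  # first-event risk identical across LDL categories
        adh = params.adherence_for(arm, category)
        inc = apply_statin_effect(base, eff, adh)
        p_mi = rate_to_probability(inc.mi, params.cycle_years)
        p_stroke = rate_to_probability(inc.stroke, params.cycle_years)
        p_death = rate_to_probability(inc.cvd_death, params.cycle_years)
    else:
        if state in COMBINED_STATES:
            p_mi, p_stroke, p_death = _combined_probs(params)
        else:
            pe = params.post_event["post_mi" if state in MI_STATES else "post_stroke"]
            if state in MI_STATES:
                p_mi, p_stroke, p_death = pe.recurrent_same, pe.other_event, pe.cvd_death
            else:
                p_mi, p_stroke, p_death = pe.other_event, pe.recurrent_same, pe.cvd_death
        if tunnel is Tunnel.NONE:
            mode = params.options.post_event_ongoing
            if mode == "baseline":
                base = apply_statin_effect(
                    _first_event_incidences(arm, category, params), high)
                p_mi = rate_to_probability(base.mi, params.cycle_years)
                p_stroke = rate_to_probability(base.stroke, params.cycle_years)
                p_death = rate_to_probability(base.cvd_death, params.cycle_years)
            else:
                if mode.startswith("quiescent"):
                    p_mi = p_stroke = 0.0  # no recurrent events beyond year 1
                if mode.endswith("with_rr"):
                    p_mi, p_stroke, p_death = _scaled_rr(p_mi, p_stroke, p_death, high)

    total = p_mi + p_stroke + p_death + q
    if total > 1.0:
        scale = 1.0 / total
        p_mi, p_stroke, p_death, q = (p_mi * scale, p_stroke * scale,
                                      p_death * scale, q * scale)
        total = 1.0
    ev = TransitionEvents(p_mi, p_stroke, p_death, q, 1.0 - total)
    ev.validate()
    return ev


# ---------------------------------------------------------------------------
# trace container


@dataclass
class MarkovTrace:
    """Per-cycle occupancy of one strategy arm.

    ``occupancy`` has one row per cycle plus a terminal row (the cohort after
    the last transition, used only by the half-cycle correction);
    ``test_mass[t]`` is the fraction of the cohort billed a CAC test during
    cycle ``t``.
    """

    arm: str
    cells: list[Cell]
    occupancy: np.ndarray  # (n_cycles + 1, n_cells)
    ages: np.ndarray       # (n_cycles,)
    test_mass: np.ndarray  # (n_cycles,)
    params: ParameterSet = field(repr=False)

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    @property
    def dead_index(self) -> int:
        return len(self.cells) - 1

    def alive_mass(self) -> np.ndarray:
        occ = self.occupancy[: self.n_cycles]
        return occ.sum(axis=1) - occ[:, self.dead_index]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell occupancy: cycle, age, state, tunnel, category, statin, mass."""
        rows = []
        for t in range(self.n_cycles):
            for j, cell in enumerate(self.cells):
                mass = self.occupancy[t, j]
                if mass == 0:
                    continue
                statin = (
                    "none"
                    if cell.state is State.DEAD
                    else "high_potency"
                    if cell.state is not State.NO_CVD
                    else _treatment_for(cell.category, self.arm)
                )
                rows.append(
                    {
                        "cycle": t,
                        "age": self.ages[t],
                        "state": cell.state.value,
                        "tunnel": cell.tunnel.value,
                        "category": cell.category,
                        "statin": statin,
                        "mass": mass,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# engine


def stratify_initial(arm: str, params: ParameterSet) -> np.ndarray:
    """Cycle-0 occupancy: all mass in No CVD, split by the decision tree."""
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}")
    cells = build_cells(arm)
    mass = np.zeros(len(cells))
    strat = params.initial[arm]
    for j, cell in enumerate(cells):
        if cell.state is State.NO_CVD:
            mass[j] = strat.category_probs[cell.category]
    return mass


def rescreen_cac_zero(
    mass: np.ndarray, cells: list[Cell], age: float, params: ParameterSet
) -> tuple[np.ndarray, float]:
    """Reassess the CAC=0 No-CVD stratum, converting by the attained-age band.

    Returns the updated occupancy and the rescreened mass (for test costing).
    Conversion moves mass into the CAC 1-99 (moderate statin) and CAC >= 100
    (high statin) No-CVD cells; its first-event risk switches with it.
    """
    band = params.cac_progression.band_for(age)
    idx = {(c.state, c.tunnel, c.category): j for j, c in enumerate(cells)}
    j0 = idx[(State.NO_CVD, Tunnel.NONE, "cac_0")]
    j1 = idx[(State.NO_CVD, Tunnel.NONE, "cac_1_99")]
    j2 = idx[(State.NO_CVD, Tunnel.NONE, "cac_ge100")]
    m0 = mass[j0]
    if m0 == 0:
        return mass, 0.0
    out = mass.copy()
    out[j1] += m0 * band.p_to_1_99
    out[j2] += m0 * band.p_to_ge100
    out[j0] = m0 * (1.0 - band.p_to_1_99 - band.p_to_ge100)
    return out, float(m0)


def _transition_structure(arm: str, cells: list[Cell], params: ParameterSet):
    """Dense one-cycle transition matrix (background mortality excluded),
    plus the per-cell event-probability sums and residual destinations."""
    n = len(cells)
    idx = {(c.state, c.tunnel, c.category): j for j, c in enumerate(cells)}
    dead = n - 1
    T = np.zeros((n, n))
    event_sum = np.zeros(n)
    res_dest = np.zeros(n, dtype=int)

    for j, cell in enumerate(cells):
        if cell.state is State.DEAD:
            T[j, j] = 1.0
            res_dest[j] = j
            continue
        ev = build_transitions(cell.state, cell.tunnel, cell.category,
                               params.start_age, params, arm)
        c = cell.category
        if cell.state is State.NO_CVD:
            mi_dest = idx[(State.POST_MI, Tunnel.FY, c)]
            stroke_dest = idx[(State.POST_STROKE, Tunnel.FY, c)]
            stay = j
        elif cell.state in MI_STATES:
            mi_dest = idx[(State.POST_REC_MI, Tunnel.FY, c)]
            stroke_dest = idx[(State.POST_MI_STROKE, Tunnel.FY_STROKE, c)]
            stay = idx[(cell.state, Tunnel.NONE, c)]
        elif cell.state in STROKE_STATES:
            mi_dest = idx[(State.POST_MI_STROKE, Tunnel.FY_MI, c)]
            stroke_dest = idx[(State.POST_REC_STROKE, Tunnel.FY, c)]
            stay = idx[(cell.state, Tunnel.NONE, c)]
        else:  # combined states
            mi_dest = idx[(State.POST_REC_MI_STROKE, Tunnel.FY_MI, c)]
            stroke_dest = idx[(State.POST_REC_MI_STROKE, Tunnel.FY_STROKE, c)]
            stay = idx[(cell.state, Tunnel.NONE, c)]

        T[j, mi_dest] += ev.p_mi
        T[j, stroke_dest] += ev.p_stroke
        T[j, dead] += ev.p_cvd_death
        T[j, stay] += ev.p_stay + ev.p_background_death  # q re-added per age below
        event_sum[j] = ev.p_mi + ev.p_stroke + ev.p_cvd_death
        res_dest[j] = stay
    return T, event_sum, res_dest


def run_markov(arm: str, params: ParameterSet) -> MarkovTrace:
    """Propagate the cohort over the full horizon; conserves mass to 1e-9."""
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}")
    cells = build_cells(arm)
    n = len(cells)
    dead = n - 1
    n_cycles = int(round((params.end_age - params.start_age) / params.cycle_years))
    T, event_sum, res_dest = _transition_structure(arm, cells, params)
    alive = np.arange(n) != dead

    occupancy = np.zeros((n_cycles + 1, n))
    ages = params.start_age + params.cycle_years * np.arange(n_cycles)
    test_mass = np.zeros(n_cycles)

    m = stratify_initial(arm, params)
    total0 = m.sum()
    if arm == "cac_screening":
        test_mass[0] = total0  # baseline scan for everyone entering the tree

    band_max = max(r.age_hi for r in params.cac_progression.rows)
    band_min = min(r.age_lo for r in params.cac_progression.rows)

    for t in range(n_cycles):
        age = ages[t]
        if (
            arm == "cac_screening"
            and t > 0
            and t % params.rescreen_interval == 0
            and band_min <= age <= band_max
        ):
            m, rescreened = rescreen_cac_zero(m, cells, age, params)
            if params.options.rescreen_test_costed:
                test_mass[t] = rescreened
        occupancy[t] = m

        q = params.life_table.prob(age)
        v = m @ T
        # background mortality: each alive cell sends q of its mass to Dead,
        # taken out of its residual (stay) destination
        v[dead] += q * (m.sum() - m[dead])
        adj = np.zeros(n)
        np.add.at(adj, res_dest[alive], (m * q)[alive])
        v -= adj
        over = np.nonzero(alive & (m > 0) & (event_sum + q > 1.0 + 1e-15))[0]
        for j in over:
            # proportional competing-risk scaling: undo the marginal update
            # for this cell and redo it with events and q scaled to sum to 1
            scale = 1.0 / (event_sum[j] + q)
            v -= m[j] * T[j]
            v[dead] -= m[j] * q
            v[res_dest[j]] += m[j] * q
            events_row = T[j].copy()
            events_row[res_dest[j]] -= 1.0 - event_sum[j]
            v += m[j] * scale * events_row
            v[dead] += m[j] * q * scale
        m = v
        if abs(m.sum() - total0) > MASS_TOL:
            raise MassConservationError(
                f"cycle {t}: total mass {m.sum():.12f} != {total0:.12f}"
            )
        if occupancy[t, dead] - 1e-12 > m[dead]:
            raise MassConservationError(f"cycle {t}: dead mass decreased")

    occupancy[n_cycles] = m
    return MarkovTrace(arm, cells, occupancy, ages, test_mass, params)
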