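"""Cohort engine: stratification, transitions, rescreening, Markov run."""

import math

import numpy as np
import pytest

from cacscreen import rate_to_probability, run_markov, stratify_initial
from cacscreen.cohort import (
    State,
    Tunnel,
    apply_statin_effect,
    build_cells,
    build_transitions,
    rescreen_cac_zero,
)
from cacscreen.economics import evaluate_arm
from cacscreen.parameters import EventIncidences, LifeTable, ValidationError


def geometric_life_years(rate: float, n: int = 35) -> float:
    return sum((1 + rate) ** (-t) for t in range(n))


class TestPrimitives:
    @pytest.mark.parametrize(
        "rate,expected",
        [(0.0, 0.0), (0.00558, 0.0055645), (0.01348, 0.0133896)],
    )
    def test_rate_to_probability(self, rate, expected):
        assert rate_to_probability(rate, 1.0) == pytest.approx(expected, abs=5e-7)

    def test_rate_to_probability_rejects_negative(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1)

    def test_statin_effect_full_adherence(self):
        base = EventIncidences(0.00626, 0.0, 0.0)
        eff = apply_statin_effect(
            base,
            effect=type("E", (), {"rr_mi": 0.58, "rr_stroke": 1.0, "rr_cvd_death": 1.0})(),
            adherence=1.0,
        )
        assert eff.mi == pytest.approx(0.0036308, abs=1e-7)

    def test_statin_effect_zero_adherence_identity(self, base_params):
        base = base_params.incidence["cac_ge100"]
        eff = apply_statin_effect(base, base_params.statin_effect["high"], 0.0)
        assert (eff.mi, eff.stroke, eff.cvd_death) == (base.mi, base.stroke, base.cvd_death)

    def test_statin_effect_partial_adherence_blend(self, base_params):
        base = EventIncidences(1.0, 0.0, 0.0)
        eff = apply_statin_effect(base, base_params.statin_effect["moderate"], 0.52)
        assert eff.mi == pytest.approx(0.52 * 0.76 + 0.48, abs=1e-12)


class TestStratification:
    def test_current_practice_split(self, base_params):
        mass = stratify_initial("current_practice", base_params)
        cells = build_cells("current_practice")
        by_cat = {
            c.category: mass[j]
            for j, c in enumerate(cells)
            if c.state is State.NO_CVD
        }
        assert by_cat == pytest.approx(
            {"ldl_ge190": 0.018, "ldl_70_189": 0.759, "ldl_lt70": 0.223}
        )

    def test_cac_split_normalized(self, base_params):
        mass = stratify_initial("cac_screening", base_params)
        assert mass.sum() == pytest.approx(1.0, abs=1e-12)
        cells = build_cells("cac_screening")
        j = next(i for i, c in enumerate(cells)
                 if c.state is State.NO_CVD and c.category == "cac_ge100")
        assert mass[j] == pytest.approx(0.35644, abs=5e-6)

    def test_degenerate_single_category(self, base_params):
        p = base_params.copy()
        p.initial["current_practice"].category_probs = {
            "ldl_ge190": 0.0, "ldl_70_189": 1.0, "ldl_lt70": 0.0
        }
        mass = stratify_initial("current_practice", p)
        assert mass.max() == pytest.approx(1.0)

    def test_unknown_arm_rejected(self, base_params):
        with pytest.raises(ValidationError):
            stratify_initial("no_such_arm", base_params)


class TestTransitions:
    def test_untreated_cac0_first_event(self, immortal_params):
        p = immortal_params
        p.incidence["cac_0"] = EventIncidences(0.00325, 0.0, 0.0)
        ev = build_transitions(State.NO_CVD, Tunnel.NONE, "cac_0", 50, p, "cac_screening")
        assert ev.p_mi == pytest.approx(1 - math.exp(-0.00325), abs=1e-12)
        assert ev.p_background_death == 0.0

    def test_post_mi_first_year_probabilities(self, base_params):
        p = base_params.copy()
        p.life_table = LifeTable({a: 0.0 for a in range(40, 76)})
        ev = build_transitions(State.POST_MI, Tunnel.FY, "cac_0", 50, p, "cac_screening")
        assert (ev.p_mi, ev.p_stroke, ev.p_cvd_death) == (0.1000, 0.0240, 0.0810)
        assert ev.p_stay == pytest.approx(1 - 0.205, abs=1e-12)

    def test_dead_is_absorbing(self, base_params):
        ev = build_transitions(State.DEAD, Tunnel.NONE, None, 60, base_params, "cac_screening")
        assert ev.p_stay == 1.0
        assert ev.p_mi == ev.p_stroke == ev.p_cvd_death == ev.p_background_death == 0.0


class TestRescreen:
    def _mass_all_cac0(self, base_params):
        cells = build_cells("cac_screening")
        mass = np.zeros(len(cells))
        j = next(i for i, c in enumerate(cells)
                 if c.state is State.NO_CVD and c.category == "cac_0")
        mass[j] = 1.0
        return cells, mass, j

    @pytest.mark.parametrize("age,p1,p2", [(45, 0.341, 0.158), (70, 0.281, 0.390)])
    def test_band_conversion(self, base_params, age, p1, p2):
        cells, mass, j0 = self._mass_all_cac0(base_params)
        out, rescreened = rescreen_cac_zero(mass, cells, age, base_params)
        assert rescreened == pytest.approx(1.0)
        by_cat = {c.category: out[j] for j, c in enumerate(cells) if c.state is State.NO_CVD}
        assert by_cat["cac_1_99"] == pytest.approx(p1)
        assert by_cat["cac_ge100"] == pytest.approx(p2)
        assert by_cat["cac_0"] == pytest.approx(1 - p1 - p2)

    def test_zero_mass_noop(self, base_params):
        cells, mass, j0 = self._mass_all_cac0(base_params)
        mass[j0] = 0.0
        out, rescreened = rescreen_cac_zero(mass, cells, 50, base_params)
        assert rescreened == 0.0
        assert np.array_equal(out, mass)

    def test_uncovered_age_rejected(self, base_params):
        cells, mass, _ = self._mass_all_cac0(base_params)
        with pytest.raises(ValidationError, match="not covered"):
            rescreen_cac_zero(mass, cells, 40, base_params)


class TestMarkovRun:
    def test_immortal_cohort_life_years(self, immortal_params):
        """No deaths: 35 undiscounted life-years; 22.132 discounted at 3%."""
        for arm in ("current_practice", "cac_screening"):
            trace = run_markov(arm, immortal_params)
            assert trace.alive_mass().sum() == pytest.approx(35.0, abs=1e-9)
            res = evaluate_arm(trace, immortal_params)
            assert res.life_years == pytest.approx(geometric_life_years(0.03), abs=1e-9)

    def test_mass_conservation_and_dead_monotone(self, base_params):
        for arm in ("current_practice", "cac_screening"):
            trace = run_markov(arm, base_params)
            totals = trace.occupancy[: trace.n_cycles].sum(axis=1)
            assert np.all(np.abs(totals - 1.0) < 1e-9)
            dead = trace.occupancy[:, trace.dead_index]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_everyone_dead_after_first_cycle(self, immortal_params):
        p = immortal_params.copy()
        p.life_table = LifeTable({a: 1.0 for a in range(40, 76)})
        trace = run_markov("current_practice", p)
        res = evaluate_arm(trace, p)
        assert res.life_years == pytest.approx(1.0, abs=1e-12)

    def test_two_state_three_cycle_closed_form(self, two_state_params):
        """Hand-computed closed form: survival 0.9^t, LY = sum 0.9^t/1.03^t."""
        trace = run_markov("current_practice", two_state_params)
        assert trace.n_cycles == 3
        expected = 1.0 + 0.9 / 1.03 + 0.81 / 1.03**2
        res = evaluate_arm(trace, two_state_params)
        assert res.life_years == pytest.approx(expected, abs=1e-12)
        assert trace.occupancy[2, trace.dead_index] == pytest.approx(0.19, abs=1e-12)

    def test_statin_dominance(self, base_params):
        """With RR < 1, cumulative CVD events under statins never exceed the
        no-effect model, cycle by cycle."""
        from cacscreen.parameters import StatinEffect

        p_none = base_params.copy()
        for k in ("moderate", "high"):
            p_none.statin_effect[k] = StatinEffect(1.0, 1.0, 1.0)

        def cumulative_first_events(p):
            tr = run_markov("cac_screening", p)
            idx = [j for j, c in enumerate(tr.cells)
                   if c.state in (State.POST_MI, State.POST_STROKE) and c.in_tunnel]
            return np.cumsum(tr.occupancy[: tr.n_cycles, idx].sum(axis=1))

        treated = cumulative_first_events(base_params)
        untreated = cumulative_first_events(p_none)
        assert np.all(treated <= untreated + 1e-12)

    def test_structural_symmetry_between_arms(self, base_params):
        """With rescreening disabled, equal incidences across CAC strata, RRs
        active in both arms and identical initial statin allocation, the two
        arms walk the same life-years path."""
        p = base_params.copy()
        p.options.cp_first_event_rr = True
        p.rescreen_interval = 100
        overall = p.incidence["no_statin_overall"]
        for s in ("cac_0", "cac_1_99", "cac_ge100"):
            p.incidence[s] = EventIncidences(overall.mi, overall.stroke, overall.cvd_death)
        cp_probs = p.initial["current_practice"].category_probs
        p.initial["cac_screening"].category_probs = {
            "cac_ge100": cp_probs["ldl_ge190"],
            "cac_1_99": cp_probs["ldl_70_189"],
            "cac_0": cp_probs["ldl_lt70"],
        }
        ly_cp = evaluate_arm(run_markov("current_practice", p), p).life_years
        ly_cac = evaluate_arm(run_markov("cac_screening", p), p).life_years
        assert ly_cac == pytest.approx(ly_cp, abs=1e-9)

    def test_trace_export_is_tidy(self, base_params):
        df = run_markov("cac_screening", base_params).to_frame()
        assert set(df.columns) == {"cycle", "age", "state", "tunnel", "category",
                                   "statin", "mass"}
        assert df[df.cycle == 0]["mass"].sum() == pytest.approx(1.0)
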