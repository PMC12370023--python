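"""Discounting, reward accrual, arm evaluation and ICER classification."""

import numpy as np
import pytest

from cacscreen import compute_icer, discount_factor, evaluate_arm, run_markov
from cacscreen.cohort import State, Tunnel, build_cells
from cacscreen.economics import ArmResult, accrue_cycle


def _arm(cost, qaly, ly=None):
    import pandas as pd

    return ArmResult("x", cost, ly if ly is not None else qaly, qaly, pd.DataFrame())


class TestDiscounting:
    @pytest.mark.parametrize(
        "t,rate,expected",
        [(0, 0.03, 1.0), (1, 0.03, 0.970874), (34, 0.05, 0.190355)],
    )
    def test_discount_factor(self, t, rate, expected):
        assert discount_factor(t, rate) == pytest.approx(expected, abs=5e-7)

    def test_zero_rate_totals_equal_ledger_sums(self, base_params):
        p = base_params.copy()
        p.discount_rate = 0.0
        res = evaluate_arm(run_markov("cac_screening", p), p)
        assert res.total_cost == pytest.approx(res.ledger["cost"].sum(), abs=1e-6)
        assert res.qalys == pytest.approx(res.ledger["qaly"].sum(), abs=1e-9)
        assert res.life_years == pytest.approx(res.ledger["life_years"].sum(), abs=1e-9)


class TestAccrual:
    def _row(self, arm, state, tunnel, category):
        cells = build_cells(arm)
        occ = np.zeros(len(cells))
        j = next(i for i, c in enumerate(cells)
                 if c.state is state and c.tunnel is tunnel and c.category == category)
        occ[j] = 1.0
        return cells, occ

    def test_moderate_statin_cost_only(self, base_params):
        cells, occ = self._row("current_practice", State.NO_CVD, Tunnel.NONE, "ldl_70_189")
        cost, qaly, ly = accrue_cycle(occ, cells, "current_practice", 40, 0.0, base_params)
        assert cost == pytest.approx(2589.0)
        assert ly == pytest.approx(1.0)

    def test_stroke_tunnel_societal_vs_provider(self, base_params):
        cells, occ = self._row("cac_screening", State.POST_STROKE, Tunnel.FY, "cac_0")
        societal, _, _ = accrue_cycle(occ, cells, "cac_screening", 60, 0.0, base_params)
        # first-year stroke treatment + non-medical cost + high-potency statin
        assert societal == pytest.approx(191_467 + 72_309 + 9_071)
        p = base_params.copy()
        p.perspective = "provider"
        provider, _, _ = accrue_cycle(occ, cells, "cac_screening", 60, 0.0, p)
        assert provider == pytest.approx(191_467 + 9_071)

    def test_provider_cost_never_exceeds_societal(self, base_params):
        p_soc = base_params
        p_prov = base_params.copy()
        p_prov.perspective = "provider"
        for arm in ("current_practice", "cac_screening"):
            tr = run_markov(arm, p_soc)
            assert (
                evaluate_arm(tr, p_prov).total_cost
                <= evaluate_arm(tr, p_soc).total_cost
            )

    def test_raising_a_cost_never_lowers_arm_total(self, base_params):
        base = evaluate_arm(run_markov("cac_screening", base_params), base_params)
        for field in ("statin_high_annual", "stroke_followup_annual", "cac_test"):
            p = base_params.copy()
            setattr(p.costs, field, getattr(p.costs, field) * 2)
            bumped = evaluate_arm(run_markov("cac_screening", p), p)
            assert bumped.total_cost >= base.total_cost

    def test_qalys_never_exceed_life_years(self, base_params):
        for arm in ("current_practice", "cac_screening"):
            res = evaluate_arm(run_markov(arm, base_params), base_params)
            assert res.qalys <= res.life_years


class TestArmEvaluation:
    def test_immortal_full_utility(self, immortal_full_utility_params):
        p = immortal_full_utility_params
        res = evaluate_arm(run_markov("current_practice", p), p)
        expected = sum(1.03 ** (-t) for t in range(35))
        assert res.qalys == pytest.approx(expected, abs=1e-9)
        assert res.qalys == pytest.approx(res.life_years, abs=1e-12)
        assert res.total_cost == 0.0

    def test_dead_at_start(self, immortal_params):
        from cacscreen.cohort import run_markov as rm
        from cacscreen.parameters import LifeTable

        p = immortal_params.copy()
        p.life_table = LifeTable({a: 1.0 for a in range(40, 76)})
        trace = rm("current_practice", p)
        # force the whole cohort dead from cycle 0 (q=1 kills the rest anyway)
        trace.occupancy[0] = 0.0
        trace.occupancy[0, trace.dead_index] = 1.0
        res = evaluate_arm(trace, p)
        assert res.life_years == 0.0
        assert res.qalys == 0.0
        assert res.total_cost == 0.0


class TestICER:
    def test_division_of_printed_deltas(self):
        ic = compute_icer(_arm(0, 0, 1), _arm(10_091, 0.62, 1.62), 160_000)
        assert ic.icer == pytest.approx(10_091 / 0.62, abs=0.5)
        assert ic.verdict == "cost_effective"

    def test_dominant(self):
        ic = compute_icer(_arm(1000, 1.0), _arm(278, 1.62), 160_000)
        assert ic.verdict == "dominant"
        assert ic.delta_cost < 0 and ic.delta_qaly > 0

    def test_dominated(self):
        ic = compute_icer(_arm(0, 1.0), _arm(500, 0.5), 160_000)
        assert ic.verdict == "dominated"

    def test_zero_deltas_non_inferior(self):
        ic = compute_icer(_arm(100, 1.0), _arm(100, 1.0), 160_000)
        assert ic.icer is None
        assert ic.verdict == "cost_effective"

    def test_zero_qaly_delta_by_cost_sign(self):
        assert compute_icer(_arm(0, 1.0), _arm(10, 1.0), 160_000).verdict == "not_cost_effective"
        assert compute_icer(_arm(10, 1.0), _arm(0, 1.0), 160_000).verdict == "cost_effective"
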