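"""Model and Results objects tying the pipeline together.

``CACScreeningModel`` wraps a validated :class:`ParameterSet`; ``fit()``
runs the decision tree + Markov cohort simulation for both strategy arms
and returns a :class:`CostUtilityResults` carrying discounted costs,
life-years, QALYs, the incremental comparison, and a printable summary.
Probabilistic and one-way sensitivity analyses and the scenario battery
hang off the model object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import uncertainty
from .cohort import MarkovTrace, run_markov
from .economics import ArmResult, ICERResult, compute_icer, evaluate_arm
from .parameters import ParameterSet, load_parameters

__all__ = ["CACScreeningModel", "CostUtilityResults"]


class CACScreeningModel:
    """Cost-utility model of CAC screening versus current statin practice.

    Parameters
    ----------
    params : ParameterSet
        Validated model inputs (see :func:`cacscreen.load_parameters`).
    """

    reference_arm = "current_practice"
    comparator_arm = "cac_screening"

    def __init__(self, params: ParameterSet):
        params.validate()
        self.params = params

    @classmethod
    def from_config(cls, config_path: str | Path | None = None) -> "CACScreeningModel":
        """Build from a YAML config; ``None`` loads the bundled base case."""
        return cls(load_parameters(config_path))

    # ------------------------------------------------------------------
    def run_arm(self, arm: str, params: ParameterSet | None = None) -> MarkovTrace:
        return run_markov(arm, params or self.params)

    def fit(self) -> "CostUtilityResults":
        """Run both arms and assemble the incremental comparison."""
        p = self.params
        ref = evaluate_arm(self.run_arm(self.reference_arm), p)
        comp = evaluate_arm(self.run_arm(self.comparator_arm), p)
        icer = compute_icer(ref, comp, p.wtp_threshold)
        return CostUtilityResults(model=self, reference=ref, comparator=comp, icer=icer)

    # ------------------------------------------------------------------
    def psa(self, n_draws: int = 1000, seed: int = 0) -> "uncertainty.PSAResult":
        """Probabilistic sensitivity analysis (see :func:`uncertainty.run_psa`)."""
        return uncertainty.run_psa(self.params, n_draws, seed)

    def tornado(self, parameters: list[str] | None = None,
                z: float = 1.96) -> pd.DataFrame:
        """One-way sensitivity analysis (see :func:`uncertainty.tornado`)."""
        return uncertainty.tornado(self.params, parameters, z=z)

    def run_scenario(self, spec) -> "pd.Series":
        from . import scenarios

        if isinstance(spec, str):
            spec = scenarios.get_scenario(spec)
        return scenarios.run_scenario(spec, self.params)

    def scenario_battery(self) -> pd.DataFrame:
        from . import scenarios

        return scenarios.run_all(self.params)

    def price_threshold(self, path: str, bracket: tuple[float, float],
                        wtp: float | None = None) -> float:
        from . import scenarios

        return scenarios.find_price_threshold(
            path, self.params, wtp=wtp or self.params.wtp_threshold, bracket=bracket
        )


@dataclass
class CostUtilityResults:
    """Fitted base-case results for both arms plus the incremental comparison."""

    model: CACScreeningModel = field(repr=False)
    reference: ArmResult
    comparator: ArmResult
    icer: ICERResult

    # -- tabular views --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Comparison table shaped like the headline base-case results."""
        ref, comp, ic = self.reference, self.comparator, self.icer
        return pd.DataFrame(
            {
                "current_practice": [ref.total_cost, ref.life_years, ref.qalys,
                                     None, None, None],
                "cac_screening": [comp.total_cost, comp.life_years, comp.qalys,
                                  ic.delta_cost, ic.delta_qaly, ic.icer],
            },
            index=[
                "costs_thb",
                "life_years",
                "qalys",
                "incremental_cost_thb",
                "incremental_qalys",
                "icer_thb_per_qaly",
            ],
        )

    def to_dict(self) -> dict:
        ic = self.icer
        return {
            "current_practice": {
                "cost_thb": self.reference.total_cost,
                "life_years": self.reference.life_years,
                "qalys": self.reference.qalys,
            },
            "cac_screening": {
                "cost_thb": self.comparator.total_cost,
                "life_years": self.comparator.life_years,
                "qalys": self.comparator.qalys,
            },
            "incremental": {
                "delta_cost_thb": ic.delta_cost,
                "delta_qalys": ic.delta_qaly,
                "icer_thb_per_qaly": ic.icer,
                "verdict": ic.verdict,
                "wtp_threshold": ic.wtp_threshold,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def summary(self) -> str:
        """Human-readable base-case comparison."""
        ref, comp, ic = self.reference, self.comparator, self.icer
        lines = [
            "Cost-utility analysis: CAC screening vs current practice",
            "=" * 58,
            f"{'':28s}{'Current practice':>16s}{'CAC screening':>14s}",
            f"{'Costs (THB)':28s}{ref.total_cost:>16,.0f}{comp.total_cost:>14,.0f}",
            f"{'Life years':28s}{ref.life_years:>16.2f}{comp.life_years:>14.2f}",
            f"{'QALYs':28s}{ref.qalys:>16.2f}{comp.qalys:>14.2f}",
            "-" * 58,
            f"{'Incremental cost (THB)':28s}{ic.delta_cost:>30,.0f}",
            f"{'Incremental QALYs':28s}{ic.delta_qaly:>30.2f}",
        ]
        if ic.icer is not None:
            lines.append(f"{'ICER (THB/QALY)':28s}{ic.icer:>30,.0f}")
        lines.append(
            f"{'Verdict at WTP %s THB/QALY' % format(ic.wtp_threshold, ',.0f'):40s}"
            f"{ic.verdict:>18s}"
        )
        return "\n".join(lines)
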