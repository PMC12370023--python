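"""Named scenario analyses: declarative parameter-override runs.

Each scenario is a :class:`ScenarioSpec` — a name plus a map of parameter
overrides (dotted paths, adherence blocks, unit drug prices annualised at
365.25 doses/year, or a replacement CAC progression table). The bundled
registry (``data/scenarios.yaml``) covers the battery of deterministic
sensitivity scenarios: statin adherence, drug and CAC-test prices, halved
CAC=0 event rates, the MESA initial CAC distribution, an alternative
(synthetic stand-in) progression table, the provider perspective, and 0%/5%
discounting. Price thresholds at which the ICER crosses the
willingness-to-pay line are recovered by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import run_markov
from .economics import compute_icer, evaluate_arm
from .parameters import (
    CACProgressionBand,
    CACProgressionTable,
    ParameterError,
    ParameterSet,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "annualize_unit_price",
    "load_registry",
    "get_scenario",
    "run_scenario",
    "run_all",
    "find_price_threshold",
]

DOSES_PER_YEAR = 365.25  # daily dosing


def annualize_unit_price(price_per_unit: float, units_per_year: float = DOSES_PER_YEAR) -> float:
    """Annual drug cost from a per-unit (per-tablet) price."""
    if price_per_unit < 0:
        raise ValueError("price must be >= 0")
    return price_per_unit * units_per_year


@dataclass
class ScenarioSpec:
    """One named set of parameter overrides.

    Override keys are dotted parameter paths; three structured keys are also
    understood: ``adherence`` (per-arm, per-category fractions),
    ``unit_prices`` (``{path: price_per_unit}``, annualised), and
    ``cac_progression`` (a full replacement table).
    """

    name: str
    overrides: dict = field(default_factory=dict)
    description: str = ""


@dataclass
class ScenarioResult:
    name: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    verdict: str
    cost_reference: float
    cost_comparator: float
    qaly_reference: float
    qaly_comparator: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def apply_overrides(spec: ScenarioSpec, params: ParameterSet) -> ParameterSet:
    p = params.copy()
    touched_arms = set()
    for key, value in spec.overrides.items():
        if key == "adherence":
            for arm, by_cat in value.items():
                p.adherence.setdefault(arm, {}).update(
                    {c: float(v) for c, v in by_cat.items()}
                )
        elif key == "unit_prices":
            for path, per_unit in value.items():
                p.set(path, annualize_unit_price(float(per_unit)))
        elif key == "cac_progression":
            p.cac_progression = CACProgressionTable(
                [CACProgressionBand(**row) for row in value]
            )
        else:
            p.set(key, value)  # raises ParameterError for unknown paths
            if key.startswith("initial.") and ".category_probs." in key:
                touched_arms.add(key.split(".")[1])
    for arm in touched_arms:
        p.initial[arm].normalize()
    p.validate()
    return p


def run_scenario(spec: ScenarioSpec, params: ParameterSet) -> ScenarioResult:
    """Evaluate both arms under the overridden parameter set."""
    p = apply_overrides(spec, params)
    ref = evaluate_arm(run_markov("current_practice", p), p)
    comp = evaluate_arm(run_markov("cac_screening", p), p)
    ic = compute_icer(ref, comp, p.wtp_threshold)
    return ScenarioResult(
        name=spec.name,
        delta_cost=ic.delta_cost,
        delta_qaly=ic.delta_qaly,
        icer=ic.icer,
        verdict=ic.verdict,
        cost_reference=ref.total_cost,
        cost_comparator=comp.total_cost,
        qaly_reference=ref.qalys,
        qaly_comparator=comp.qalys,
    )


# ---------------------------------------------------------------------------
# registry


def default_registry_path() -> Path:
    return Path(__file__).parent / "data" / "scenarios.yaml"


def load_registry(path: str | Path | None = None) -> list[ScenarioSpec]:
    with open(path or default_registry_path()) as fh:
        raw = yaml.safe_load(fh)
    return [
        ScenarioSpec(
            name=entry["name"],
            overrides=entry.get("overrides", {}) or {},
            description=entry.get("description", ""),
        )
        for entry in raw
    ]


def get_scenario(name: str, path: str | Path | None = None) -> ScenarioSpec:
    for spec in load_registry(path):
        if spec.name == name:
            return spec
    raise ParameterError(f"unknown scenario {name!r}")


def run_all(params: ParameterSet, path: str | Path | None = None) -> pd.DataFrame:
    rows = [run_scenario(spec, params).to_series() for spec in load_registry(path)]
    return pd.DataFrame(rows).set_index("name")


# ---------------------------------------------------------------------------
# price thresholds


def _icer_at(path: str, value: float, params: ParameterSet) -> float:
    p = params.copy()
    p.set(path, float(value))
    p.validate()
    ref = evaluate_arm(run_markov("current_practice", p), p)
    comp = evaluate_arm(run_markov("cac_screening", p), p)
    ic = compute_icer(ref, comp, p.wtp_threshold)
    if ic.icer is None:
        raise RuntimeError("ICER undefined inside threshold bracket")
    return ic.icer


def find_price_threshold(
    path: str,
    params: ParameterSet,
    wtp: float,
    bracket: tuple[float, float],
    tol: float = 1.0,
    grid_points: int = 5,
) -> float:
    """Price at which the ICER equals the willingness-to-pay threshold.

    Asserts numerically that the ICER is monotone in the price over the
    bracket, then bisects until the ICER is within ``tol`` THB/QALY of the
    target. Raises if the bracket does not straddle the threshold.
    """
    lo, hi = bracket
    grid = np.linspace(lo, hi, grid_points)
    icers = [_icer_at(path, v, params) for v in grid]
    diffs = np.diff(icers)
    if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        raise RuntimeError(f"ICER not monotone in {path} over {bracket}")
    f_lo, f_hi = icers[0] - wtp, icers[-1] - wtp
    if f_lo * f_hi > 0:
        raise RuntimeError(f"no ICER={wtp} crossing for {path} in {bracket}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _icer_at(path, mid, params) - wtp
        if abs(f_mid) < tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    raise RuntimeError("bisection failed to converge")
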