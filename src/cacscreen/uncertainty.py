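"""Probabilistic and one-way sensitivity analyses.

The PSA redraws every registered parameter from its uncertainty distribution
(beta for probabilities and utilities, lognormal for relative risks, gamma
for costs), reruns both strategy arms per draw, and summarises the
incremental cost / incremental QALY cloud as a cost-effectiveness
acceptability curve. The one-way (tornado) analysis moves one parameter at a
time to its interval bounds and records the ICER response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import run_markov
from .economics import compute_icer, evaluate_arm
from .parameters import (
    ARMS,
    CATEGORIES,
    ParameterSet,
    ValidationError,
    sample_parameter_set,
)

__all__ = [
    "PSAResult",
    "run_psa",
    "ceac",
    "default_thresholds",
    "tornado",
    "TORNADO_DOMAINS",
]


def _evaluate_pair(params: ParameterSet):
    ref = evaluate_arm(run_markov("current_practice", params), params)
    comp = evaluate_arm(run_markov("cac_screening", params), params)
    return ref, comp


@dataclass
class PSAResult:
    """Monte-Carlo cloud of incremental outcomes.

    ``samples`` has one row per retained draw (draw, seed, delta_cost,
    delta_qaly plus per-arm totals); draws whose sampled parameters violated
    a model invariant are excluded, not redrawn, and counted in
    ``n_excluded``.
    """

    samples: pd.DataFrame
    n_requested: int
    n_excluded: int
    excluded_draws: list[int] = field(default_factory=list)

    def prob_cost_effective(self, threshold: float) -> float:
        s = self.samples
        nmb = threshold * s["delta_qaly"].to_numpy() - s["delta_cost"].to_numpy()
        return float(np.mean(nmb > 0))

    def ceac(self, thresholds=None) -> pd.DataFrame:
        return ceac(self.samples, thresholds)

    def ce_plane(self) -> pd.DataFrame:
        return self.samples[["draw", "delta_cost", "delta_qaly"]].copy()


def run_psa(params: ParameterSet, n_draws: int, master_seed: int) -> PSAResult:
    """Repeat the full model under parameter uncertainty.

    Per-draw seeds derive deterministically from ``master_seed`` by counter,
    so the same master seed reproduces the identical sample list.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rows = []
    excluded: list[int] = []
    for i in range(n_draws):
        rng = np.random.default_rng([int(master_seed), i])
        try:
            drawn = sample_parameter_set(params, rng)
            ref, comp = _evaluate_pair(drawn)
        except ValidationError:
            excluded.append(i)
            continue
        rows.append(
            {
                "draw": i,
                "seed": int(master_seed),
                "delta_cost": comp.total_cost - ref.total_cost,
                "delta_qaly": comp.qalys - ref.qalys,
                "cost_reference": ref.total_cost,
                "cost_comparator": comp.total_cost,
                "qaly_reference": ref.qalys,
                "qaly_comparator": comp.qalys,
            }
        )
    samples = pd.DataFrame(rows)
    if not np.all(np.isfinite(samples[["delta_cost", "delta_qaly"]].to_numpy())):
        raise RuntimeError("non-finite PSA sample")
    return PSAResult(samples, n_draws, len(excluded), excluded)


def default_thresholds() -> np.ndarray:
    """Willingness-to-pay grid 0..600,000 THB/QALY in steps of 10,000."""
    return np.arange(0, 600_001, 10_000, dtype=float)


def ceac(samples: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    """P(cost-effective) per threshold: fraction of draws with positive net
    monetary benefit, t * delta_qaly - delta_cost > 0."""
    if len(samples) == 0:
        raise ValueError("empty PSA sample")
    if thresholds is None:
        thresholds = default_thresholds()
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    probs = [float(np.mean(t * dq - dc > 0)) for t in thresholds]
    return pd.DataFrame({"threshold": np.asarray(thresholds, float),
                         "prob_cost_effective": probs})


# ---------------------------------------------------------------------------
# one-way (tornado) analysis

#: valid domains for tornado bounds, by path prefix/suffix matching
TORNADO_DOMAINS = {
    "probability": (0.0, 1.0),
    "rr": (1e-9, 1.0),
    "cost": (0.0, np.inf),
    "utility": (0.0, 1.0),
    "discount_rate": (0.0, 0.05),
}


def _domain_for(path: str) -> tuple[float, float]:
    if path == "discount_rate":
        return TORNADO_DOMAINS["discount_rate"]
    if path.startswith("costs."):
        return TORNADO_DOMAINS["cost"]
    if ".rr_" in path:
        return TORNADO_DOMAINS["rr"]
    return TORNADO_DOMAINS["probability"]


def _apply_bound(params: ParameterSet, path: str, value: float) -> ParameterSet:
    p = params.copy()
    p.set(path, value)
    if ".category_probs." in path:
        arm = path.split(".")[1]
        p.initial[arm].normalize()
    p.validate()
    return p


def tornado(
    params: ParameterSet,
    parameter_list: list[str] | None = None,
    z: float = 1.96,
) -> pd.DataFrame:
    """ICER at each parameter's low/high bound, sorted by descending spread.

    Bounds default to mean +/- z*SE truncated to the parameter's valid
    domain (probabilities to [0,1], relative risks to (0,1], costs to >= 0);
    the discount rate is varied over [0, 0.05]. Every other parameter is
    held at its base value; both arms are rerun deterministically.
    """
    if parameter_list is None:
        parameter_list = params.tornado_parameters
    entries = []
    for path in parameter_list:
        lo_dom, hi_dom = _domain_for(path)
        if path == "discount_rate":
            low, high = lo_dom, hi_dom
        else:
            spec = params.distributions.get(path)
            if spec is None:
                raise ValidationError(f"tornado parameter {path!r} has no DistributionSpec")
            low = min(max(spec.mean - z * spec.se, lo_dom), hi_dom)
            high = min(max(spec.mean + z * spec.se, lo_dom), hi_dom)
        icers = []
        for bound in (low, high):
            ref, comp = _evaluate_pair(_apply_bound(params, path, bound))
            ic = compute_icer(ref, comp, params.wtp_threshold)
            icers.append(ic.icer if ic.icer is not None else np.nan)
        entries.append(
            {
                "parameter": path,
                "low_value": low,
                "high_value": high,
                "icer_at_low": icers[0],
                "icer_at_high": icers[1],
                "spread": abs(icers[1] - icers[0]),
            }
        )
    out = pd.DataFrame(entries).sort_values("spread", ascending=False, kind="stable")
    return out.reset_index(drop=True)
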