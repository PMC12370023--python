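"""Synthetic stand-ins for inputs that exist only as supplementary material.

Three inputs of the cost-utility model are not printed in the main parameter
tables: the age-specific utility of the No-CVD state, the background
all-cause life table, and the hospital cohort from which the initial
LDL-C/CAC proportions and the 5-yearly CAC-conversion fractions were
estimated. This module generates statistically structured stand-ins for all
three so the full pipeline runs, and is testable, without any download:

* a Gompertz-form life table, q(age) = q40 * exp(b * (age - 40));
* a linearly age-declining No-CVD utility;
* hospital-style patient records (category draws + 5-year CAC conversion)
  together with the estimators that turn them back into beta-distributed
  model inputs, closing a parameter-recovery loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import LifeTable

__all__ = [
    "SyntheticCohortConfig",
    "generate_lifetable",
    "generate_no_cvd_utility",
    "generate_patient_records",
    "estimate_category_proportions",
    "estimate_progression_rates",
    "write_age_series_csv",
    "write_progression_csv",
]


def generate_lifetable(
    q40: float,
    log_increase: float,
    start_age: int = 40,
    end_age: int = 75,
) -> LifeTable:
    """Gompertz life table: q(age) = q40 * exp(b * (age - 40)), capped at 1.

    ``q40`` is the annual background mortality probability at age 40 and
    ``log_increase`` (b) the annual log-linear increase. ``q40 = 0`` yields
    the immortal fixture used by the cohort-engine tests.
    """
    if not 0 <= q40 < 1:
        raise ValueError(f"q40 must be in [0, 1), got {q40}")
    q = {
        age: min(1.0, q40 * math.exp(log_increase * (age - 40)))
        for age in range(start_age, end_age + 1)
    }
    return LifeTable(q)


def generate_no_cvd_utility(
    anchor_age: int = 40,
    anchor_utility: float = 0.95,
    slope_per_year: float = 0.002,
    start_age: int = 40,
    end_age: int = 75,
) -> dict[int, float]:
    """Linearly age-declining No-CVD utility, clipped to [0, 1]."""
    return {
        age: float(np.clip(anchor_utility - slope_per_year * (age - anchor_age), 0.0, 1.0))
        for age in range(start_age, end_age + 1)
    }


@dataclass
class SyntheticCohortConfig:
    """Generator settings for hospital-style patient records."""

    n_patients: int = 10_000
    seed: int = 0
    #: CAC category probabilities at entry, ordered (cac_ge100, cac_1_99, cac_0)
    true_cac_probs: tuple[float, float, float] = (0.36, 0.39, 0.25)
    #: LDL category probabilities, ordered (ldl_ge190, ldl_70_189, ldl_lt70)
    true_ldl_probs: tuple[float, float, float] = (0.018, 0.759, 0.223)
    #: per-age-band 5-year conversion out of CAC=0: (lo, hi, p_1_99, p_ge100)
    cac_progression_rates: list[tuple[int, int, float, float]] = field(
        default_factory=lambda: [
            (45, 49, 0.341, 0.158),
            (50, 54, 0.338, 0.195),
            (55, 59, 0.331, 0.237),
            (60, 64, 0.319, 0.284),
            (65, 69, 0.302, 0.336),
            (70, 74, 0.281, 0.390),
        ]
    )
    age_range: tuple[int, int] = (45, 74)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for probs in (self.true_cac_probs, self.true_ldl_probs):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-6:
                raise ValueError(f"invalid probability triple {probs}")


CAC_LABELS = ("cac_ge100", "cac_1_99", "cac_0")
LDL_LABELS = ("ldl_ge190", "ldl_70_189", "ldl_lt70")


def generate_patient_records(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Draw a hospital-style cohort table.

    Columns: id, age, ldl_category, cac_category, cac_category_5y (the CAC
    category observed five years later; non-zero scores are carried forward,
    CAC=0 converts according to the age band's conversion probabilities).
    LDL and CAC categories are drawn independently — the data offer nothing
    to constrain their joint distribution.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    ldl = rng.choice(LDL_LABELS, size=n, p=config.true_ldl_probs)
    cac = rng.choice(CAC_LABELS, size=n, p=config.true_cac_probs)

    cac_5y = cac.copy()
    for lo, hi, p1, p2 in config.cac_progression_rates:
        mask = (cac == "cac_0") & (ages >= lo) & (ages <= hi)
        k = int(mask.sum())
        if k == 0:
            continue
        dest = rng.choice(
            ["cac_1_99", "cac_ge100", "cac_0"], size=k, p=[p1, p2, 1 - p1 - p2]
        )
        cac_5y[mask] = dest
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": ages,
            "ldl_category": ldl,
            "cac_category": cac,
            "cac_category_5y": cac_5y,
        }
    )


def estimate_category_proportions(
    records: pd.DataFrame, column: str = "cac_category"
) -> dict[str, tuple[float, float]]:
    """Binomial point estimates and SEs per category: p = k/n, SE = sqrt(p(1-p)/n).

    The output feeds ``DistributionSpec("beta", p, SE)``; a category with
    zero (or full) count yields SE = 0, for which the beta family is
    infeasible and callers fall back to a fixed point mass.
    """
    if len(records) == 0:
        raise ValueError("empty records table")
    n = len(records)
    labels = CAC_LABELS if column == "cac_category" else LDL_LABELS
    out = {}
    for label in labels:
        p = float((records[column] == label).sum()) / n
        out[label] = (p, math.sqrt(p * (1 - p) / n))
    return out


def estimate_progression_rates(
    records: pd.DataFrame,
    bands: list[tuple[int, int]] | None = None,
) -> dict[tuple[int, int], tuple[float, float]]:
    """5-year CAC conversion fractions out of CAC=0 by age band.

    Returns ``{(lo, hi): (p_to_1_99, p_to_ge100)}`` among patients with
    CAC=0 at entry. Bands with no CAC=0 patients are omitted.
    """
    if bands is None:
        bands = [(45, 49), (50, 54), (55, 59), (60, 64), (65, 69), (70, 74)]
    zero = records[records["cac_category"] == "cac_0"]
    out = {}
    for lo, hi in bands:
        sub = zero[(zero["age"] >= lo) & (zero["age"] <= hi)]
        if len(sub) == 0:
            continue
        p1 = float((sub["cac_category_5y"] == "cac_1_99").mean())
        p2 = float((sub["cac_category_5y"] == "cac_ge100").mean())
        out[(lo, hi)] = (p1, p2)
    return out


# ---------------------------------------------------------------------------
# writers producing the same CSV dialects the config loader reads


def write_age_series_csv(series: dict[int, float], path: str | Path,
                         value_column: str = "q") -> None:
    """Write an ``age,value`` series (life table or utility) as CSV."""
    pd.DataFrame(
        {"age": sorted(series), value_column: [series[a] for a in sorted(series)]}
    ).to_csv(path, index=False)


def write_progression_csv(
    rates: dict[tuple[int, int], tuple[float, float]], path: str | Path
) -> None:
    rows = [
        {"age_lo": lo, "age_hi": hi, "p_to_1_99": p1, "p_to_ge100": p2}
        for (lo, hi), (p1, p2) in sorted(rates.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
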