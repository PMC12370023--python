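"""Typed model parameters, config loading, and PSA sampling distributions.

Every input of the cost-utility model lives here as a validated container:
initial risk-category proportions for the two screening strategies, per
person-year cardiovascular event incidences by CAC stratum, first-year
post-event transition probabilities, statin relative risks by potency,
annual costs (2024 THB), health-state utilities, the 5-yearly CAC
progression table, and the background (non-CVD) life table.

Parameter uncertainty for probabilistic sensitivity analysis is described by
:class:`DistributionSpec` triples (family, mean, SE); beta for probabilities
and utilities, gamma for costs, lognormal for relative risks, all matched by
method of moments.
"""

from __future__ import annotations

import copy
import functools
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "ValidationError",
    "DistributionSpec",
    "InitialStratification",
    "EventIncidences",
    "PostEventProbabilities",
    "StatinEffect",
    "CACProgressionBand",
    "CACProgressionTable",
    "CostTable",
    "UtilityTable",
    "LifeTable",
    "ModelOptions",
    "ParameterSet",
    "moment_match",
    "load_parameters",
    "default_config_path",
    "sample_parameter_set",
]

ARMS = ("current_practice", "cac_screening")
#: category labels per arm, ordered high-potency, moderate-potency, no statin
CATEGORIES = {
    "current_practice": ("ldl_ge190", "ldl_70_189", "ldl_lt70"),
    "cac_screening": ("cac_ge100", "cac_1_99", "cac_0"),
}
TREATMENT_BY_POSITION = ("high_potency", "moderate_potency", "none")
INCIDENCE_STRATA = ("no_statin_overall", "cac_0", "cac_1_99", "cac_ge100")
FAMILIES = ("beta", "gamma", "lognormal", "fixed")


class ParameterError(KeyError):
    """A required parameter is missing from the configuration."""


class ValidationError(ValueError):
    """A parameter value violates its invariant."""


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one scalar parameter: (family, mean, SE)."""

    family: str
    mean: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ValidationError(f"se must be >= 0, got {self.se}")
        if self.family == "beta":
            if not 0 < self.mean < 1:
                raise ValidationError(f"beta requires 0 < mean < 1, got {self.mean}")
            if self.se > 0 and self.se**2 >= self.mean * (1 - self.mean):
                raise ValidationError(
                    f"beta infeasible: se^2={self.se**2:.3g} >= "
                    f"mean*(1-mean)={self.mean * (1 - self.mean):.3g}"
                )
        elif self.family in ("gamma", "lognormal") and self.mean <= 0:
            raise ValidationError(f"{self.family} requires mean > 0, got {self.mean}")

    def rvs(self, rng: np.random.Generator) -> float:
        """Draw one value; SE of zero collapses to the mean for any family."""
        if self.family == "fixed" or self.se == 0:
            return self.mean
        a, b = moment_match(self)
        if self.family == "beta":
            return float(rng.beta(a, b))
        if self.family == "gamma":
            return float(rng.gamma(a, b))
        return float(rng.lognormal(a, b))


@functools.lru_cache(maxsize=None)
def moment_match(spec: DistributionSpec) -> tuple[float, float]:
    """Method-of-moments parameters reproducing (mean, se) exactly.

    beta -> (alpha, beta); gamma -> (shape, scale); lognormal -> (mu, sigma);
    fixed -> (mean, 0.0).
    """
    m, s = spec.mean, spec.se
    if spec.family == "fixed" or s == 0:
        return (m, 0.0)
    if spec.family == "beta":
        nu = m * (1 - m) / s**2 - 1
        if nu <= 0:
            raise ValidationError(f"beta infeasible for mean={m}, se={s}")
        return (m * nu, (1 - m) * nu)
    if spec.family == "gamma":
        return (m**2 / s**2, s**2 / m)
    # lognormal
    sigma2 = math.log1p((s / m) ** 2)
    return (math.log(m) - sigma2 / 2, math.sqrt(sigma2))


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class InitialStratification:
    """Decision-tree split of the cohort at entry for one strategy arm."""

    strategy: str
    category_probs: dict[str, float]
    category_treatment: dict[str, str]

    def normalize(self) -> None:
        total = sum(self.category_probs.values())
        if total <= 0:
            raise ValidationError(f"{self.strategy}: category probabilities sum to 0")
        for k in self.category_probs:
            self.category_probs[k] /= total

    def validate(self) -> None:
        if self.strategy not in ARMS:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        expected = CATEGORIES[self.strategy]
        if tuple(self.category_probs) != expected:
            raise ValidationError(
                f"{self.strategy}: categories {tuple(self.category_probs)} != {expected}"
            )
        for cat, p in self.category_probs.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"{self.strategy}.{cat}: probability {p} outside [0,1]")
        if abs(sum(self.category_probs.values()) - 1.0) > 1e-9:
            raise ValidationError(f"{self.strategy}: probabilities not normalized")
        for cat, pos in zip(expected, TREATMENT_BY_POSITION):
            if self.category_treatment.get(cat) != pos:
                raise ValidationError(
                    f"{self.strategy}.{cat}: treatment must be {pos}, "
                    f"got {self.category_treatment.get(cat)}"
                )


@dataclass
class EventIncidences:
    """First-event rates per person-year for one risk stratum."""

    mi: float
    stroke: float
    cvd_death: float

    def validate(self, name: str = "incidence") -> None:
        for f_ in ("mi", "stroke", "cvd_death"):
            v = getattr(self, f_)
            if not 0 <= v < 1:
                raise ValidationError(f"{name}.{f_}: rate {v} outside [0, 1)")


@dataclass
class PostEventProbabilities:
    """First-year transition probabilities out of a post-event state."""

    recurrent_same: float
    other_event: float
    cvd_death: float

    def validate(self, name: str = "post_event") -> None:
        vals = (self.recurrent_same, self.other_event, self.cvd_death)
        for f_, v in zip(("recurrent_same", "other_event", "cvd_death"), vals):
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}.{f_}: probability {v} outside [0,1]")
        if sum(vals) > 1 + 1e-12:
            raise ValidationError(f"{name}: probabilities sum to {sum(vals)} > 1")


@dataclass
class StatinEffect:
    """Relative risks versus no statin for one potency level."""

    rr_mi: float
    rr_stroke: float
    rr_cvd_death: float

    def validate(self, name: str = "statin_effect") -> None:
        for f_ in ("rr_mi", "rr_stroke", "rr_cvd_death"):
            v = getattr(self, f_)
            if not 0 < v <= 1:
                raise ValidationError(f"{name}.{f_}: RR {v} outside (0, 1]")


@dataclass
class CACProgressionBand:
    age_lo: int
    age_hi: int
    p_to_1_99: float
    p_to_ge100: float


@dataclass
class CACProgressionTable:
    """5-yearly conversion probabilities out of CAC=0, by attained-age band."""

    rows: list[CACProgressionBand]

    def band_for(self, age: float) -> CACProgressionBand:
        for row in self.rows:
            if row.age_lo <= age <= row.age_hi:
                return row
        raise ValidationError(f"age {age} not covered by CAC progression table")

    def validate(self) -> None:
        if not self.rows:
            raise ValidationError("cac_progression: empty table")
        rows = sorted(self.rows, key=lambda r: r.age_lo)
        if rows[0].age_lo > 45 or rows[-1].age_hi < 74:
            raise ValidationError("cac_progression: bands must cover ages 45-74")
        for prev, cur in zip(rows, rows[1:]):
            if cur.age_lo != prev.age_hi + 1:
                raise ValidationError(
                    f"cac_progression: bands {prev.age_lo}-{prev.age_hi} and "
                    f"{cur.age_lo}-{cur.age_hi} not contiguous"
                )
        for row in rows:
            for f_ in ("p_to_1_99", "p_to_ge100"):
                v = getattr(row, f_)
                if not 0 <= v <= 1:
                    raise ValidationError(f"cac_progression[{row.age_lo}].{f_}: {v} outside [0,1]")
            if row.p_to_1_99 + row.p_to_ge100 > 1 + 1e-12:
                raise ValidationError(
                    f"cac_progression[{row.age_lo}]: conversion probabilities sum > 1"
                )


COST_FIELDS = (
    "statin_moderate_annual",
    "statin_high_annual",
    "cac_test",
    "mi_first_year",
    "mi_recurrent_first_year",
    "mi_followup_annual",
    "stroke_first_year",
    "stroke_recurrent_first_year",
    "stroke_followup_annual",
    "nonmed_mi_first_year",
    "nonmed_mi_followup",
    "nonmed_stroke_first_year",
    "nonmed_stroke_followup",
)


@dataclass
class CostTable:
    """Annual costs in THB (cac_test: THB per test)."""

    statin_moderate_annual: float
    statin_high_annual: float
    cac_test: float
    mi_first_year: float
    mi_recurrent_first_year: float
    mi_followup_annual: float
    stroke_first_year: float
    stroke_recurrent_first_year: float
    stroke_followup_annual: float
    nonmed_mi_first_year: float
    nonmed_mi_followup: float
    nonmed_stroke_first_year: float
    nonmed_stroke_followup: float

    def validate(self) -> None:
        for f_ in COST_FIELDS:
            if getattr(self, f_) < 0:
                raise ValidationError(f"costs.{f_}: negative cost")


@dataclass
class UtilityTable:
    """Health-state utilities and recurrence disutility decrements."""

    no_cvd_by_age: dict[int, float]
    post_mi: float
    post_stroke: float
    post_mi_and_stroke: float
    disutil_recurrent_mi: float
    disutil_recurrent_stroke: float
    disutil_recurrent_with_prior_event: float

    def no_cvd(self, age: float) -> float:
        return self.no_cvd_by_age[int(age)]

    def validate(self, start_age: int, end_age: int) -> None:
        scalars = (
            "post_mi",
            "post_stroke",
            "post_mi_and_stroke",
            "disutil_recurrent_mi",
            "disutil_recurrent_stroke",
            "disutil_recurrent_with_prior_event",
        )
        for f_ in scalars:
            v = getattr(self, f_)
            if not 0 <= v <= 1:
                raise ValidationError(f"utilities.{f_}: {v} outside [0,1]")
        for age in range(start_age, end_age + 1):
            if age not in self.no_cvd_by_age:
                raise ValidationError(f"utilities.no_cvd_by_age: age {age} missing")
            u = self.no_cvd_by_age[age]
            if not 0 <= u <= 1:
                raise ValidationError(f"utilities.no_cvd_by_age[{age}]: {u} outside [0,1]")


@dataclass
class LifeTable:
    """Annual background (non-CVD) all-cause mortality probability by age."""

    q: dict[int, float]

    def prob(self, age: float) -> float:
        return self.q[int(age)]

    def validate(self, start_age: int, end_age: int) -> None:
        for age in range(start_age, end_age + 1):
            if age not in self.q:
                raise ValidationError(f"life_table: age {age} missing")
            v = self.q[age]
            if not 0 <= v <= 1:
                raise ValidationError(f"life_table[{age}]: {v} outside [0,1]")


@dataclass
class ModelOptions:
    """Structural conventions exposed as switches (defaults documented in docs)."""

    #: book a CAC-test cost for rescreened CAC=0 mass at each reassessment
    rescreen_test_costed: bool = True
    #: apply statin relative risks to first events in the current-practice arm;
    #: off means the first-event risk is the no-statin incidence for every LDL
    #: category (risk "the same regardless of LDL-C level")
    cp_first_event_rr: bool = True
    #: post-event risk beyond year 1: "recurrent_with_rr" / "recurrent" reuse
    #: the first-year probabilities with / without high-potency RRs;
    #: "quiescent_with_rr" / "quiescent" keep only the CVD-death channel;
    #: "baseline" reverts to the stratum's first-event incidences
    post_event_ongoing: str = "recurrent_with_rr"
    #: charge the high-potency statin cost in post-event states
    post_event_statin_cost: bool = True
    #: non-adherent mass does not fill prescriptions (no drug cost, no RR)
    statin_cost_scaled_by_adherence: bool = True
    #: trapezoidal half-cycle correction on rewards (off: simple annual accrual)
    half_cycle_correction: bool = False

    _ONGOING = ("recurrent_with_rr", "recurrent", "quiescent_with_rr",
                "quiescent", "baseline")

    def validate(self) -> None:
        if self.post_event_ongoing not in self._ONGOING:
            raise ValidationError(
                f"options.post_event_ongoing: {self.post_event_ongoing!r} unknown"
            )


@dataclass
class ParameterSet:
    """The complete calibrated input of the cost-utility model."""

    start_age: int
    end_age: int
    cycle_years: float
    discount_rate: float
    wtp_threshold: float
    perspective: str
    rescreen_interval: int
    initial: dict[str, InitialStratification]
    incidence: dict[str, EventIncidences]
    post_event: dict[str, PostEventProbabilities]
    statin_effect: dict[str, StatinEffect]
    cac_progression: CACProgressionTable
    costs: CostTable
    utilities: UtilityTable
    life_table: LifeTable
    adherence: dict[str, dict[str, float]] = field(default_factory=dict)
    options: ModelOptions = field(default_factory=ModelOptions)
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)
    tornado_parameters: list[str] = field(default_factory=list)

    # -- path access --------------------------------------------------------

    def get(self, path: str):
        """Fetch a scalar by dotted path, e.g. ``"incidence.cac_0.mi"``."""
        obj = self
        for token in path.split("."):
            if isinstance(obj, Mapping):
                if token not in obj:
                    raise ParameterError(f"unknown parameter path {path!r} (at {token!r})")
                obj = obj[token]
            elif isinstance(obj, list):
                obj = obj[int(token)]
            else:
                if not hasattr(obj, token):
                    raise ParameterError(f"unknown parameter path {path!r} (at {token!r})")
                obj = getattr(obj, token)
        return obj

    def set(self, path: str, value) -> None:
        tokens = path.split(".")
        obj = self
        for token in tokens[:-1]:
            if isinstance(obj, Mapping):
                if token not in obj:
                    raise ParameterError(f"unknown parameter path {path!r} (at {token!r})")
                obj = obj[token]
            elif isinstance(obj, list):
                obj = obj[int(token)]
            else:
                if not hasattr(obj, token):
                    raise ParameterError(f"unknown parameter path {path!r} (at {token!r})")
                obj = getattr(obj, token)
        last = tokens[-1]
        if isinstance(obj, Mapping):
            if last not in obj:
                raise ParameterError(f"unknown parameter path {path!r} (at {last!r})")
            obj[last] = value
        elif isinstance(obj, list):
            obj[int(last)] = value
        else:
            if not hasattr(obj, last):
                raise ParameterError(f"unknown parameter path {path!r} (at {last!r})")
            setattr(obj, last, value)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def adherence_for(self, arm: str, category: str) -> float:
        return self.adherence.get(arm, {}).get(category, 1.0)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.start_age >= self.end_age:
            raise ValidationError("start_age must be < end_age")
        if not 0 <= self.discount_rate <= 0.10:
            raise ValidationError(f"discount_rate {self.discount_rate} outside [0, 0.10]")
        if self.perspective not in ("societal", "provider"):
            raise ValidationError(f"unknown perspective {self.perspective!r}")
        if self.rescreen_interval <= 0:
            raise ValidationError("rescreen_interval must be positive")
        for arm in ARMS:
            if arm not in self.initial:
                raise ParameterError(f"initial.{arm} missing")
            self.initial[arm].validate()
        for stratum in INCIDENCE_STRATA:
            if stratum not in self.incidence:
                raise ParameterError(f"incidence.{stratum} missing")
            self.incidence[stratum].validate(f"incidence.{stratum}")
        for state in ("post_mi", "post_stroke"):
            if state not in self.post_event:
                raise ParameterError(f"post_event.{state} missing")
            self.post_event[state].validate(f"post_event.{state}")
        for potency in ("moderate", "high"):
            if potency not in self.statin_effect:
                raise ParameterError(f"statin_effect.{potency} missing")
            self.statin_effect[potency].validate(f"statin_effect.{potency}")
        self.cac_progression.validate()
        self.costs.validate()
        self.utilities.validate(self.start_age, self.end_age)
        self.life_table.validate(self.start_age, self.end_age)
        for arm, by_cat in self.adherence.items():
            for cat, a in by_cat.items():
                if not 0 <= a <= 1:
                    raise ValidationError(f"adherence.{arm}.{cat}: {a} outside [0,1]")
        self.options.validate()
        for path in self.tornado_parameters:
            if path != "discount_rate" and path not in self.distributions:
                raise ValidationError(f"tornado parameter {path!r} has no DistributionSpec")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "start_age": self.start_age,
            "end_age": self.end_age,
            "cycle_years": self.cycle_years,
            "discount_rate": self.discount_rate,
            "wtp_threshold": self.wtp_threshold,
            "perspective": self.perspective,
            "rescreen_interval": self.rescreen_interval,
            "initial": {a: asdict(s) for a, s in self.initial.items()},
            "incidence": {k: asdict(v) for k, v in self.incidence.items()},
            "post_event": {k: asdict(v) for k, v in self.post_event.items()},
            "statin_effect": {k: asdict(v) for k, v in self.statin_effect.items()},
            "cac_progression": [asdict(r) for r in self.cac_progression.rows],
            "costs": asdict(self.costs),
            "utilities": asdict(self.utilities),
            "life_table": dict(self.life_table.q),
            "adherence": {a: dict(c) for a, c in self.adherence.items()},
            "options": asdict(self.options),
            "distributions": {k: asdict(v) for k, v in self.distributions.items()},
            "tornado_parameters": list(self.tornado_parameters),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        ps = cls(
            start_age=d["start_age"],
            end_age=d["end_age"],
            cycle_years=d["cycle_years"],
            discount_rate=d["discount_rate"],
            wtp_threshold=d["wtp_threshold"],
            perspective=d["perspective"],
            rescreen_interval=d["rescreen_interval"],
            initial={a: InitialStratification(**s) for a, s in d["initial"].items()},
            incidence={k: EventIncidences(**v) for k, v in d["incidence"].items()},
            post_event={k: PostEventProbabilities(**v) for k, v in d["post_event"].items()},
            statin_effect={k: StatinEffect(**v) for k, v in d["statin_effect"].items()},
            cac_progression=CACProgressionTable(
                [CACProgressionBand(**r) for r in d["cac_progression"]]
            ),
            costs=CostTable(**d["costs"]),
            utilities=UtilityTable(**d["utilities"]),
            life_table=LifeTable({int(k): v for k, v in d["life_table"].items()}),
            adherence={a: dict(c) for a, c in d.get("adherence", {}).items()},
            options=ModelOptions(**d.get("options", {})),
            distributions={
                k: DistributionSpec(**v) for k, v in d.get("distributions", {}).items()
            },
            tornado_parameters=list(d.get("tornado_parameters", [])),
        )
        ps.utilities.no_cvd_by_age = {
            int(k): v for k, v in ps.utilities.no_cvd_by_age.items()
        }
        return ps


# ---------------------------------------------------------------------------
# config loading


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "base_case.yaml"


def _require(section: Mapping, key: str, context: str):
    if key not in section:
        raise ParameterError(f"{context}.{key}" if context else key)
    return section[key]


def _spec(entry, family: str, context: str) -> DistributionSpec:
    """Build a DistributionSpec from a ``{mean, se?, family?}`` mapping.

    A missing SE defaults to 10% of the mean (the convention used for the
    starred entries of the cost/utility tables).
    """
    if not isinstance(entry, Mapping) or "mean" not in entry:
        raise ParameterError(f"{context}: expected mapping with 'mean'")
    mean = float(entry["mean"])
    se = float(entry.get("se", 0.10 * abs(mean)))
    fam = entry.get("family", family)
    try:
        return DistributionSpec(fam, mean, se)
    except ValidationError as exc:
        raise ValidationError(f"{context}: {exc}") from exc


def _load_age_series(entry, what: str) -> dict[int, float]:
    """Read an ``age -> value`` series from inline mapping, CSV path, or
    synthetic-generator parameters."""
    from . import synthetic  # local import to avoid a cycle

    if "csv" in entry:
        import pandas as pd

        df = pd.read_csv(entry["csv"])
        cols = list(df.columns)
        return {int(a): float(v) for a, v in zip(df[cols[0]], df[cols[1]])}
    if "values" in entry:
        return {int(k): float(v) for k, v in entry["values"].items()}
    if "synthetic" in entry:
        syn = entry["synthetic"]
        if what == "life_table":
            return synthetic.generate_lifetable(
                q40=syn["q40"],
                log_increase=syn["log_increase"],
                start_age=syn.get("start_age", 40),
                end_age=syn.get("end_age", 75),
            ).q
        return synthetic.generate_no_cvd_utility(
            anchor_age=syn.get("anchor_age", 40),
            anchor_utility=syn.get("anchor_utility", 0.95),
            slope_per_year=syn.get("slope_per_year", 0.002),
            start_age=syn.get("start_age", 40),
            end_age=syn.get("end_age", 75),
        )
    raise ParameterError(f"{what}: expected one of csv / values / synthetic")


def load_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from a YAML config.

    Category-probability triples are proportionally renormalised (the printed
    CAC proportions sum to 1.01 because of rounding). Every distribution for
    the PSA is registered along the way.
    """
    path = Path(config_path) if config_path is not None else default_config_path()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ParameterError("config root must be a mapping")

    dists: dict[str, DistributionSpec] = {}

    initial = {}
    init_cfg = _require(cfg, "initial", "")
    for arm in ARMS:
        arm_cfg = _require(init_cfg, arm, "initial")
        probs, treat = {}, {}
        for cat, pos in zip(CATEGORIES[arm], TREATMENT_BY_POSITION):
            spec = _spec(_require(arm_cfg, cat, f"initial.{arm}"), "beta",
                         f"initial.{arm}.{cat}")
            dists[f"initial.{arm}.category_probs.{cat}"] = spec
            probs[cat] = spec.mean
            treat[cat] = pos
        strat = InitialStratification(arm, probs, treat)
        strat.normalize()
        initial[arm] = strat

    incidence = {}
    inc_cfg = _require(cfg, "incidence", "")
    for stratum in INCIDENCE_STRATA:
        s_cfg = _require(inc_cfg, stratum, "incidence")
        vals = {}
        for ev in ("mi", "stroke", "cvd_death"):
            spec = _spec(_require(s_cfg, ev, f"incidence.{stratum}"), "beta",
                         f"incidence.{stratum}.{ev}")
            dists[f"incidence.{stratum}.{ev}"] = spec
            vals[ev] = spec.mean
        incidence[stratum] = EventIncidences(**vals)

    post_event = {}
    pe_cfg = _require(cfg, "post_event", "")
    for state in ("post_mi", "post_stroke"):
        s_cfg = _require(pe_cfg, state, "post_event")
        vals = {}
        for f_ in ("recurrent_same", "other_event", "cvd_death"):
            spec = _spec(_require(s_cfg, f_, f"post_event.{state}"), "beta",
                         f"post_event.{state}.{f_}")
            dists[f"post_event.{state}.{f_}"] = spec
            vals[f_] = spec.mean
        post_event[state] = PostEventProbabilities(**vals)

    statin_effect = {}
    se_cfg = _require(cfg, "statin_effect", "")
    for potency in ("moderate", "high"):
        p_cfg = _require(se_cfg, potency, "statin_effect")
        vals = {}
        for f_ in ("rr_mi", "rr_stroke", "rr_cvd_death"):
            spec = _spec(_require(p_cfg, f_, f"statin_effect.{potency}"), "lognormal",
                         f"statin_effect.{potency}.{f_}")
            dists[f"statin_effect.{potency}.{f_}"] = spec
            vals[f_] = spec.mean
        statin_effect[potency] = StatinEffect(**vals)

    rows = []
    for i, row in enumerate(_require(cfg, "cac_progression", "")):
        for f_, col in (("p_to_1_99", "p_to_1_99"), ("p_to_ge100", "p_to_ge100")):
            spec = _spec({"mean": row[col], "se": row.get(f"{col}_se", 0.10 * row[col])},
                         "beta", f"cac_progression.{i}.{f_}")
            dists[f"cac_progression.rows.{i}.{f_}"] = spec
        rows.append(
            CACProgressionBand(
                age_lo=int(row["age_lo"]),
                age_hi=int(row["age_hi"]),
                p_to_1_99=float(row["p_to_1_99"]),
                p_to_ge100=float(row["p_to_ge100"]),
            )
        )
    cac_progression = CACProgressionTable(rows)

    cost_cfg = _require(cfg, "costs", "")
    cost_vals = {}
    for f_ in COST_FIELDS:
        spec = _spec(_require(cost_cfg, f_, "costs"), "gamma", f"costs.{f_}")
        dists[f"costs.{f_}"] = spec
        cost_vals[f_] = spec.mean
    costs = CostTable(**cost_vals)

    util_cfg = _require(cfg, "utilities", "")
    util_vals = {}
    for f_ in (
        "post_mi",
        "post_stroke",
        "post_mi_and_stroke",
        "disutil_recurrent_mi",
        "disutil_recurrent_stroke",
        "disutil_recurrent_with_prior_event",
    ):
        spec = _spec(_require(util_cfg, f_, "utilities"), "beta", f"utilities.{f_}")
        dists[f"utilities.{f_}"] = spec
        util_vals[f_] = spec.mean
    no_cvd = _load_age_series(_require(cfg, "no_cvd_utility", ""), "no_cvd_utility")
    utilities = UtilityTable(no_cvd_by_age=no_cvd, **util_vals)

    life_table = LifeTable(_load_age_series(_require(cfg, "life_table", ""), "life_table"))

    adherence_cfg = cfg.get("adherence", {}) or {}
    adherence = {a: {c: float(v) for c, v in by_cat.items()}
                 for a, by_cat in adherence_cfg.items()}

    options = ModelOptions(**(cfg.get("options", {}) or {}))

    tornado = cfg.get("tornado_parameters")
    if tornado is None:
        tornado = _default_tornado_list()

    ps = ParameterSet(
        start_age=int(cfg.get("start_age", 40)),
        end_age=int(cfg.get("end_age", 75)),
        cycle_years=float(cfg.get("cycle_years", 1.0)),
        discount_rate=float(_require(cfg, "discount_rate", "")),
        wtp_threshold=float(_require(cfg, "wtp_threshold", "")),
        perspective=str(cfg.get("perspective", "societal")),
        rescreen_interval=int(cfg.get("rescreen_interval", 5)),
        initial=initial,
        incidence=incidence,
        post_event=post_event,
        statin_effect=statin_effect,
        cac_progression=cac_progression,
        costs=costs,
        utilities=utilities,
        life_table=life_table,
        adherence=adherence,
        options=options,
        distributions=dists,
        tornado_parameters=list(tornado),
    )
    ps.validate()
    return ps


def _default_tornado_list() -> list[str]:
    """Parameters varied in the one-way sensitivity analysis: initial
    proportions, first-event incidences, statin prices, statin relative
    risks, health-state utilities, and the discount rate."""
    paths = []
    for arm in ARMS:
        for cat in CATEGORIES[arm]:
            paths.append(f"initial.{arm}.category_probs.{cat}")
    for stratum in INCIDENCE_STRATA:
        for ev in ("mi", "stroke", "cvd_death"):
            paths.append(f"incidence.{stratum}.{ev}")
    paths += ["costs.statin_moderate_annual", "costs.statin_high_annual"]
    for potency in ("moderate", "high"):
        for f_ in ("rr_mi", "rr_stroke", "rr_cvd_death"):
            paths.append(f"statin_effect.{potency}.{f_}")
    paths += ["utilities.post_mi", "utilities.post_stroke", "utilities.post_mi_and_stroke"]
    paths.append("discount_rate")
    return paths


# ---------------------------------------------------------------------------
# PSA sampling


def sample_parameter_set(
    params: ParameterSet, rng_seed: int | np.random.Generator
) -> ParameterSet:
    """Draw one parameter set from the registered uncertainty distributions.

    Unregistered fields are copied verbatim; category-probability triples are
    renormalised after sampling; the draw is validated (an infeasible draw,
    e.g. a relative risk above 1, raises :class:`ValidationError` so callers
    can count and exclude it).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    new = params.copy()
    for path, spec in params.distributions.items():
        new.set(path, spec.rvs(rng))
    for arm in ARMS:
        strat = new.initial[arm]
        strat.category_probs = {c: new.get(f"initial.{arm}.category_probs.{c}")
                                for c in CATEGORIES[arm]}
        strat.normalize()
    new.validate()
    return new
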