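# Methods

## Model structure

A decision tree splits the entering cohort (statin-naive, intermediate
10-year cardiovascular risk, age 40) into treatment strata, and a Markov
cohort model with annual cycles follows each stratum to age 75 (35
cycles). The eight health states are No CVD, post non-fatal MI, post
recurrent non-fatal MI, post non-fatal stroke, post recurrent non-fatal
stroke, post non-fatal MI-and-stroke, post recurrent MI-and-stroke, and
Dead (absorbing). Occupancy is fractional over cells
`(state, tunnel phase, risk category)`; tunnel phases mark the single
cycle after an acute event, in which first-year transition probabilities,
first-year (incident- or recurrent-specific) treatment costs and one-off
recurrence disutilities apply. The combined MI-and-stroke states encode
the incident event in their tunnel phase so that first-year costing can
charge the incident event's acute cost plus the other condition's
follow-up cost.

### Transitions

* **First events (No CVD).** Per person-year incidences of non-fatal MI,
  non-fatal stroke and CVD death are stratum-specific: the CAC arm uses
  the incidences of its current CAC category; the current-practice arm
  uses a single "no statin" incidence set for every LDL category (LDL-C
  drifts over time, so first-event risk is assumed not to track the
  entry category). Statin relative risks by potency then scale the rates,
  blended by adherence a as `a·RR + (1 − a)`; rates become per-cycle
  probabilities via `1 − exp(−r·t)`.
* **Post-event states.** The printed first-year probabilities (recurrent
  event, other event, CVD death) act in the tunnel cycle. Beyond the
  first year the same probabilities are reused with the high-potency
  relative risks applied, since every post-event patient is switched to a
  high-potency statin. Recurrent states reuse their first-event
  probabilities; the combined state uses the element-wise maximum of the
  MI and stroke profiles (a conservative choice; no combined values are
  published). Both conventions are switches
  (`options.post_event_ongoing`: `recurrent_with_rr` (default),
  `recurrent`, `quiescent[_with_rr]`, `baseline`;
  `options.cp_first_event_rr`).
* **Background mortality.** A non-CVD life table q(age) adds a marginal
  death probability to every alive cell; the residual goes to "stay". If
  marginal probabilities ever exceeded 1 they would be proportionally
  rescaled — at the base-case magnitudes this never triggers.
* **Rescreening.** In the CAC arm, No-CVD mass in CAC=0 is reassessed at
  ages 45, 50, …, 70 (the progression table covers 45–74), converting to
  CAC 1–99 (moderate statin) and CAC ≥ 100 (high statin) with the
  attained-age band's 5-year probabilities, conditional on a prior zero
  score. Each reassessment books one CAC-test cost for the rescreened
  mass (`options.rescreen_test_costed`).

### Rewards and discounting

Cycle timing is simple annual accounting: events occur at cycle end and
rewards accrue for the state occupied during the cycle; the first year is
undiscounted and cycle t is discounted by (1 + r)^(−t) at r = 3%/yr
(varied 0–5%). A trapezoidal half-cycle correction exists as a switch
(`options.half_cycle_correction`, default off) but is not part of the
base case. Costs (2024 THB, societal perspective) comprise statin costs
(moderate 2,589 / high 9,071 THB/yr; the non-adherent fraction neither
benefits nor pays, switchable), CAC tests (4,000 THB; once at entry for
the whole screening arm, again at each rescreen), event costs (first-year
and recurrent first-year acute costs on tunnel mass, annual follow-up
costs otherwise), and direct non-medical costs, dropped under the
provider perspective. Death carries no terminal cost. QALYs weight
occupancy by state utilities (age-specific No-CVD utility; post-MI 0.828;
post-stroke 0.690; combined 0.678) minus one-off recurrence disutilities
(0.147 MI, 0.226 stroke, 0.187 with a prior event) on tunnel mass.

### Decision rule

ΔC and ΔQ compare CAC screening against current practice; the verdict is
dominant (cheaper, more effective), dominated (the reverse), or decided
by net monetary benefit λ·ΔQ − ΔC at λ = 160,000 THB/QALY.

## Parameter uncertainty

Every printed parameter carries a (family, mean, SE) distribution:
beta for probabilities, proportions and utilities, gamma for costs,
lognormal for relative risks, matched by method of moments (round-trip
exact to 1e-9). A missing SE defaults to 10% of the mean, the convention
the parameter tables themselves use for starred entries. The PSA redraws
all registered parameters independently (1,000 draws by default),
renormalises category-probability triples, revalidates each draw, and
excludes (without redrawing) any draw violating a model invariant, e.g. a
relative risk above 1 — with the printed SEs this effectively never
happens. Per-draw seeds derive from the master seed by counter. The
age-specific No-CVD utility and the life table are not sampled (no SEs
exist for them). The tornado analysis varies one parameter at a time to
mean ± 1.96·SE truncated to its domain (probabilities [0,1], relative
risks (0,1], costs ≥ 0; discount rate over [0, 0.05]) and ranks by ICER
spread.

## Synthetic stand-ins

Two inputs exist only as supplementary material and one as an
unpublished hospital database; `cacscreen.synthetic` generates
statistically structured stand-ins, so passing tests demonstrate the
pipeline's correctness on realistic inputs, not agreement with the
unpublished data themselves:

* **Life table** — Gompertz form q(age) = q40·exp(b·(age − 40)). The
  defaults q40 = 0.0012, b = 0.09 were calibrated once, as the
  documented, spec-sanctioned procedure, so that base-case discounted
  life-years land near the published 19.37/19.88 (achieved 19.52/19.81);
  b = 0.09/yr is the conventional adult mortality slope. The table is
  interpreted as background non-CVD mortality, applied on top of modelled
  CVD death to avoid double counting.
* **No-CVD utility** — anchor 0.95 at age 40 declining linearly by
  0.002/yr, a plausible population-norm shape; any CSV of per-age values
  can replace it.
* **Hospital-style records** — per-patient LDL and CAC categories (drawn
  independently; nothing published constrains their correlation) and a
  5-year CAC conversion outcome, with binomial estimators that close a
  parameter-recovery loop feeding beta distributions exactly as the
  entry-proportion inputs were derived.

## Numerical choices

Category-probability triples are proportionally renormalised at load (the
printed CAC proportions sum to 1.01 through rounding; occupancy must
conserve mass). The stroke follow-up cost printed as "37,7812" is read as
37,781 THB/yr (its SE, 3,198, is ~10% of that reading). Mass conservation
is enforced to 1e-9 per cycle and dead-state occupancy must be
non-decreasing; violations are hard failures, not warnings. Price
thresholds are found by bisection to |ICER − λ| < 1 THB/QALY after a
numerical monotonicity check over the bracket.

## Reproduction limits

The published result blocks cannot all be derived from one internally
consistent model of the printed parameter tables, so this implementation
reproduces some and documents the rest:

* Reproduced within 10%: absolute per-arm discounted costs, life-years
  and QALYs; the identity of the most influential tornado parameter
  (untreated stroke incidence) with an ICER range crossing zero; the
  qualitative scenario verdicts (screening dominant at low high-potency
  statin prices, monotone improvement as current-practice adherence
  falls).
* Not reproduced: the published incremental block (ΔC 10,091 / ΔQ 0.62 /
  ICER 16,308; this implementation yields 1,726 / 0.36 / 4,796) and the
  scenario ICERs that inherit it. A systematic sweep over the open
  conventions shows why: the only convention matching the published
  incremental effectiveness at 0/3/5% discounting (no statin RR on
  current-practice first events, first-year risks persisting without RR)
  is contradicted by the published adherence scenarios — which require
  the RR to bind in the current-practice arm, and whose ΔQ of 1.07 at
  19%/~55% adherence exceeds what any monotone RR model of the printed
  inputs can produce — while the published price-scenario cost slopes
  imply a between-arm event-cost difference roughly half of what those
  same effectiveness flows generate under the printed cost table. The
  defaults therefore follow the stated assumptions directly; every
  explored alternative remains available as a configuration switch.
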