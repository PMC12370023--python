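# cacscreen

Cost-utility analysis of coronary artery calcium (CAC) screening to guide
statin initiation for primary cardiovascular prevention in adults at
intermediate 10-year risk, implemented as a reusable, tested Python
pipeline for the Thai setting (2024 THB, societal perspective).

## Who this is for

Health-economic modellers and HTA analysts who want a decision-tree +
Markov cohort model they can rerun, audit, and stress-test: every input is
a validated, serialisable parameter with an uncertainty distribution, and
every published-style output (incremental cost-effectiveness ratio,
acceptability curve, tornado diagram, scenario battery) is a library call.

## The model

Two strategies allocate statins to a statin-naive cohort entering at age
40:

* **Current practice** — LDL-C based: LDL-C ≥ 190 mg/dL → high-potency
  statin, 70–189 → moderate-potency, < 70 → none.
* **CAC screening** — a non-contrast cardiac CT stratifies by Agatston
  score: ≥ 100 → high-potency, 1–99 → moderate-potency, 0 → no statin with
  reassessment every 5 years (age-banded probabilities of developing a
  positive score).

Each stratum then walks an annual-cycle Markov model over 35 years with
eight health states: No CVD, post (recurrent) non-fatal MI, post
(recurrent) non-fatal stroke, post (recurrent) MI-and-stroke, and Dead.
Tunnel sub-states carry first-year post-event risks, costs and recurrence
disutilities; statin relative risks (RR) scale first-event rates
r → r·(a·RR + 1 − a) under adherence a; rates convert to probabilities by
p = 1 − exp(−r·t); background non-CVD mortality q(age) acts on every alive
state. Discounted totals per arm give costs C, life-years and QALYs Q, and
strategies compare through

ICER = ΔC / ΔQ  vs a willingness-to-pay threshold λ = 160,000 THB/QALY,

with probabilistic sensitivity analysis (beta/gamma/lognormal
method-of-moments distributions, 1,000 draws), CEAC over λ ∈ [0, 600k],
one-way tornado analysis, and a named scenario battery (adherence, drug
and test prices, halved CAC=0 risks, MESA initial distribution, provider
perspective, 0–5% discounting). See `docs/methods.md` for assumptions,
conventions and reproduction limits.

## Worked example

```python
from cacscreen import CACScreeningModel

model = CACScreeningModel.from_config()   # bundled base case
results = model.fit()
print(results.summary())
```

```
Cost-utility analysis: CAC screening vs current practice
==========================================================
                            Current practice CAC screening
Costs (THB)                          339,307       341,033
Life years                             19.52         19.81
QALYs                                  17.45         17.81
----------------------------------------------------------
Incremental cost (THB)                               1,726
Incremental QALYs                                     0.36
ICER (THB/QALY)                                      4,796
Verdict at WTP 160,000 THB/QALY             cost_effective
```

CAC screening buys 0.36 QALYs per person for 1,726 THB extra — about
4,800 THB per QALY gained, far below the Thai willingness-to-pay
threshold, so screening is cost-effective under the base-case inputs
(the two supplementary inputs, age-specific No-CVD utility and the
background life table, are synthetic stand-ins; see `docs/methods.md`).

Uncertainty and scenarios hang off the same object:

```python
psa = model.psa(n_draws=1000, seed=1)
psa.prob_cost_effective(160_000)          # 0.913
psa.ceac()                                # DataFrame: threshold, probability

model.tornado().head(1)                   # most influential: untreated stroke incidence
model.run_scenario("discount_0")          # 0% discounting
model.price_threshold("costs.cac_test", bracket=(4_000, 300_000))
```

A CLI mirrors the library: `cacscreen basecase`, `cacscreen psa`,
`cacscreen tornado`, `cacscreen scenario --all`, `cacscreen synth`, each
writing CSV/JSON plus a run manifest.

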