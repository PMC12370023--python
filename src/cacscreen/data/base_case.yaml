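# Base-case inputs for the CAC-screening cost-utility model.
# Monetary values are annual 2024 THB (cac_test: THB per test); incidences
# are rates per person-year; an omitted `se` defaults to 10% of the mean.

start_age: 40
end_age: 75
cycle_years: 1.0
discount_rate: 0.03
wtp_threshold: 160000
perspective: societal
rescreen_interval: 5

initial:
  current_practice:
    ldl_ge190:  {mean: 0.018, se: 0.013}
    ldl_70_189: {mean: 0.759, se: 0.04}
    ldl_lt70:   {mean: 0.223, se: 0.04}
  cac_screening:
    cac_ge100:  {mean: 0.36, se: 0.013}
    cac_1_99:   {mean: 0.39, se: 0.013}
    cac_0:      {mean: 0.26, se: 0.012}

incidence:
  # first CVD event without statin therapy (used for every LDL category in
  # the current-practice arm, which does not re-stratify by LDL over time)
  no_statin_overall:
    mi:        {mean: 0.00558, se: 0.00039}
    stroke:    {mean: 0.01348, se: 0.00106}
    cvd_death: {mean: 0.00148, se: 0.00013}
  cac_0:
    mi:        {mean: 0.00325, se: 0.00050}
    stroke:    {mean: 0.00883, se: 0.00137}
    cvd_death: {mean: 0.00105, se: 0.00016}
  cac_1_99:
    mi:        {mean: 0.00340, se: 0.00042}
    stroke:    {mean: 0.00918, se: 0.00114}
    cvd_death: {mean: 0.00103, se: 0.00014}
  cac_ge100:
    mi:        {mean: 0.00626, se: 0.00064}
    stroke:    {mean: 0.01689, se: 0.00175}
    cvd_death: {mean: 0.00190, se: 0.00021}

post_event:
  post_mi:
    recurrent_same: {mean: 0.1000, se: 0.0010}   # first-year recurrent MI
    other_event:    {mean: 0.0240, se: 0.0004}   # first-year stroke
    cvd_death:      {mean: 0.0810, se: 0.0010}
  post_stroke:
    recurrent_same: {mean: 0.0900, se: 0.0010}   # first-year recurrent stroke
    other_event:    {mean: 0.0095, se: 0.0004}   # first-year MI
    cvd_death:      {mean: 0.0340, se: 0.0040}

statin_effect:
  moderate:
    rr_mi:        {mean: 0.76, se: 0.026}
    rr_stroke:    {mean: 0.86, se: 0.041}
    rr_cvd_death: {mean: 0.88, se: 0.020}
  high:
    rr_mi:        {mean: 0.58, se: 0.026}
    rr_stroke:    {mean: 0.74, se: 0.041}
    rr_cvd_death: {mean: 0.77, se: 0.020}

# 5-yearly conversion out of CAC=0 by attained-age band (hospital data)
cac_progression:
  - {age_lo: 45, age_hi: 49, p_to_1_99: 0.341, p_to_ge100: 0.158}
  - {age_lo: 50, age_hi: 54, p_to_1_99: 0.338, p_to_ge100: 0.195}
  - {age_lo: 55, age_hi: 59, p_to_1_99: 0.331, p_to_ge100: 0.237}
  - {age_lo: 60, age_hi: 64, p_to_1_99: 0.319, p_to_ge100: 0.284}
  - {age_lo: 65, age_hi: 69, p_to_1_99: 0.302, p_to_ge100: 0.336}
  - {age_lo: 70, age_hi: 74, p_to_1_99: 0.281, p_to_ge100: 0.390}

costs:
  statin_moderate_annual:      {mean: 2589}
  statin_high_annual:          {mean: 9071}
  cac_test:                    {mean: 4000}
  mi_first_year:               {mean: 149285, se: 68107}
  mi_recurrent_first_year:     {mean: 149285, se: 68107}
  mi_followup_annual:          {mean: 29340, se: 2934}
  stroke_first_year:           {mean: 191467, se: 54378}
  stroke_recurrent_first_year: {mean: 92396, se: 7670}
  # printed as 37,7812(3,198); the SE pattern identifies 37,781 THB/yr
  stroke_followup_annual:      {mean: 37781, se: 3198}
  nonmed_mi_first_year:        {mean: 3667}
  nonmed_mi_followup:          {mean: 5304}
  nonmed_stroke_first_year:    {mean: 72309, se: 2279}
  nonmed_stroke_followup:      {mean: 46390, se: 1470}

utilities:
  post_mi:             {mean: 0.828, se: 0.038}
  post_stroke:         {mean: 0.69, se: 0.062}
  post_mi_and_stroke:  {mean: 0.678, se: 0.036}
  disutil_recurrent_mi:     {mean: 0.147, se: 0.015}
  disutil_recurrent_stroke: {mean: 0.226, se: 0.022}
  disutil_recurrent_with_prior_event: {mean: 0.187, se: 0.019}

# Synthetic stand-in for the age-specific No-CVD utility table
no_cvd_utility:
  synthetic: {anchor_age: 40, anchor_utility: 0.95, slope_per_year: 0.002}

# Synthetic Gompertz background (non-CVD) mortality; parameters calibrated
# once so base-case discounted life-years land near the published ~19.4/19.9
life_table:
  synthetic: {q40: 0.0012, log_increase: 0.09}

adherence: {}

options:
  rescreen_test_costed: true
  # Both arms apply potency-specific statin relative risks to first events
  # (the current-practice arm shares one first-event risk across LDL
  # categories); post-event cycles beyond year 1 reuse the first-year
  # probabilities with the high-potency relative risks applied. Alternative
  # conventions remain available as switches (see docs/methods.md).
  cp_first_event_rr: true
  post_event_ongoing: recurrent_with_rr
  post_event_statin_cost: true
  statin_cost_scaled_by_adherence: true
  half_cycle_correction: false
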