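# Deterministic scenario battery. Unit prices are THB per tablet and are
# annualised at 365.25 doses/year; adherence fractions are per arm and
# risk category (the non-adherent fraction receives neither the statin
# relative risk nor the drug cost).

- name: base_case
  description: No overrides; must reproduce the base case bit-for-bit.
  overrides: {}

- name: adherence_19
  description: 19% statin adherence under current practice vs CAC-aware adherence.
  overrides:
    adherence:
      current_practice: {ldl_ge190: 0.19, ldl_70_189: 0.19, ldl_lt70: 0.19}
      cac_screening: {cac_ge100: 0.56, cac_1_99: 0.52, cac_0: 0.36}

- name: adherence_30
  description: 30% statin adherence under current practice vs CAC-aware adherence.
  overrides:
    adherence:
      current_practice: {ldl_ge190: 0.30, ldl_70_189: 0.30, ldl_lt70: 0.30}
      cac_screening: {cac_ge100: 0.56, cac_1_99: 0.52, cac_0: 0.36}

- name: adherence_52
  description: 52% statin adherence under current practice vs CAC-aware adherence.
  overrides:
    adherence:
      current_practice: {ldl_ge190: 0.52, ldl_70_189: 0.52, ldl_lt70: 0.52}
      cac_screening: {cac_ge100: 0.56, cac_1_99: 0.52, cac_0: 0.36}

- name: statin_high_15_per_unit
  overrides:
    unit_prices: {costs.statin_high_annual: 15}

- name: statin_high_20_per_unit
  overrides:
    unit_prices: {costs.statin_high_annual: 20}

- name: statin_high_30_per_unit
  overrides:
    unit_prices: {costs.statin_high_annual: 30}

- name: statin_high_35_per_unit
  overrides:
    unit_prices: {costs.statin_high_annual: 35}

- name: cac_test_2000
  overrides: {costs.cac_test: 2000}

- name: cac_test_6000
  overrides: {costs.cac_test: 6000}

- name: cac_test_8000
  overrides: {costs.cac_test: 8000}

- name: cac0_mi_half
  description: Non-fatal MI incidence in CAC=0 halved (printed half value).
  overrides: {incidence.cac_0.mi: 0.00160}

- name: cac0_stroke_half
  description: Non-fatal stroke incidence in CAC=0 halved (printed half value).
  overrides: {incidence.cac_0.stroke: 0.00440}

- name: cac0_cvd_death_half
  description: CVD-death incidence in CAC=0 halved (printed half value).
  overrides: {incidence.cac_0.cvd_death: 0.00052}

- name: cac0_all_half
  description: All CAC=0 event incidences halved jointly.
  overrides:
    incidence.cac_0.mi: 0.001625
    incidence.cac_0.stroke: 0.004415
    incidence.cac_0.cvd_death: 0.000525

- name: mesa_initial_distribution
  description: Initial CAC distribution from the MESA cohort (0.24 / 0.26 / 0.50).
  overrides:
    initial.cac_screening.category_probs.cac_ge100: 0.24
    initial.cac_screening.category_probs.cac_1_99: 0.26
    initial.cac_screening.category_probs.cac_0: 0.50

- name: progression_cac_consortium
  description: >
    Slower CAC progression; synthetic stand-in for the CAC Consortium
    prediction model (hospital-table conversion probabilities halved).
  overrides:
    cac_progression:
      - {age_lo: 45, age_hi: 49, p_to_1_99: 0.1705, p_to_ge100: 0.079}
      - {age_lo: 50, age_hi: 54, p_to_1_99: 0.169, p_to_ge100: 0.0975}
      - {age_lo: 55, age_hi: 59, p_to_1_99: 0.1655, p_to_ge100: 0.1185}
      - {age_lo: 60, age_hi: 64, p_to_1_99: 0.1595, p_to_ge100: 0.142}
      - {age_lo: 65, age_hi: 69, p_to_1_99: 0.151, p_to_ge100: 0.168}
      - {age_lo: 70, age_hi: 74, p_to_1_99: 0.1405, p_to_ge100: 0.195}

- name: provider_perspective
  description: Direct non-medical costs excluded.
  overrides: {perspective: provider}

- name: discount_0
  overrides: {discount_rate: 0.0}

- name: discount_5
  overrides: {discount_rate: 0.05}
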