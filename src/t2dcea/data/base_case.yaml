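# Base-case inputs for the second-line T2D treatment-pathway model.
# All costs in 2015 USD; all rates are annual probabilities.
discount_rate: 0.03
horizon: 25
start_age: 60
cycle_length: 1
cost_accrual: post

mortality:
  bands:
    - {age_low: 60, age_high: 70, annual_death_probability: 0.021}
    - {age_low: 71, age_high: 80, annual_death_probability: 0.051}
    - {age_low: 81, age_high: 85, annual_death_probability: 0.107}

event_rates_by_state:
  mono:
    severe_hypoglycemia: 0.0
    hypoglycemia_medical_assistance: 0.0
    myocardial_infarction: 0.004
    heart_failure: 0.003
    stroke: 0.003
    weight_gain_first_year: 0.0
  dual_dpp4i:
    severe_hypoglycemia: 0.0
    hypoglycemia_medical_assistance: 0.0
    myocardial_infarction: 0.004
    heart_failure: 0.017
    stroke: 0.002
    weight_gain_first_year: 0.0
  dual_su:
    severe_hypoglycemia: 0.016
    hypoglycemia_medical_assistance: 0.009
    myocardial_infarction: 0.0
    heart_failure: 0.020
    stroke: 0.020
    weight_gain_first_year: 0.510
  triple:
    severe_hypoglycemia: 0.010
    hypoglycemia_medical_assistance: 0.0
    myocardial_infarction: 0.009
    heart_failure: 0.009
    stroke: 0.009
    weight_gain_first_year: 0.0

unit_costs:
  myocardial_infarction: 18627
  heart_failure: 14118
  stroke: 7939
  hypo_medical_assistance: 199
  severe_hypo: 146
  weight_gain: 289
  drug_metformin: 24
  drug_dpp4i: 3500
  drug_su: 16
  drug_insulin_glargine: 3646

pathways:
  dpp4i:
    second_line_agent: DPP4i
    failure_rate_mono: 0.046
    failure_rate_dual: 0.013
    dual_state_death_hazard_ratio: 1.0
    weight_gain_transition_cost_applies: false
  su:
    second_line_agent: SU
    failure_rate_mono: 0.046
    failure_rate_dual: 0.053
    dual_state_death_hazard_ratio: 1.85
    weight_gain_transition_cost_applies: true
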