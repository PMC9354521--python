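# Base-case inputs: first-line nivolumab + ipilimumab vs platinum-pemetrexed
# chemotherapy in unresectable malignant pleural mesothelioma.
# Time is months throughout the survival layer; prices are 2021 USD per
# 3-week cycle.
units:
  time: months
  currency: USD-2021

settings:
  cycle_days: 21
  horizon_years: 10
  annual_discount: 0.03
  half_cycle: true
  mode: partitioned
  annual_step_discount: false

wtp:
  per_qaly: 207659          # 3 x 2021 US GDP per capita (69,231)

costs:                      # USD per 3-week cycle
  cisplatin: 48.6108
  carboplatin: 55.80288
  pemetrexed: 12832.512
  nivolumab: 18419.94
  ipilimumab: 11258.31
  laboratory_test: 157.5
  follow_up: 59.2
  administration: 69.81
  best_supportive_care: 117.1
  pembrolizumab: 21479.6
  vinorelbine: 227.2756
  body_surface_area: 1.68   # m^2, dosing constant behind the unit prices

utilities:
  pfs: 0.65
  pd: 0.47

strategies:
  intervention:
    name: nivolumab_ipilimumab
    os:  {family: weibull,   parameters: [1.19536, 25.48855]}
    pfs: {family: lognormal, parameters: [1.88660, 1.23141]}
    on_treatment: {nivolumab: 1.0, ipilimumab: 1.0}
    max_treatment_cycles: null          # treat while progression-free
    adverse_events:
      - {name: diarrhea,          risk: 0.003, cost: 303.0,  disutility: -0.047}
      - {name: increased_lipase,  risk: 0.005, cost: 2933.0, disutility: -0.47}
      - {name: increased_amylase, risk: 0.003, cost: 2933.0, disutility: -0.47}
    subsequent:
      immunotherapy: 0.033
      chemotherapy: 0.432
      immunotherapy_drug: pembrolizumab
      chemotherapy_drug: vinorelbine
      duration_cycles: 6
  comparator:
    name: chemotherapy
    os:  {family: loglogistic, parameters: [1.7027, 14.1088]}
    pfs: {family: loglogistic, parameters: [2.185, 7.392]}
    on_treatment: {pemetrexed: 1.0, cisplatin: 0.5, carboplatin: 0.5}
    max_treatment_cycles: 6             # induction chemotherapy cap
    adverse_events:
      - {name: anemia,             risk: 0.36, cost: 493.04, disutility: -0.09}
      - {name: nausea,             risk: 0.36, cost: 218.27, disutility: -0.048}
      - {name: decreased_appetite, risk: 0.18, cost: 115.4,  disutility: -0.038}
    subsequent:
      immunotherapy: 0.202
      chemotherapy: 0.315
      immunotherapy_drug: pembrolizumab
      chemotherapy_drug: vinorelbine
      duration_cycles: 6
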