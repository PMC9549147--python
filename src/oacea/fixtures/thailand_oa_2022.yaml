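# Knee-osteoarthritis care-sequence model, Thailand (published 2022 inputs).
#
# All money in THB; probabilities are per 6-month cycle.  Drug costs are the
# cost of a 6-month cycle at the stated maximum daily dose (diclofenac_ppi is
# diclofenac 150 mg/day, 128, plus omeprazole 20 mg/day, 94; ta_injection is
# two 3-monthly 40 mg injections at 114 each).  TKA is a one-time procedure
# cost at state entry.  Laboratory costs, doctor fees and productivity losses
# are declared in the source costing but unpublished; they default to 0 via
# economics.indirect_cost_per_cycle.
states:
  acetaminophen:
    pain_relief_prob: 0.3380
    cycle_cost: 213.0
    ae_incidence:
      gi_discomfort: 0.2382
      symptomatic_ulcer: 0.0007
      stroke: 0.0005
      mi: 0.0013
      heart_failure: 0.0000
  diclofenac_ppi:
    pain_relief_prob: 0.8647
    cycle_cost: 222.0          # diclofenac 128 + omeprazole 94
    ae_incidence:
      gi_discomfort: 0.1013
      symptomatic_ulcer: 0.0044
      stroke: 0.1012
      mi: 0.2289
      heart_failure: 0.0007
  etoricoxib:
    pain_relief_prob: 0.5657
    cycle_cost: 5213.0
    ae_incidence:
      gi_discomfort: 0.0556
      symptomatic_ulcer: 0.0014
      stroke: 0.1071
      mi: 0.2107
      heart_failure: 0.0010
  crystalline_glucosamine_sulfate:
    pain_relief_prob: 0.3857
    cycle_cost: 1874.0
    ae_incidence:
      gi_discomfort: 0.1093
      symptomatic_ulcer: 0.0000
      stroke: 0.0019
      mi: 0.0019
      heart_failure: 0.0000
  ta_injection:
    pain_relief_prob: 0.0392
    cycle_cost: 228.0          # 114 per 3-monthly injection, two per cycle
    ae_incidence: {}
  tka:
    pain_relief_prob: 0.5122
    cycle_cost: 0.0
    one_time_cost: 78925.0
    is_terminal_treatment: true
    ae_incidence:
      symptomatic_ulcer: 0.0899
      mi: 0.0469
      heart_failure: 0.0100

# The six published care sequences.  Etoricoxib (a COX-2 selective NSAID) is
# placed after diclofenac+PPI, before TA injection.
strategies:
  standard:
    [acetaminophen, diclofenac_ppi, ta_injection, tka]
  standard_plus_glucosamine_before_diclofenac_ppi:
    [acetaminophen, crystalline_glucosamine_sulfate, diclofenac_ppi,
     ta_injection, tka]
  standard_plus_glucosamine_after_diclofenac_ppi:
    [acetaminophen, diclofenac_ppi, crystalline_glucosamine_sulfate,
     ta_injection, tka]
  standard_plus_etoricoxib:
    [acetaminophen, diclofenac_ppi, etoricoxib, ta_injection, tka]
  standard_plus_etoricoxib_plus_glucosamine_before_diclofenac_ppi:
    [acetaminophen, crystalline_glucosamine_sulfate, diclofenac_ppi,
     etoricoxib, ta_injection, tka]
  standard_plus_etoricoxib_plus_glucosamine_after_diclofenac_ppi:
    [acetaminophen, diclofenac_ppi, crystalline_glucosamine_sulfate,
     etoricoxib, ta_injection, tka]

# Adverse-event treatment costs (THB) with standard errors, and EQ-5D
# disutilities.  Chronic events: acute = event cycle, first_year = the
# following year, subsequent_year = each later year.
ae_costs:
  gi_discomfort:
    acute_cost: 436.0
    acute_cost_se: 11.0
    disutility: -0.0228
    disutility_se: 0.0001
  symptomatic_ulcer:
    acute_cost: 3734.0
    acute_cost_se: 95.0
    disutility: -0.0269
    disutility_se: 0.0002
  stroke:
    acute_cost: 56133.0
    acute_cost_se: 1432.0
    first_year_cost: 7173.0
    first_year_cost_se: 183.0
    subsequent_year_cost: 10029.0
    subsequent_year_cost_se: 256.0
    disutility: -0.0524
    disutility_se: 0.0001
  mi:
    acute_cost: 138916.0
    acute_cost_se: 3544.0
    first_year_cost: 4706.0
    first_year_cost_se: 120.0
    subsequent_year_cost: 13588.0
    subsequent_year_cost_se: 347.0
    disutility: -0.0409
    disutility_se: 0.0002
  heart_failure:
    acute_cost: 15347.0
    acute_cost_se: 392.0
    first_year_cost: 3974.0
    first_year_cost_se: 101.0
    subsequent_year_cost: 7948.0
    subsequent_year_cost_se: 203.0
    disutility: -0.0635
    disutility_se: 0.0002

utilities:
  no_pain: 0.62
  no_pain_se: 0.0036
  moderate_pain: 0.56
  moderate_pain_se: 0.0152

economics:
  annual_discount_rate: 0.03
  cycle_length_years: 0.5
  wtp_per_qaly: 160000.0
  fx_thb_per_usd: 36.16
  start_age_years: 45.0
  max_age_years: 110.0
  visit_cost_per_cycle: 196.0   # one outpatient visit: travel 143 + food 53
  indirect_cost_per_cycle: 0.0

# Background mortality: synthetic demo life table (not published input data).
mortality:
  mode: age_table
  table_file: life_table_demo_synthetic.csv

uncertainty:
  # Probabilities published without SEs sample with se = 20% of the mean.
  default_se_fraction: 0.20
  overrides:
    econ.visit_cost_per_cycle: {se: 13.0, family: gamma}

# One-way sensitivity ranges.  TKA cost and moderate-pain utility ranges are
# published; the others default to +/-20% of the base value (probabilities
# capped at 1).
dsa:
  - {param: utilities.moderate_pain, low: 0.35, high: 0.77}
  - {param: states.tka.one_time_cost, low: 78533.0, high: 79316.0}
  - {param: states.crystalline_glucosamine_sulfate.cycle_cost, low: 1499.2, high: 2248.8}
  - {param: states.diclofenac_ppi.pain_relief_prob, low: 0.69176, high: 1.0}
  - {param: states.ta_injection.pain_relief_prob, low: 0.03136, high: 0.04704}
  - {param: states.tka.pain_relief_prob, low: 0.40976, high: 0.61464}
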