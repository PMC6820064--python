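# Base-case model inputs (2019 US dollars).  Strategies may alternatively be
# given an `npv:` key (negative predictive value); the postdischarge risk is
# then 1 - npv.
short_strategy:
  label: 1-h observation
  observation_hours: 1.0
  postdischarge_biphasic_prob: 0.05
extended_strategy:
  label: 6-h observation
  observation_hours: 6.0
  postdischarge_biphasic_prob: 0.027
costs:
  direct_hourly: 286.92
  indirect_hourly: 27.77
  perspective: healthcare_sector
fatality:
  case_fatality: 0.0033
  fold: 10
distributions:        # [min, mode, max]
  direct_hourly: [100.0, 286.92, 500.0]
  indirect_hourly: [0.0, 27.77, 50.0]
  extended_hours: [6.0, 6.0, 24.0]
  p_short: [0.01, 0.05, 0.05]
  p_extended: [0.01, 0.027, 0.027]
  case_fatality: [0.0025, 0.0033, 0.0033]
wtp_per_biphasic: 10000.0
wtp_per_death: 10000000.0
horizon_hours: 78.0
n_iterations: 10000
seed: 2019
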