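# Shipped run configuration: male projection 2015-2025 under the six
# tobacco-control scenarios, on the synthetic demography.
base_year: 2015
horizon_end: 2025
sex: male
# Annual probability a former smoker resumes smoking. The source surveys do
# not identify this rate; it is a required, explicit parameter. The shipped
# value lies in the meta-analytic range for sustained quitters and is
# calibrated so the baseline run tracks the published slow decline in male
# smoking prevalence.
relapse_rate: 0.07
anchor_prevalence_2010: 41.7
target_relative_reduction: 0.30
scenarios:
  - {name: baseline, type: identity}
  - {name: youth_access, type: youth_access, params: {reduction: 0.5}}
  - {name: tax, type: tax,
     params: {annual_price_increase: 0.15, elasticity: -0.5, quitting_share: 0.5, youth_factor: 2}}
  - {name: quit_line, type: coverage, params: {coverage: 0.12, success: 0.195}}
  - {name: brief_advice, type: coverage, params: {coverage: 0.30, success: 0.66}}
  - {name: combined, type: combined,
     params: {components: [youth_access, tax, quit_line, brief_advice]}}
  - {name: theoretical, type: theoretical, params: {include_tax: true}}
synthetic:
  base_population: {male: 27000000, female: 28000000}
  growth_rate: 0.003
  age_mode: 45.0
  age_spread_young: 20.0
  age_spread_old: 12.0
  gompertz_level: 0.0010
  gompertz_slope: 0.068
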