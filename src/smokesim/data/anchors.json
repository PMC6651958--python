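{
  "anchor_prevalence_2010_male": 41.7,
  "survey_prevalence_2015_male": 40.8,
  "table2_overall_current_male": 40.5,
  "target_relative_reduction": 0.30,
  "quit_duration_shares": [0.659, 0.105, 0.237],
  "reported_2025_prevalence": {
    "baseline": 37.8,
    "tax": 36.1,
    "combined": 33.7,
    "theoretical": 28.5
  },
  "table4_cumulative": {
    "baseline_all_cause": 2235851,
    "youth_access": 9668,
    "tax": 24164,
    "quit_line": 6816,
    "brief_advice": 54999,
    "combined": 99784
  },
  "table4_reduction_pct": {
    "youth_access": 0.43,
    "tax": 1.08,
    "quit_line": 0.30,
    "brief_advice": 2.46,
    "combined": 4.46
  },
  "female_observed_prevalence": {"2007": 2.4, "2011": 2.1, "2014": 2.2}
}
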