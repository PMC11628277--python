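[
  {"factor_id": "bmi", "rr": 1.03, "ci_low": 1.00, "ci_high": 1.07},
  {"factor_id": "smoking", "rr": 1.09, "ci_low": 1.02, "ci_high": 1.17},
  {"factor_id": "disease_course", "rr": 1.71, "ci_low": 1.23, "ci_high": 2.36},
  {"factor_id": "psa", "rr": 1.13, "ci_low": 1.07, "ci_high": 1.19},
  {"factor_id": "faster_relief", "rr": 0.73, "ci_low": 0.51, "ci_high": 0.92},
  {"factor_id": "higher_relief", "rr": 0.60, "ci_low": 0.40, "ci_high": 0.91},
  {"factor_id": "prior_biologics", "rr": 1.19, "ci_low": 1.04, "ci_high": 1.37},
  {"factor_id": "treatment_course", "rr": 0.70, "ci_low": 0.64, "ci_high": 0.76}
]
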