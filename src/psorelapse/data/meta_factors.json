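{
  "significant_factors": [
    "bmi",
    "weight",
    "smoking",
    "disease_duration_years",
    "disease_course",
    "psa",
    "faster_relief",
    "higher_relief",
    "prior_biologics",
    "treatment_course"
  ],
  "collinear_groups": [
    ["bmi", "weight"],
    ["disease_course", "disease_duration_years"]
  ]
}
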