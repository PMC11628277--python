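{
  "version_tag": "canonical-v1",
  "provenance": "canonical",
  "items": [
    {"factor_id": "bmi", "stratum_label": "<24",
     "predicate": {"kind": "interval", "low": null, "high": 24.0, "low_closed": true, "high_closed": false},
     "points": 0.0},
    {"factor_id": "bmi", "stratum_label": "24 ~ 27.99",
     "predicate": {"kind": "interval", "low": 24.0, "high": 28.0, "low_closed": true, "high_closed": false},
     "points": 1.5},
    {"factor_id": "bmi", "stratum_label": ">=28",
     "predicate": {"kind": "interval", "low": 28.0, "high": null, "low_closed": true, "high_closed": false},
     "points": 3.0},
    {"factor_id": "smoking", "stratum_label": "No",
     "predicate": {"kind": "flag", "value": false}, "points": 0.0},
    {"factor_id": "smoking", "stratum_label": "Yes",
     "predicate": {"kind": "flag", "value": true}, "points": 1.0},
    {"factor_id": "disease_course", "stratum_label": "<=2",
     "predicate": {"kind": "flag", "value": false}, "points": 0.0},
    {"factor_id": "disease_course", "stratum_label": ">2",
     "predicate": {"kind": "flag", "value": true}, "points": 5.0},
    {"factor_id": "psa", "stratum_label": "No",
     "predicate": {"kind": "flag", "value": false}, "points": 0.0},
    {"factor_id": "psa", "stratum_label": "Yes",
     "predicate": {"kind": "flag", "value": true}, "points": 1.0},
    {"factor_id": "higher_relief", "stratum_label": "No",
     "predicate": {"kind": "flag", "value": false}, "points": 0.0},
    {"factor_id": "higher_relief", "stratum_label": "Yes",
     "predicate": {"kind": "flag", "value": true}, "points": 5.0},
    {"factor_id": "faster_relief", "stratum_label": "No",
     "predicate": {"kind": "flag", "value": false}, "points": 0.0},
    {"factor_id": "faster_relief", "stratum_label": "Yes",
     "predicate": {"kind": "flag", "value": true}, "points": 3.0},
    {"factor_id": "prior_biologics", "stratum_label": "No",
     "predicate": {"kind": "flag", "value": false}, "points": 0.0},
    {"factor_id": "prior_biologics", "stratum_label": "Yes",
     "predicate": {"kind": "flag", "value": true}, "points": 2.0},
    {"factor_id": "treatment_course", "stratum_label": "<=10.75",
     "predicate": {"kind": "interval", "low": null, "high": 10.75, "low_closed": true, "high_closed": true},
     "points": 3.5},
    {"factor_id": "treatment_course", "stratum_label": ">10.75",
     "predicate": {"kind": "interval", "low": 10.75, "high": null, "low_closed": false, "high_closed": false},
     "points": 0.0}
  ]
}
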