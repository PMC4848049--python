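{
  "name": "set1",
  "provenance": "epicardial right-ventricle linear lesion survey, first assessment set: 6 contact-force measurements, 5 inside the lesion pattern and 1 outside; MAPs appeared at B3 (in-pattern, 7.3 g) and D1 (outside, 8.9 g), both non-ablated myocardium; the 4 silent in-pattern sites were probed at forces exceeding the viable-tissue reference (values not printed)",
  "sites": [
    {"site_id": "B3", "in_pattern": true,  "map_present": true,  "cf_at_detection_g": 7.3,  "max_cf_g": 7.3,  "supra_reference": false},
    {"site_id": "D1", "in_pattern": false, "map_present": true,  "cf_at_detection_g": 8.9,  "max_cf_g": 8.9,  "supra_reference": false},
    {"site_id": "A4", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true},
    {"site_id": "B2", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true},
    {"site_id": "C1", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true},
    {"site_id": "C4", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true}
  ]
}
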