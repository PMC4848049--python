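{
  "name": "set2",
  "provenance": "epicardial right-ventricle survey after an additional radiofrequency application at the former gap site B3: MAP collection attempted at A1, B2, B3 and C2; B2 silent even at 8.9 g, B3 silent at a force exceeding the viable-tissue reference; A1 and C2 elicited MAPs (forces not printed; pattern membership of A1 not stated, recorded here as out-of-pattern)",
  "sites": [
    {"site_id": "A1", "in_pattern": false, "map_present": true,  "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": false},
    {"site_id": "C2", "in_pattern": false, "map_present": true,  "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": false},
    {"site_id": "B2", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": 8.9,  "supra_reference": false},
    {"site_id": "B3", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true}
  ]
}
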