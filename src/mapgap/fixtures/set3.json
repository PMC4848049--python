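{
  "name": "set3",
  "provenance": "epicardial right-ventricle survey repeated after a stabilization period, same locations as the second set, no further ablation; forces deliberately raised above the viable-tissue reference at every site: B3 silent up to 11 g, B2 silent at elevated force (value not printed), A2 and C2 outside the pattern elicited MAPs at peak forces of 11.57 g and 11.96 g",
  "sites": [
    {"site_id": "A2", "in_pattern": false, "map_present": true,  "cf_at_detection_g": 11.57, "max_cf_g": 11.57, "supra_reference": false},
    {"site_id": "C2", "in_pattern": false, "map_present": true,  "cf_at_detection_g": 11.96, "max_cf_g": 11.96, "supra_reference": false},
    {"site_id": "B3", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null,  "max_cf_g": 11.0,  "supra_reference": false},
    {"site_id": "B2", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null,  "max_cf_g": null,  "supra_reference": true}
  ]
}
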