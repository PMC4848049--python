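{
  "name": "endocardial_mi",
  "provenance": "endocardial left-atrial mitral-isthmus linear lesion survey: catheter placed at 9 relative locations within the zones of the lesion line; sites 1, 4, 5 and 6 yielded no MAPs although contact force was raised above 10 g, while the remaining 5 sites showed reproducible MAPs at forces below 10 g (per-site values not printed)",
  "sites": [
    {"site_id": "1", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true},
    {"site_id": "2", "in_pattern": false, "map_present": true,  "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": false},
    {"site_id": "3", "in_pattern": false, "map_present": true,  "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": false},
    {"site_id": "4", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true},
    {"site_id": "5", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true},
    {"site_id": "6", "in_pattern": true,  "map_present": false, "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": true},
    {"site_id": "7", "in_pattern": false, "map_present": true,  "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": false},
    {"site_id": "8", "in_pattern": false, "map_present": true,  "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": false},
    {"site_id": "9", "in_pattern": false, "map_present": true,  "cf_at_detection_g": null, "max_cf_g": null, "supra_reference": false}
  ]
}
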