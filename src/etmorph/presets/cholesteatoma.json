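{
 "name": "cholesteatoma",
 "angle_mean_deg": 27.8,
 "angle_sd_deg": 5.1,
 "length_mean_mm": 25.9,
 "length_sd_mm": 5.1,
 "age_mean_yr": 42.5,
 "age_sd_yr": 14.3,
 "female_fraction": 0.3333333333333333,
 "landmark_jitter_sd_mm": 0.0,
 "mfp_tilt_deg": 0.0,
 "provenance": "Adults with acquired cholesteatoma (middle-ear dysfunction), measured against the Ku-Copson mandibular-fossa plane on cone-beam CT temporal-bone scans; more horizontal and shorter tubes than the normal cohorts."
}
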