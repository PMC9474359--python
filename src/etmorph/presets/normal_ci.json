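{
 "name": "normal_ci",
 "angle_mean_deg": 33.0,
 "angle_sd_deg": 6.1,
 "length_mean_mm": 31.9,
 "length_sd_mm": 2.4,
 "age_mean_yr": 63.9,
 "age_sd_yr": 21.3,
 "female_fraction": 0.4666666666666667,
 "landmark_jitter_sd_mm": 0.0,
 "mfp_tilt_deg": 0.0,
 "provenance": "Cochlear-implant candidates with normal middle ears, cone-beam CT temporal-bone protocol (0.15 mm slices), measured against the Ku-Copson mandibular-fossa plane. The published summaries pair this cohort's length inconsistently (31.3 (3.7) vs 31.9 (2.4) mm in different comparisons); this preset follows the cohort-comparison pairing, 31.9 (2.4) mm."
}
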