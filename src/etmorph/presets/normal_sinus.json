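{
 "name": "normal_sinus",
 "angle_mean_deg": 34.7,
 "angle_sd_deg": 5.2,
 "length_mean_mm": 31.3,
 "length_sd_mm": 3.7,
 "age_mean_yr": 46.0,
 "age_sd_yr": 14.0,
 "female_fraction": 0.4666666666666667,
 "landmark_jitter_sd_mm": 0.0,
 "mfp_tilt_deg": -2.6703537555513243,
 "provenance": "Normal-middle-ear adults imaged with a cone-beam sinus CT protocol (0.3 mm slices); angle/length calibrated to the mandibular-fossa-plane summary of that cohort. The tilt (-1.7*pi/2 deg) makes the cohort-mean Reid's-plane angle read 1.7 deg below the fossa-plane angle (33.0 vs 34.7 deg); the pi/2 factor compensates azimuth averaging. Age SD is unreported for this cohort and set to 14 yr from the 18-71 yr range."
}
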