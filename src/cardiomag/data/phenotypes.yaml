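# Default phenotype constants for the synthetic cohort generator.
# Tuned once so the cohort-level contrasts (stress heart rate, T-wave
# amplitude, monopolarity admixture, T-peak latency spread) point in the
# directions observed for healthy controls versus CAD patients.
healthy:
  t_amplitude_scale: 1.0
  injury_current_fraction: 0.0
  t_peak_jitter_ms: 3.0
  hr_rest_bpm: 70.0
  hr_stress_bpm: 103.0
  noise_sd: 0.15
  dipole_depth_m: 0.06
  stress_t_gain: 1.10
CAD:
  t_amplitude_scale: 0.58
  injury_current_fraction: 0.38
  t_peak_jitter_ms: 7.0
  hr_rest_bpm: 70.0
  hr_stress_bpm: 85.0
  noise_sd: 0.15
  dipole_depth_m: 0.06
  stress_t_gain: 1.0
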