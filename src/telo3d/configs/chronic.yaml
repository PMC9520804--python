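# Chronic-phase CML cohort calibration.
# Counts and aggregate frequency reproduce the chronic-phase column of the
# published cohort (telomere signals 39.45 +/- 6.49, aggregates 3.37 +/- 1.19
# per nucleus); the pooled SD is split into a patient-level and a
# nucleus-level component (see docs/methods.md).
phase_label: chronic
n_patients: 18
n_nuclei_per_sample: 30
patient_telomere_sd: 0.5
patient_aggregate_sd: 0.5
patient_radius_log_sd: 0.03
nucleus_radius_log_sd: 0.06
rng_seed: 101
nucleus:
  semi_axes: [4430.0, 3740.0, 2770.0]   # nm; volume ~191.8 um^3
  n_telomeres: [39.45, 6.46]
  n_aggregates: [3.37, 1.04]
  aggregate_multiplicity: [[2, 0.3], [3, 0.5], [4, 0.2]]
  flattening: 1.595                      # cloud a/c ~ 2.55
  intensity_mixture:
    weights: [0.20, 0.55, 0.25]
    log_means: [6.9028, 7.0851, 7.3082]  # component means ~1000/1200/1500 a.u.
    log_sds: [0.10, 0.10, 0.10]
  psf_sigma: [150.0, 150.0, 300.0]
  background_level: 20.0
  noise_sd: 2.0
  cd34_positive: true
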