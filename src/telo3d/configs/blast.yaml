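# Accelerated/blast-phase CML cohort calibration.
# Telomere signals 41.51 +/- 5.25, aggregates 4.73 +/- 0.92 per nucleus;
# larger nuclei (~328.7 um^3), flatter telomere cloud (a/c ~ 6.65), brighter
# signals than the chronic phase.
phase_label: accelerated_blast
n_patients: 18
n_nuclei_per_sample: 30
patient_telomere_sd: 0.5
patient_aggregate_sd: 0.5
patient_radius_log_sd: 0.03
nucleus_radius_log_sd: 0.06
rng_seed: 202
nucleus:
  semi_axes: [5300.0, 4470.0, 3310.0]   # nm; volume ~328.4 um^3
  n_telomeres: [41.51, 5.22]
  n_aggregates: [4.73, 0.72]
  aggregate_multiplicity: [[2, 0.3], [3, 0.5], [4, 0.2]]
  flattening: 4.154                      # cloud a/c ~ 6.65
  intensity_mixture:
    weights: [0.20, 0.55, 0.25]
    log_means: [7.0851, 7.2674, 7.4905]  # component means ~1200/1440/1800 a.u.
    log_sds: [0.10, 0.10, 0.10]
  psf_sigma: [150.0, 150.0, 300.0]
  background_level: 20.0
  noise_sd: 2.0
  cd34_positive: true
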