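# Default study configuration: the reference intraoperative pacing protocol.
# Cycle lengths / SDs in ms, durations in s, rates as noted.
sim:
  n_patients: 50
  baseline_cl_median: 815.0        # cohort median sinus cycle length
  baseline_cl_iqr: [759.0, 957.0]  # cohort IQR of the baseline cycle length
  sd_succ_diff: 19.0               # baseline SD of successive PP differences
  sd_succ_diff_dispersion: 0.35    # between-patient lognormal sigma
  surge_multiplier_k: 2.7          # post-pacing vagal surge on variability
  surge_multiplier_dispersion: 0.25
  surge_cl_prolongation: 40.0      # additive CL increase at surge onset
  surge_decay_tau: 25.0            # surge decay time constant
  surge_plateau: 4.0               # full-amplitude hold before decay
  snrt_excess: 330.0               # SNRT pause beyond baseline CL
  snrt_excess_dispersion: 0.26
  snrt_protocol_jitter: 0.08
  pacing_rate: 100.0               # bpm -> paced CL 600 ms
  pacing_duration: 30.0
  inter_protocol_gap: 120.0        # second protocol starts 2 min later
  rest_duration: 60.0
  tail_duration: 60.0
  rsa_amplitude: 5.0               # respiratory sinus arrhythmia, ms
  rsa_frequency: 0.25              # Hz (~15 breaths/min)
  ectopy_rate: 0.0                 # contaminating events per minute
  artifact_rate: 0.0
  capture_failure_prob: 0.0
  wp_threshold_mean: 370.0         # AV Wenckebach threshold CL, ms
  wp_threshold_sd: 30.0
  wp_protocol_jitter: 10.0
  n_spare_epochs: 1                # spare epoch for the 2-min repeat rule
  seed: 0

include_recovery_beat: false       # SNRT pause excluded from the B/D window
alpha: 0.05
bonferroni_m: 2                    # two prespecified contrasts -> p < 0.025
csnrt_aggregator: mean
make_plots: true
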