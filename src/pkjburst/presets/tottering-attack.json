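{
  "name": "tottering-attack",
  "kind": "burst",
  "targets": {
    "mean_rate_hz": 54.0,
    "isi_cv": 1.47,
    "pfr_hz": 180.0,
    "reported_sem": {
      "rate": 9.0,
      "cv": 0.14,
      "pfr": 29.0
    },
    "note": ""
  },
  "params": {
    "kind": "burst",
    "burst": {
      "intra_burst_rate_hz": 180.62971747954575,
      "burst_shape_kb": 25.0,
      "mean_burst_size": 3.2191065772958267,
      "pause_mean_s": 0.04641609870181975,
      "pause_shape_kp": 1.8576553724135758,
      "pause_drift_cv": 0.0,
      "pause_slow_frac": 0.0,
      "pause_long_mult": 1.0,
      "t_ref_s": 0.001
    }
  },
  "achieved": [
    54.0,
    1.470015395018036,
    181.81818181818178
  ],
  "n_replicates": 12,
  "converged": true,
  "objective_value": 0.00010203051474027318,
  "provenance": {
    "generator": "analysis/01_calibrate_presets.py",
    "pkjburst_version": "0.1.0",
    "calibration_seed": 20260920,
    "objective": "simulated"
  }
}
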