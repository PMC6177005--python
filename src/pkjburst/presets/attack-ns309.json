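{
  "name": "attack-ns309",
  "kind": "tonic",
  "targets": {
    "mean_rate_hz": 45.0,
    "isi_cv": 0.74,
    "pfr_hz": 71.0,
    "reported_sem": {
      "rate": 9.0,
      "cv": 0.19,
      "pfr": 19.0
    },
    "note": ""
  },
  "params": {
    "kind": "tonic",
    "tonic": {
      "mean_rate_hz": 44.95498062880451,
      "shape_k": 10.0,
      "rate_drift_cv": 0.0,
      "slow_state_frac": 0.4207825807753069,
      "slow_rate_mult": 0.29135805207077053,
      "segment_len_s": 10.0,
      "t_ref_s": 0.001
    }
  },
  "achieved": [
    44.996944444444445,
    0.7399141397891172,
    71.09408258833547
  ],
  "n_replicates": 12,
  "converged": true,
  "objective_value": 1.7739811528150345e-06,
  "provenance": {
    "generator": "analysis/01_calibrate_presets.py",
    "pkjburst_version": "0.1.0",
    "calibration_seed": 20260920,
    "objective": "simulated"
  }
}
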