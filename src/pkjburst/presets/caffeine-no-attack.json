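{
  "name": "caffeine-no-attack",
  "kind": "tonic",
  "targets": {
    "mean_rate_hz": 52.0,
    "isi_cv": 0.78,
    "pfr_hz": 85.0,
    "reported_sem": {
      "rate": 5.0,
      "cv": 0.23,
      "pfr": 5.0
    },
    "note": "mean rate not reported; baseline rate reused"
  },
  "params": {
    "kind": "tonic",
    "tonic": {
      "mean_rate_hz": 52.001643779713454,
      "shape_k": 10.0,
      "rate_drift_cv": 0.0,
      "slow_state_frac": 0.4400168657098488,
      "slow_rate_mult": 0.2740209941216199,
      "segment_len_s": 10.0,
      "t_ref_s": 0.001
    }
  },
  "achieved": [
    51.999444444444435,
    0.780011985991291,
    85.21739130434786
  ],
  "n_replicates": 12,
  "converged": true,
  "objective_value": 6.541385461073722e-06,
  "provenance": {
    "generator": "analysis/01_calibrate_presets.py",
    "pkjburst_version": "0.1.0",
    "calibration_seed": 20260920,
    "objective": "simulated"
  }
}
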