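{
  "name": "wt-vehicle",
  "kind": "tonic",
  "targets": {
    "mean_rate_hz": 55.0,
    "isi_cv": 0.48,
    "pfr_hz": 68.0,
    "reported_sem": {
      "rate": 15.0,
      "cv": 0.09,
      "pfr": 25.0
    },
    "note": ""
  },
  "params": {
    "kind": "tonic",
    "tonic": {
      "mean_rate_hz": 54.92788237828574,
      "shape_k": 10.0,
      "rate_drift_cv": 0.0,
      "slow_state_frac": 0.19486637704079282,
      "slow_rate_mult": 0.4139970159253762,
      "segment_len_s": 10.0,
      "t_ref_s": 0.001
    }
  },
  "achieved": [
    54.71097222222222,
    0.4783917081480636,
    67.85317018909899
  ],
  "n_replicates": 12,
  "converged": true,
  "objective_value": 4.3504542007757776e-05,
  "provenance": {
    "generator": "analysis/01_calibrate_presets.py",
    "pkjburst_version": "0.1.0",
    "calibration_seed": 20260920,
    "objective": "simulated"
  }
}
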