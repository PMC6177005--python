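{
  "name": "tottering-baseline",
  "kind": "tonic",
  "targets": {
    "mean_rate_hz": 52.0,
    "isi_cv": 0.66,
    "pfr_hz": 74.0,
    "reported_sem": {
      "rate": 5.0,
      "cv": 0.06,
      "pfr": 4.0
    },
    "note": ""
  },
  "params": {
    "kind": "tonic",
    "tonic": {
      "mean_rate_hz": 52.020905217670744,
      "shape_k": 10.0,
      "rate_drift_cv": 0.0,
      "slow_state_frac": 0.32770703750376334,
      "slow_rate_mult": 0.3176483590333964,
      "segment_len_s": 10.0,
      "t_ref_s": 0.001
    }
  },
  "achieved": [
    52.000972222222224,
    0.6599874648435103,
    74.14218816517668
  ],
  "n_replicates": 12,
  "converged": true,
  "objective_value": 3.692725315530365e-06,
  "provenance": {
    "generator": "analysis/01_calibrate_presets.py",
    "pkjburst_version": "0.1.0",
    "calibration_seed": 20260920,
    "objective": "simulated"
  }
}
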