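{
  "name": "wt-cadmium",
  "kind": "burst",
  "targets": {
    "mean_rate_hz": 59.0,
    "isi_cv": 0.99,
    "pfr_hz": 142.0,
    "reported_sem": {
      "rate": 25.0,
      "cv": 0.38,
      "pfr": 85.0
    },
    "note": ""
  },
  "params": {
    "kind": "burst",
    "burst": {
      "intra_burst_rate_hz": 137.39981820683587,
      "burst_shape_kb": 25.0,
      "mean_burst_size": 2.1085043299868733,
      "pause_mean_s": 0.027160128206326257,
      "pause_shape_kp": 2.0000982514886116,
      "pause_drift_cv": 0.0,
      "pause_slow_frac": 0.0,
      "pause_long_mult": 1.0,
      "t_ref_s": 0.001
    }
  },
  "achieved": [
    58.981666666666655,
    0.9888575529793379,
    141.88034188034186
  ],
  "n_replicates": 12,
  "converged": true,
  "objective_value": 2.138322266869999e-06,
  "provenance": {
    "generator": "analysis/01_calibrate_presets.py",
    "pkjburst_version": "0.1.0",
    "calibration_seed": 20260920,
    "objective": "simulated"
  }
}
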