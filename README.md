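# pkjburst

Spike-train irregularity analysis for cerebellar Purkinje cells, built
around the question of what happens to their firing during episodic motor
attacks. In the tottering mouse (a loss-of-function Cacna1a model of
episodic ataxia type 2), caffeine-triggered attacks transform the cells'
regular pacemaking into high-frequency burst firing: the mean firing rate
barely moves, but the interspike-interval (ISI) coefficient of variation
and the predominant firing rate rise sharply, and they rise in step with
the behavioral severity of the attack.

The package provides, for that style of analysis:

- **`pkjburst.metrics`** — the three summary statistics per spike train:
  mean firing rate (spike count / recording duration), **ISI CV**
  (sd(ISI)/mean(ISI), sample standard deviation), and **PFR**, the
  predominant firing rate (reciprocal of the modal 1-ms ISI-histogram bin
  center), plus ISI histograms and cumulative distributions.
- **`pkjburst.synthetic`** — generative spike-train families: gamma-renewal
  tonic pacemaking with slow multiplicative rate drift, an alternating
  burst–pause process (geometric burst sizes, gamma intra-burst intervals
  and pauses), Poisson complex spikes with the post-complex-spike pause,
  severity-graded regime interpolation, and deterministic cohort
  generation.
- **`pkjburst.calibration`** — inversion of the statistic triplet: given a
  target (rate, CV, PFR), closed-form initialization plus Nelder–Mead
  refinement against simulated cohorts finds generator parameters that
  reproduce it. Six calibrated condition presets ship with the package
  (`tottering-baseline`, `tottering-attack`, `caffeine-no-attack`,
  `attack-ns309`, `wt-vehicle`, `wt-cadmium`).
- **`pkjburst.behavior`** — the 0–5 disability rating scale: a latent
  attack-severity time course (rise to a peak near 30 min, slow decay) and
  blinded multi-observer integer scoring.
- **`pkjburst.analysis`** — the group statistics: pooled-variance t-tests,
  one-way ANOVA with Tukey's HSD, two-way ANOVA with Sidak-adjusted
  per-bin contrasts for ISI cumulative distributions, and the
  time-binned regression of firing irregularity on disability score.
- **`pkjburst.io` / `pkjburst.cli`** — long-format spike CSV round-trips,
  flat key–value run configuration, and the `pkjburst` command-line
  pipeline (`simulate`, `metrics`, `calibrate`, `analyze`, `timecourse`).

The numbered scripts under `analysis/` run the full study on synthetic
cohorts: `01_calibrate_presets.py` (regenerates the packaged presets),
`02_simulate_cohorts.py`, `03_condition_statistics.py`,
`04_severity_experiment.py`. Each writes its tables under `results/`.

## Worked example

```python
from pkjburst import load_preset, summarize_train
from pkjburst.synthetic import generate_regime_train, insert_complex_spikes

regime = load_preset("tottering-attack").params
train = generate_regime_train(regime, 300.0, seed=1)
train = insert_complex_spikes(train, cs_rate_hz=1.0, cs_pause_s=0.015, seed=2)
s = summarize_train(train)
print(f"rate {s.mean_rate_hz:.1f} spikes/s, ISI CV {s.isi_cv:.2f}, "
      f"PFR {s.pfr_hz:.0f} spikes/s")
```

prints

```
rate 54.3 spikes/s, ISI CV 1.48, PFR 182 spikes/s
```

— a burst-firing cell: its mean rate is indistinguishable from a baseline
pacemaker (~52 spikes/s), but the ISI CV (1.48 vs ~0.66) and PFR
(182 vs ~74 spikes/s) expose the high-frequency bursts separated by long
pauses. The same comparison from the shell:

```sh
pkjburst simulate --preset tottering-attack --n-cells 14 --duration 300 \
    --seed 1 -o attack/
pkjburst metrics -i attack/spikes.csv -o attack_summaries.csv
```

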