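# Methods

## The statistics

Every spike train is reduced to a triplet:

- **mean firing rate** = simple-spike count / recording duration
  (spikes/s). Complex spikes are excluded from the count by default: the
  recordings this emulates mark complex spikes separately, and they are
  an order of magnitude rarer than simple spikes.
- **ISI CV** = sd(ISI) / mean(ISI), with the sample (n−1) standard
  deviation. The (n−1) convention is irrelevant at the n ≥ 100 intervals
  we require (`min_isis`, default 100; shorter records raise an error
  rather than return a noisy value) but is fixed for reproducibility.
  Intervals with a complex spike strictly inside them are dropped
  (default `exclude_complex=True`), so the post-complex-spike pause does
  not contaminate the simple-spike statistics.
- **PFR (predominant firing rate)** = 1 / (modal ISI-histogram bin
  center). Histogram: 1-ms left-closed bins on [0, 1 s), intervals ≥ 1 s
  counted as overflow; ties broken toward the shortest-ISI bin. The 1-ms
  width resolves a 180 spikes/s mode (5.6 ms) while keeping a ~13 ms
  baseline mode stable; the tie rule is deterministic and biased toward
  detecting bursting, matching the PFR's role as a burst index.

A CV near 0 is a perfect clock, near 1 a Poisson process; burst–pause
firing pushes it above 1 while the mean rate can stay unchanged. The PFR
is the complementary index: intra-burst intervals dominate the histogram
mode, so bursting inflates the PFR even when bursts are sparse.

## Tonic generative family

Gamma renewal with multiplicative rate drift. Time is divided into
segments (`segment_len_s`, default 10 s — slow relative to the ~20 ms
ISI, fast relative to a 300 s recording). Segment rate = `mean_rate_hz` ×
S × L, where L is unit-mean lognormal with coefficient of variation
`rate_drift_cv` and S is a unit-mean two-state modulation: with
probability `slow_state_frac` (q) the segment fires at `slow_rate_mult`
(z) times the active rate. Within a segment, ISIs are gamma with shape
`shape_k`; every sampled interval is floored at the absolute refractory
period `t_ref_s` (default 1 ms, a physiological floor). The interval in
progress at a segment boundary keeps the rate it was drawn under, so the
process remains a proper renewal process.

Because an interval sampled at random falls in a segment with probability
proportional to that segment's rate, the marginal ISI is distributed as
gamma(k, mean 1/rate) × M with M the rate-tilted reciprocal multiplier,
and

CV² = (1 + 1/k) · E[S]E[1/S] · (1 + c²) − 1,

which reduces to the familiar 1/k + c²(1 + 1/k) when q = 0. The predicted
ISI mode (hence PFR) is computed as the numeric argmax of this mixture
density (two-state values × Gauss–Hermite nodes over the lognormal).

The two-state component is what decouples the CV from the mode. With
lognormal-only drift the mode scales as ≈ (1 + c²)^(−3/2) of the mean
interval — almost exactly canceling the CV inflation — so that family
alone is pinned to PFR/rate ratios ≥ ~1.7 at CV 0.66, whereas awake
baseline recordings combine a low ratio (~1.4) with that CV. Minority
slow segments supply the missing degree of freedom: they add a
long-interval tail (E[1/S] grows, CV rises) while the histogram mode
stays at the active-state rate. For the calibrated baseline this lands at
roughly a third of segments at a third of the active rate — epochs of
slowed, irregular firing superimposed on ~70 Hz pacemaking.

## Burst–pause generative family

Alternating renewal: a pause, then a burst, repeated. Burst spike counts
are geometric on {1, 2, ...} with mean `mean_burst_size` (μ); intra-burst
ISIs are gamma (shape `burst_shape_kb`, mean 1/`intra_burst_rate_hz`);
pauses are gamma (shape `pause_shape_kp`, mean `pause_mean_s`) times an
optional unit-mean modulation (lognormal `pause_drift_cv` × two-point
`pause_slow_frac`/`pause_long_mult`) mirroring the tonic drift. A burst
of n spikes emits n−1 intra-burst intervals and one pause, so the ISI
marginal is a two-component mixture with intra weight w = (μ−1)/μ; its
mean, variance and density (hence all three predicted statistics) are in
closed form. At μ = 1 the family degenerates to a pause-only renewal
process, and with matched shape and modulation that process reproduces
the tonic family's ISI marginal exactly — the identity that anchors the
severity interpolation.

## Severity interpolation

`interpolate_regime(baseline, attack, f)` returns a burst regime whose
predicted mean rate and ISI CV lie on the straight lines between the
endpoint predictions; mean burst size interpolates linearly and the
intra-burst rate geometrically (both monotone in f); the pause mean is
solved from the rate constraint and the pause modulation from the CV
constraint. At f = 0 the result is statistically identical to the tonic
baseline; at f = 1 it is the attack regime exactly. Linearity of CV in f
is by construction, which is what makes the binned CV-versus-disability
regression near-perfectly linear.

## Complex spikes

Complex spikes are a homogeneous Poisson overlay (default 1 Hz) and every
simple spike within (t_cs, t_cs + 15 ms] is deleted. The source
recordings state that the pause exists but give neither its duration nor
the complex-spike rate; 1 Hz and 15 ms are conventional values for awake
Purkinje cells and are configurable. Calibration simulates with the
overlay enabled and the default metric options, so the packaged presets
absorb the thinning (~1.5% of simple spikes) and the exclusion of
complex-spanning intervals.

## Calibration

`calibrate_regime(targets, kind)` inverts a (rate, CV, PFR) triplet:

1. **Closed-form initialization.** Tonic: first the lognormal branch
   (solve c from the CV identity per k, root-find k on the numeric-mode
   PFR equation); if the target ratio lies below that branch's floor, the
   two-state branch (shape fixed at `tonic_shape_k` = 10, solve q and z
   linearly from E[S] and E[1/S]). Burst: intra rate from the PFR, then a
   1-D root in μ at fixed shapes. Infeasible targets (e.g. CV below the
   gamma floor implied by the PFR/rate ratio) raise an error naming the
   binding constraint.
2. **Nelder–Mead refinement** of the sum of squared relative errors over
   the triplet, with the PFR measured by the package's own binned
   estimator on simulated trains (12 replicates × 600 s, complex spikes
   included) under common random numbers — the same per-replicate seeds
   at every iteration, making the objective smooth and the whole
   procedure bit-reproducible. Free parameters: (rate, k, c) or
   (rate, q, z) for tonic; (intra rate, μ, pause mean, pause shape) for
   burst. Because the binned-PFR term is a staircase in the parameters
   (bin centers quantize the attainable values), the refinement uses a
   small deterministic multi-start (±0.15 in each transformed coordinate)
   and keeps the best optimum.

A preset is `converged` when all three achieved statistics are within 2%
relative (the default `StatTargets` tolerance). All six packaged presets
converge; `analysis/01_calibrate_presets.py` regenerates them.

## Behavioral model

Latent severity: baseline 1.57 for t ≤ 0, linear rise to 4.5 at 30 min,
then exponential decay with 35 min half-life (floor at baseline; at the
nominal 150 min endpoint the excess is under 10% of the rise). A
lognormal-pulse shape is available as an alternative. Observers report
round(latent + ε) clipped to [0, 5], ε ~ N(0, `sigma_obs`); the default
σ = 0.3 reproduces the few-tenths inter-observer s.e.m. typical of 3–4
blinded raters, and with σ = 0 the pipeline is deterministic. The default
video schedule samples every 10 min from −10 to +100 min.

## Group statistics and regression

Two-condition comparisons use the pooled-variance (Student's) t-test —
deliberately not Welch, following the analysis convention being
reproduced. Three conditions: one-way ANOVA with Tukey's HSD
(scipy's studentized-range implementation; cross-checked in the tests
against statsmodels). ISI cumulative distributions: balanced two-factor
fixed-effects ANOVA with per-bin condition contrasts on the residual mean
square, Sidak-adjusted (p_adj = 1 − (1−p)^m, m = number of grid points);
unbalanced designs are an explicit error rather than a silent type-III
fit. s.e.m. is always sd/√n with n = cells for electrophysiology and
n = mice for behavior.

The severity regression bins cells and scores into common 10-min bins
**centered on the video-schedule sampling times** (bin b covers
[10b−5, 10b+5) min), pairing the score taken at 10b min with the cells
recorded around that time, then fits ordinary least squares on the bin
means. Binning is essential: per-cell triplets are noisy, and the
near-perfect published linearity (R² ≈ 0.99) is a property of bin means.
Left-edge binning would lag scores half a bin behind the cells and costs
~0.1 of R² on the rising phase.

## Synthetic cohorts: what they do and do not emulate

A cohort draws every cell of a condition from one calibrated regime;
cells differ only by seed (per-cell substream: SeedSequence of
(master_seed, crc32(cell_id)), platform-stable). Consequences:

- Cohort means recover the condition's statistics tightly (the
  acceptance gate compares them against the reported means at one reported
  s.e.m.), and the graded experiment reproduces the published regression
  quality.
- Between-cell variance is far smaller than in real cohorts, where cells
  differ in intrinsic rate. Group tests on synthetic cohorts therefore
  overstate significance: in particular, the ~2 spikes/s baseline–attack
  rate difference tests significant here although the real comparison
  does not, because real between-cell scatter (s.e.m. 5–9 spikes/s)
  swamps it. Passing tests validate the pipeline's estimators and the
  calibrated means, not field-realistic p-values for the rate contrast.
- The default graded design spreads 20 cells uniformly over 0–50 min
  after injection (window midpoints at recording-window centers); the
  recording-window assignment in the original experiments is not
  reported beyond "specific time points".

## Numerical choices and degenerate inputs

- Histogram bins are left-closed; the modal-bin tie goes to the shortest
  interval; PFR of an all-empty histogram is an error.
- The analytic ISI-mode search evaluates the mixture density on a 0.05 ms
  grid and refines the argmax by bounded scalar minimization, so
  predicted PFR is continuous in the parameters (a grid-only argmax makes
  the calibration objective piecewise constant and stalls the simplex).
- Trains too short for 2 spikes, ISIs below the refractory floor,
  non-positive durations, empty designs, out-of-range severity fractions
  and malformed configs all raise typed errors (`pkjburst.errors`).
- Problem sizes: invariant tests use ~10⁵ intervals (2% tolerance on
  closed-form CVs, 3% on mixture moments); acceptance cohorts use the
  published cell counts at 300 s per cell; the regression check runs ten
  seeds of the 20-cell graded experiment. These sizes put sampling error
  well inside every stated tolerance.

## Known limitations

- No membrane-potential or channel-level modeling; interventions are
  firing-regime switches only, with no pharmacokinetics.
- No burst-detection algorithm: burstiness is quantified only through CV
  and PFR, as in the analysis being reproduced.
- The no-attack condition's mean rate is not reported in the source; its
  preset reuses the baseline rate and carries a note in its metadata.
- Complex-spike rate and pause duration are conventional defaults, not
  measured values.
- PFR along the severity path is not controlled (the histogram mode jumps
  from the pause peak to the intra-burst peak partway); its regression R²
  is therefore slightly below the ISI CV's.
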