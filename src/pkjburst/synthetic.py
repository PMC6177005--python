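"""Synthetic Purkinje-cell spike trains.

Two generative families cover the firing regimes seen in awake recordings:

* **Tonic pacemaking** — a gamma renewal process (shape ``shape_k``) whose
  rate drifts slowly and multiplicatively between segments.  The drift
  multiplier is the product of a unit-mean lognormal (coefficient of
  variation ``rate_drift_cv``) and an optional unit-mean two-state
  active/slow modulation (``slow_state_frac`` of segments fire at
  ``slow_rate_mult`` times the active rate).  The lognormal part models
  smooth nonstationarity of awake recordings; the two-state part models
  epochs of slowed firing and is what lets the family decouple the ISI
  CV from the histogram mode: slow minority segments contribute a
  long-interval tail (inflating CV via E[1/S]) while the mode stays
  pinned near the active rate.
* **Burst–pause firing** — an alternating renewal process: bursts whose
  spike count is geometric with mean ``mean_burst_size``, gamma-distributed
  intra-burst intervals with mean ``1/intra_burst_rate_hz``, and
  gamma-distributed pauses with mean ``pause_mean_s`` (optionally with the
  same multiplicative lognormal drift, used by the severity interpolation).

Every emitted interspike interval is floored at an absolute refractory
period ``t_ref_s``.  All generators are deterministic given their seed.

The analytic first/second moments and the ISI density of both families are
implemented on the parameter classes (``predicted_stats``); the calibration
module uses them as closed-form oracles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTrainError, ParameterError

__all__ = [
    "SpikeTrain",
    "TonicParams",
    "BurstParams",
    "RegimeParams",
    "GradedRegime",
    "CohortDesign",
    "CohortDataset",
    "generate_tonic_train",
    "generate_burst_train",
    "insert_complex_spikes",
    "interpolate_regime",
    "generate_cohort",
    "cell_seed_sequence",
]

DEFAULT_T_REF_S = 0.001  # physiological absolute refractory floor
DEFAULT_CS_RATE_HZ = 1.0  # climbing-fiber complex-spike rate
DEFAULT_CS_PAUSE_S = 0.015  # post-complex-spike simple-spike pause

_GH_NODES = 21  # Gauss-Hermite order for lognormal-drift mixtures


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """One cell's sorted spike times with simple/complex labels.

    Times are in seconds on the recording clock.  ``t_injection_s``, when
    set, is the drug-injection time on the same clock and lets downstream
    analyses express recording times relative to the injection.
    """

    cell_id: str
    mouse_id: str
    condition: str
    t_start_s: float
    duration_s: float
    simple_spikes: np.ndarray
    complex_spikes: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_injection_s: float | None = None

    def __post_init__(self) -> None:
        ss = np.asarray(self.simple_spikes, dtype=float)
        cs = np.asarray(self.complex_spikes, dtype=float)
        object.__setattr__(self, "simple_spikes", ss)
        object.__setattr__(self, "complex_spikes", cs)
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        lo, hi = self.t_start_s, self.t_start_s + self.duration_s
        for name, ev in (("simple_spikes", ss), ("complex_spikes", cs)):
            if ev.size and (ev[0] < lo - 1e-9 or ev[-1] > hi + 1e-9):
                raise ParameterError(f"{name} outside [t_start, t_start+duration]")
            if ev.size > 1 and np.any(np.diff(ev) <= 0):
                raise ParameterError(f"{name} must be strictly increasing")
        if ss.size and cs.size and np.intersect1d(ss, cs).size:
            raise ParameterError("complex spike coincides with a simple spike")

    @property
    def n_simple(self) -> int:
        return int(self.simple_spikes.size)

    def shifted(self, dt_s: float) -> "SpikeTrain":
        """Translate the recording clock by ``dt_s`` (statistics-preserving)."""
        return replace(
            self,
            t_start_s=self.t_start_s + dt_s,
            simple_spikes=self.simple_spikes + dt_s,
            complex_spikes=self.complex_spikes + dt_s,
            t_injection_s=None
            if self.t_injection_s is None
            else self.t_injection_s + dt_s,
        )


def _drift_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _drift_nodes(cv: float, n: int = _GH_NODES) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for a unit-mean lognormal multiplier."""
    if cv <= 0:
        return np.ones(1), np.ones(1)
    sigma = _drift_sigma(cv)
    x, w = np.polynomial.hermite_e.hermegauss(n)
    nodes = np.exp(-0.5 * sigma * sigma + sigma * x)
    weights = w / w.sum()
    return nodes, weights


def _mixture_mode(
    component_pdf, mean_isi_s: float, drift_cv: float, kind_hint_s: float
) -> float:
    """Argmax of a drift-smeared ISI density, by dense-grid evaluation.

    ``component_pdf(t)`` is the density at drift multiplier 1; the drifted
    density is averaged over lognormal multipliers by quadrature.  The grid
    spans well past the mean ISI at 0.05 ms resolution.
    """
    nodes, weights = _drift_nodes(drift_cv)

    def dens(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for z, w in zip(nodes, weights):
            out += w * component_pdf(t / z) / z
        return out

    upper = max(5.0 * mean_isi_s, 4.0 * kind_hint_s, 0.01)
    grid = np.arange(5e-5, upper, 5e-5)
    i = int(np.argmax(dens(grid)))
    return _refine_argmax(dens, grid, i)


def _refine_argmax(dens, grid: np.ndarray, i: int) -> float:
    """Continuous refinement of a density argmax around grid point ``i``."""
    from scipy.optimize import minimize_scalar

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(
        lambda t: -float(dens(np.array([t]))[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


@dataclass(frozen=True)
class TonicParams:
    """Gamma-renewal pacemaking with slow multiplicative rate drift.

    ``slow_state_frac`` (q) and ``slow_rate_mult`` (z) define the two-state
    modulation: a fraction q of drift segments fire at z times the active
    rate.  The two-state multiplier is normalized to unit mean, so
    ``mean_rate_hz`` is always the time-averaged firing rate.  Defaults
    q = 0, z = 1 recover the plain gamma-renewal-with-lognormal-drift
    family.
    """

    mean_rate_hz: float
    shape_k: float
    rate_drift_cv: float = 0.0
    slow_state_frac: float = 0.0
    slow_rate_mult: float = 1.0
    segment_len_s: float = 10.0
    t_ref_s: float = DEFAULT_T_REF_S

    def __post_init__(self) -> None:
        if not self.mean_rate_hz > 0:
            raise ParameterError("mean_rate_hz must be > 0")
        if not (self.shape_k > 1 and np.isfinite(self.shape_k)):
            raise ParameterError("shape_k must be finite and > 1")
        if not 0 <= self.rate_drift_cv < 1:
            raise ParameterError("rate_drift_cv must lie in [0, 1)")
        if not 0 <= self.slow_state_frac < 1:
            raise ParameterError("slow_state_frac must lie in [0, 1)")
        if not 0 < self.slow_rate_mult <= 1:
            raise ParameterError("slow_rate_mult must lie in (0, 1]")
        if not self.segment_len_s > 0:
            raise ParameterError("segment_len_s must be > 0")
        if not 0 <= self.t_ref_s < 1.0 / self.mean_rate_hz:
            raise ParameterError("t_ref_s must lie in [0, 1/mean_rate_hz)")

    def state_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-mean two-state rate multipliers and their probabilities."""
        q, z = self.slow_state_frac, self.slow_rate_mult
        if q == 0 or z == 1:
            return np.ones(1), np.ones(1)
        a = 1.0 / (1.0 - q + q * z)  # active multiplier, > 1
        return np.array([a, z * a]), np.array([1.0 - q, q])

    def isi_scale_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """ISI-scale multiplier mixture (count-weighted, unit mean).

        An interval sampled at random falls in a segment with probability
        proportional to the segment rate, so the ISI-side multiplier is the
        rate-tilted reciprocal of the rate multiplier; for the lognormal
        part the tilt turns the unit-mean rate multiplier into a unit-mean
        ISI multiplier with the same log-sd.
        """
        s_vals, s_probs = self.state_values()
        ln_nodes, ln_w = _drift_nodes(self.rate_drift_cv)
        vals = (1.0 / s_vals)[:, None] * ln_nodes[None, :]
        wts = (s_probs * s_vals)[:, None] * ln_w[None, :]
        return vals.ravel(), wts.ravel()

    def predicted_stats(self) -> tuple[float, float, float]:
        """(mean rate, ISI CV, predominant firing rate), analytic.

        The drift multiplier has unit mean, so the time-averaged rate is
        exactly ``mean_rate_hz``.  Count-weighting the per-segment gamma
        ISIs by segment rate gives CV^2 = (1 + 1/k) E[S] E[1/S] (1 + c^2)
        - 1, which reduces to 1/k + c^2 (1 + 1/k) without the two-state
        part.  The mode is the numeric argmax of the ISI mixture density.
        """
        k, c, r = self.shape_k, self.rate_drift_cv, self.mean_rate_hz
        s_vals, s_probs = self.state_values()
        e_inv_s = float(np.sum(s_probs / s_vals))  # E[S]=1 by construction
        cv = float(np.sqrt((1.0 + 1.0 / k) * e_inv_s * (1.0 + c * c) - 1.0))
        scale = 1.0 / (k * r)
        nodes, weights = self.isi_scale_nodes()
        gam = sps.gamma(k, scale=scale)

        def dens(t):
            t = np.asarray(t, dtype=float)
            out = np.zeros_like(t)
            for z, w in zip(nodes, weights):
                out += w * gam.pdf(t / z) / z
            return out

        upper = max(5.0 / r, 4.0 * (k - 1.0) * scale, 0.01)
        grid = np.arange(5e-5, upper, 5e-5)
        i = int(np.argmax(dens(grid)))
        mode = _refine_argmax(dens, grid, i)
        return r, cv, 1.0 / mode


@dataclass(frozen=True)
class BurstParams:
    """Alternating burst-pause renewal process.

    Pauses may carry a multiplicative unit-mean modulation mirroring the
    tonic family's drift: a lognormal factor (``pause_drift_cv``) times a
    two-point factor that takes the value ``pause_long_mult`` (> 1) with
    probability ``pause_slow_frac``.  With ``mean_burst_size == 1`` and
    matched shape/modulation the process reproduces the tonic family's ISI
    marginal exactly, which anchors the severity interpolation at zero
    severity.
    """

    intra_burst_rate_hz: float
    burst_shape_kb: float
    mean_burst_size: float
    pause_mean_s: float
    pause_shape_kp: float
    pause_drift_cv: float = 0.0
    pause_slow_frac: float = 0.0
    pause_long_mult: float = 1.0
    t_ref_s: float = DEFAULT_T_REF_S

    def __post_init__(self) -> None:
        if not self.intra_burst_rate_hz > 0:
            raise ParameterError("intra_burst_rate_hz must be > 0")
        if not self.burst_shape_kb >= 1:
            raise ParameterError("burst_shape_kb must be >= 1")
        if not self.mean_burst_size >= 1:
            raise ParameterError("mean_burst_size must be >= 1")
        if not self.pause_shape_kp >= 1:
            raise ParameterError("pause_shape_kp must be >= 1")
        if not 0 <= self.pause_drift_cv < 1:
            raise ParameterError("pause_drift_cv must lie in [0, 1)")
        if not 0 <= self.pause_slow_frac < 1:
            raise ParameterError("pause_slow_frac must lie in [0, 1)")
        if not self.pause_long_mult >= 1:
            raise ParameterError("pause_long_mult must be >= 1")
        if self.pause_slow_frac * self.pause_long_mult >= 1:
            raise ParameterError(
                "pause_slow_frac * pause_long_mult must be < 1 (unit-mean)"
            )
        if not self.t_ref_s >= 0:
            raise ParameterError("t_ref_s must be >= 0")
        if not 1.0 / self.intra_burst_rate_hz > self.t_ref_s:
            raise ParameterError("1/intra_burst_rate_hz must exceed t_ref_s")
        if not self.pause_mean_s > 1.0 / self.intra_burst_rate_hz:
            raise ParameterError("pause_mean_s must exceed the intra-burst ISI")

    def pause_mult_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Two-point pause multipliers (unit mean) and their probabilities."""
        xi, long = self.pause_slow_frac, self.pause_long_mult
        if xi == 0 or long == 1:
            return np.ones(1), np.ones(1)
        short = (1.0 - xi * long) / (1.0 - xi)
        return np.array([short, long]), np.array([1.0 - xi, xi])

    def pause_mult_e2(self) -> float:
        """Second moment of the full (two-point x lognormal) pause multiplier."""
        vals, probs = self.pause_mult_values()
        return float(np.sum(probs * vals * vals) * (1.0 + self.pause_drift_cv**2))

    def mixture_moments(self) -> tuple[float, float]:
        """Exact (mean, variance) of the emitted ISI mixture.

        Each burst of n spikes emits n-1 intra-burst ISIs and one pause, so
        the intra component has weight w = (E[n]-1)/E[n].
        """
        mu = self.mean_burst_size
        w = (mu - 1.0) / mu
        m_b = 1.0 / self.intra_burst_rate_hz
        m_p = self.pause_mean_s
        e2_b = (1.0 + 1.0 / self.burst_shape_kb) * m_b * m_b
        e2_p = (1.0 + 1.0 / self.pause_shape_kp) * self.pause_mult_e2() * m_p * m_p
        mean = w * m_b + (1.0 - w) * m_p
        var = w * e2_b + (1.0 - w) * e2_p - mean * mean
        return float(mean), float(var)

    def pause_scale_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        vals, probs = self.pause_mult_values()
        ln_nodes, ln_w = _drift_nodes(self.pause_drift_cv)
        return (
            (vals[:, None] * ln_nodes[None, :]).ravel(),
            (probs[:, None] * ln_w[None, :]).ravel(),
        )

    def predicted_stats(self) -> tuple[float, float, float]:
        """(mean rate, ISI CV, predominant firing rate), analytic."""
        mean, var = self.mixture_moments()
        rate = 1.0 / mean
        cv = float(np.sqrt(var)) / mean
        mu = self.mean_burst_size
        w = (mu - 1.0) / mu
        kb, kp = self.burst_shape_kb, self.pause_shape_kp
        intra = sps.gamma(kb, scale=1.0 / (kb * self.intra_burst_rate_hz))
        pause = sps.gamma(kp, scale=self.pause_mean_s / kp)
        nodes, weights = self.pause_scale_nodes()

        def pdf(t):
            t = np.asarray(t, dtype=float)
            p = np.zeros_like(t)
            for z, wt in zip(nodes, weights):
                p += wt * pause.pdf(t / z) / z
            return w * intra.pdf(t) + (1.0 - w) * p

        upper_hint = (kp - 1.0) / kp * self.pause_mean_s if kp > 1 else mean
        grid_upper = max(5.0 * mean, 4.0 * upper_hint, 0.01)
        grid = np.arange(5e-5, grid_upper, 5e-5)
        i = int(np.argmax(pdf(grid)))
        mode = _refine_argmax(pdf, grid, i)
        return rate, cv, 1.0 / mode


@dataclass(frozen=True)
class RegimeParams:
    """Tagged union over the two generative families."""

    kind: Literal["tonic", "burst"]
    tonic: TonicParams | None = None
    burst: BurstParams | None = None

    def __post_init__(self) -> None:
        if self.kind == "tonic":
            if self.tonic is None or self.burst is not None:
                raise ParameterError("kind='tonic' requires exactly the tonic field")
        elif self.kind == "burst":
            if self.burst is None or self.tonic is not None:
                raise ParameterError("kind='burst' requires exactly the burst field")
        else:
            raise ParameterError("kind must be 'tonic' or 'burst'")

    @property
    def params(self) -> TonicParams | BurstParams:
        return self.tonic if self.kind == "tonic" else self.burst  # type: ignore[return-value]

    def predicted_stats(self) -> tuple[float, float, float]:
        return self.params.predicted_stats()


def tonic_regime(params: TonicParams) -> RegimeParams:
    return RegimeParams(kind="tonic", tonic=params)


def burst_regime(params: BurstParams) -> RegimeParams:
    return RegimeParams(kind="burst", burst=params)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_tonic_train(
    params: TonicParams,
    duration_s: float,
    seed,
    *,
    cell_id: str = "cell",
    mouse_id: str = "mouse",
    condition: str = "tonic",
    t_start_s: float = 0.0,
    t_injection_s: float | None = None,
) -> SpikeTrain:
    """Simulate one tonic-pacemaking train of ``duration_s`` seconds.

    Within each drift segment the interspike intervals are gamma renewal
    with shape ``shape_k`` and mean ``1/r_seg``; the interval in progress
    when a segment boundary passes keeps the rate it was drawn under, so
    the process remains a proper renewal process.
    """
    if duration_s < 1:
        raise ParameterError("duration_s must be >= 1")
    rng = _as_rng(seed)
    k, t_ref = params.shape_k, params.t_ref_s
    seg_len = params.segment_len_s
    n_seg = int(np.ceil(duration_s / seg_len))
    if params.rate_drift_cv > 0:
        sigma = _drift_sigma(params.rate_drift_cv)
        mult = rng.lognormal(-0.5 * sigma * sigma, sigma, n_seg)
    else:
        mult = np.ones(n_seg)
    s_vals, s_probs = params.state_values()
    if s_vals.size > 1:
        mult = mult * rng.choice(s_vals, size=n_seg, p=s_probs)
    rates = params.mean_rate_hz * mult

    chunks: list[np.ndarray] = []
    t = 0.0
    for i in range(n_seg):
        seg_end = min((i + 1) * seg_len, duration_s)
        r = rates[i]
        while t < seg_end:
            m = max(int((seg_end - t) * r * 1.3) + 10, 16)
            isis = np.maximum(rng.gamma(k, 1.0 / (k * r), m), t_ref)
            ts = t + np.cumsum(isis)
            j = int(np.searchsorted(ts, seg_end, side="right"))
            if j < ts.size:
                # keep the boundary-crossing spike (drawn under this rate)
                chunks.append(ts[: j + 1])
                t = float(ts[j])
                break
            chunks.append(ts)
            t = float(ts[-1])
    times = np.concatenate(chunks) if chunks else np.empty(0)
    times = times[times <= duration_s]
    if times.size < 2:
        raise DegenerateTrainError("duration too short to hold >= 2 spikes")
    return SpikeTrain(
        cell_id=cell_id,
        mouse_id=mouse_id,
        condition=condition,
        t_start_s=t_start_s,
        duration_s=float(duration_s),
        simple_spikes=times + t_start_s,
        t_injection_s=t_injection_s,
    )


def generate_burst_train(
    params: BurstParams,
    duration_s: float,
    seed,
    *,
    cell_id: str = "cell",
    mouse_id: str = "mouse",
    condition: str = "burst",
    t_start_s: float = 0.0,
    t_injection_s: float | None = None,
) -> SpikeTrain:
    """Simulate one burst-pause train: pause, burst, pause, burst, ..."""
    if duration_s < 1:
        raise ParameterError("duration_s must be >= 1")
    rng = _as_rng(seed)
    mu = params.mean_burst_size
    mean_isi, _ = params.mixture_moments()
    cycle_mean = mu * mean_isi  # n ISIs per cycle on average

    times: list[np.ndarray] = []
    t = 0.0
    while t < duration_s:
        n_cycles = max(int((duration_s - t) / cycle_mean) + 8, 16)
        sizes = (
            rng.geometric(1.0 / mu, n_cycles)
            if mu > 1
            else np.ones(n_cycles, dtype=np.int64)
        )
        pauses = rng.gamma(
            params.pause_shape_kp,
            params.pause_mean_s / params.pause_shape_kp,
            n_cycles,
        )
        if params.pause_drift_cv > 0:
            sigma = _drift_sigma(params.pause_drift_cv)
            pauses = pauses * rng.lognormal(-0.5 * sigma * sigma, sigma, n_cycles)
        m_vals, m_probs = params.pause_mult_values()
        if m_vals.size > 1:
            pauses = pauses * rng.choice(m_vals, size=n_cycles, p=m_probs)
        pauses = np.maximum(pauses, params.t_ref_s)
        n_intra = int(np.sum(sizes - 1))
        intra = np.maximum(
            rng.gamma(
                params.burst_shape_kb,
                1.0 / (params.burst_shape_kb * params.intra_burst_rate_hz),
                n_intra,
            ),
            params.t_ref_s,
        )
        # interleave: each cycle contributes [pause, isi_1 .. isi_{n-1}]
        starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        stream = np.empty(int(np.sum(sizes)))
        stream[starts] = pauses
        mask = np.ones(stream.size, dtype=bool)
        mask[starts] = False
        stream[mask] = intra
        ts = t + np.cumsum(stream)
        times.append(ts)
        t = float(ts[-1])
    all_times = np.concatenate(times)
    all_times = all_times[all_times <= duration_s]
    if all_times.size < 2:
        raise DegenerateTrainError("duration too short to hold >= 2 spikes")
    return SpikeTrain(
        cell_id=cell_id,
        mouse_id=mouse_id,
        condition=condition,
        t_start_s=t_start_s,
        duration_s=float(duration_s),
        simple_spikes=all_times + t_start_s,
        t_injection_s=t_injection_s,
    )


def generate_regime_train(params: RegimeParams, duration_s: float, seed, **meta) -> SpikeTrain:
    """Dispatch on regime kind."""
    if params.kind == "tonic":
        return generate_tonic_train(params.tonic, duration_s, seed, **meta)
    return generate_burst_train(params.burst, duration_s, seed, **meta)


def insert_complex_spikes(
    train: SpikeTrain,
    cs_rate_hz: float,
    cs_pause_s: float,
    seed,
) -> SpikeTrain:
    """Overlay Poisson complex spikes and impose the post-complex-spike pause.

    Complex-spike times are homogeneous Poisson at ``cs_rate_hz``; every
    simple spike in ``(t_cs, t_cs + cs_pause_s]`` is deleted, emulating the
    brief cessation of simple-spike firing after each climbing-fiber event.
    """
    if cs_rate_hz < 0 or cs_pause_s < 0:
        raise ParameterError("cs_rate_hz and cs_pause_s must be >= 0")
    if cs_rate_hz == 0:
        return train
    rng = _as_rng(seed)
    n_cs = rng.poisson(cs_rate_hz * train.duration_s)
    cs = np.sort(
        rng.uniform(train.t_start_s, train.t_start_s + train.duration_s, n_cs)
    )
    cs = np.unique(cs)
    # a.s. no exact coincidence with a simple spike; nudge if it ever happens
    while np.intersect1d(cs, train.simple_spikes).size:
        hit = np.isin(cs, train.simple_spikes)
        cs[hit] += 1e-9
        cs = np.unique(cs)
    ss = train.simple_spikes
    keep = np.ones(ss.size, dtype=bool)
    lo = np.searchsorted(ss, cs, side="right")
    hi = np.searchsorted(ss, cs + cs_pause_s, side="right")
    delta = np.zeros(ss.size + 1, dtype=int)
    np.add.at(delta, lo, 1)
    np.add.at(delta, hi, -1)
    keep &= np.cumsum(delta[:-1]) == 0
    return replace(train, simple_spikes=ss[keep], complex_spikes=cs)


# ---------------------------------------------------------------------------
# severity interpolation
# ---------------------------------------------------------------------------


def interpolate_regime(
    baseline: RegimeParams, attack: RegimeParams, severity_frac: float
) -> RegimeParams:
    """Burst regime on a severity path from tonic baseline to full attack.

    The path holds the predicted mean rate on the straight line between the
    endpoint rates and the predicted ISI CV on the straight line between the
    endpoint CVs.  Mean burst size and intra-burst rate increase
    monotonically with severity.  At ``severity_frac == 0`` the regime is a
    pause-only process whose ISI marginal equals the tonic baseline's
    (gamma x lognormal product identity); at 1 it is the attack regime
    exactly.
    """
    if not 0.0 <= severity_frac <= 1.0:
        raise ParameterError("severity_frac must lie in [0, 1]")
    if baseline.kind != "tonic" or attack.kind != "burst":
        raise ParameterError("baseline must be tonic and attack must be burst")
    if severity_frac == 1.0:
        return attack
    tb = baseline.tonic
    ab = attack.burst
    f = float(severity_frac)
    rate_b, cv_b, pfr_b = tb.predicted_stats()
    rate_a, cv_a, _ = ab.predicted_stats()

    rate = (1 - f) * rate_b + f * rate_a
    cv_target = (1 - f) * cv_b + f * cv_a
    mu = 1.0 + f * (ab.mean_burst_size - 1.0)
    r_b = float(np.exp((1 - f) * np.log(pfr_b) + f * np.log(ab.intra_burst_rate_hz)))
    k_p = float(np.exp((1 - f) * np.log(tb.shape_k) + f * np.log(ab.pause_shape_kp)))
    k_b = ab.burst_shape_kb

    # pause modulation: at f=0, the rate-tilted reciprocal of the tonic
    # two-state multiplier (so pauses reproduce the tonic ISI marginal);
    # faded out toward the attack endpoint
    s_vals, s_probs = tb.state_values()
    if s_vals.size > 1:
        xi0 = float(s_probs[1] * s_vals[1])  # tilted slow-state probability
        long0 = float(1.0 / s_vals[1])  # slow segments -> long intervals
        xi = (1.0 - f) * xi0 + f * ab.pause_slow_frac
        long = float(np.exp((1 - f) * np.log(long0) + f * np.log(max(ab.pause_long_mult, 1.0))))
    else:
        xi, long = (1.0 - f) * ab.pause_slow_frac + f * ab.pause_slow_frac, ab.pause_long_mult

    w = (mu - 1.0) / mu
    tau = mu / rate - (mu - 1.0) / r_b
    if tau <= 1.0 / r_b:
        raise ParameterError("interpolated pause shorter than intra-burst ISI")
    # solve the lognormal pause drift so the mixture CV hits the linear target
    probe = BurstParams(
        intra_burst_rate_hz=r_b,
        burst_shape_kb=k_b,
        mean_burst_size=mu,
        pause_mean_s=tau,
        pause_shape_kp=k_p,
        pause_slow_frac=xi,
        pause_long_mult=long,
        t_ref_s=ab.t_ref_s,
    )
    vals, probs = probe.pause_mult_values()
    e2_2pt = float(np.sum(probs * vals * vals))
    e2_needed = (1.0 + cv_target**2) / rate**2
    e2_intra = w * (1.0 + 1.0 / k_b) / r_b**2
    base = (1.0 - w) * (1.0 + 1.0 / k_p) * e2_2pt * tau * tau
    one_plus_c2 = (e2_needed - e2_intra) / base
    c_p = float(np.sqrt(max(one_plus_c2 - 1.0, 0.0)))
    return burst_regime(replace(probe, pause_drift_cv=min(c_p, 0.999)))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradedRegime:
    """Severity-driven interpolation rule for a condition.

    Cells are assigned recording windows spread uniformly over
    ``window_min`` (minutes after injection); the latent severity at each
    window midpoint is mapped to a severity fraction and the regime is
    interpolated between ``baseline`` and ``attack``.
    """

    baseline: RegimeParams
    attack: RegimeParams
    window_min: tuple[float, float] = (0.0, 50.0)


@dataclass(frozen=True)
class CohortDesign:
    """Experimental design for a synthetic recording cohort."""

    n_cells: int
    n_mice: int
    duration_s: float
    regimes: Mapping[str, RegimeParams | GradedRegime]
    complex_spike_rate_hz: float = DEFAULT_CS_RATE_HZ
    cs_pause_s: float = DEFAULT_CS_PAUSE_S
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_mice < 1:
            raise ParameterError("n_cells and n_mice must be positive")
        if self.n_cells < self.n_mice:
            raise ParameterError("n_cells must be >= n_mice")
        if self.duration_s < 300:
            raise ParameterError("duration_s must be >= 300 (>= 5 min of recording)")
        if not self.regimes:
            raise ParameterError("regimes map must not be empty")


@dataclass(frozen=True)
class CohortDataset:
    """Generated trains plus the per-cell ground truth table."""

    trains: tuple[SpikeTrain, ...]
    ground_truth: "object"  # pandas.DataFrame; avoided in the type to keep numpy-only imports light


def cell_seed_sequence(master_seed: int, cell_id: str) -> np.random.SeedSequence:
    """Stable per-cell substream: entropy = (master_seed, crc32(cell_id))."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(cell_id.encode())])


def generate_cohort(design: CohortDesign, profile=None) -> CohortDataset:
    """Generate every cell in the design; deterministic in ``master_seed``.

    ``profile`` (a :class:`pkjburst.behavior.SeverityProfile`) is required
    when any condition uses a :class:`GradedRegime`; the latent severity at
    each cell's window midpoint is mapped to
    ``(score - baseline) / (peak - baseline)`` clipped to [0, 1].
    """
    import pandas as pd

    from .behavior import severity_profile as eval_profile

    conditions = list(design.regimes)
    n_per = {c: design.n_cells // len(conditions) for c in conditions}
    for i, c in enumerate(conditions):
        if i < design.n_cells % len(conditions):
            n_per[c] += 1

    trains: list[SpikeTrain] = []
    rows: list[dict] = []
    for cond in conditions:
        rule = design.regimes[cond]
        n = n_per[cond]
        for i in range(n):
            cell_id = f"{cond}-c{i:03d}"
            mouse_id = f"m{i % design.n_mice:02d}"
            ss = cell_seed_sequence(design.master_seed, cell_id)
            train_seed, cs_seed = ss.spawn(2)
            if isinstance(rule, GradedRegime):
                if profile is None:
                    raise ParameterError(
                        f"condition {cond!r} is severity-graded but no profile given"
                    )
                lo, hi = rule.window_min
                t_mid_min = lo + (i + 0.5) * (hi - lo) / n
                latent = eval_profile(t_mid_min, profile)
                denom = profile.peak_score - profile.baseline_score
                frac = 0.0 if denom <= 0 else (latent - profile.baseline_score) / denom
                frac = float(np.clip(frac, 0.0, 1.0))
                regime = interpolate_regime(rule.baseline, rule.attack, frac)
                t_injection_s = 0.0
                t_start_s = t_mid_min * 60.0 - design.duration_s / 2.0
            else:
                regime = rule
                frac = np.nan
                latent = np.nan
                t_mid_min = np.nan
                t_injection_s = None
                t_start_s = 0.0
            train = generate_regime_train(
                regime,
                design.duration_s,
                np.random.default_rng(train_seed),
                cell_id=cell_id,
                mouse_id=mouse_id,
                condition=cond,
                t_start_s=t_start_s,
                t_injection_s=t_injection_s,
            )
            train = insert_complex_spikes(
                train,
                design.complex_spike_rate_hz,
                design.cs_pause_s,
                np.random.default_rng(cs_seed),
            )
            trains.append(train)
            rows.append(
                {
                    "cell_id": cell_id,
                    "mouse_id": mouse_id,
                    "condition": cond,
                    "t_mid_min": t_mid_min,
                    "severity_frac": frac,
                    "latent_score": latent,
                    "regime_kind": regime.kind,
                    "seed_entropy": f"{design.master_seed}:{zlib.crc32(cell_id.encode())}",
                }
            )
    return CohortDataset(trains=tuple(trains), ground_truth=pd.DataFrame(rows))
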