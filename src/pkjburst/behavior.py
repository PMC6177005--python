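"""Disability scoring and the stereotyped attack time course.

Motor dysfunction is rated on a 0-5 ordinal scale (0 normal ... 5 almost
no ambulation, sustained abnormal movements) by several observers blind to
the condition, and the observer scores are averaged.  Caffeine-triggered
attacks follow a stereotyped time course: severity rises over roughly the
first 30 minutes and then slowly abates over one to two hours.

The model here is a latent continuous severity ``profile(t)`` plus an
observer layer: each observer reports ``round(latent + noise)`` clipped to
[0, 5], with independent Gaussian noise of standard deviation
``sigma_obs`` per observer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "SeverityProfile",
    "DisabilityScore",
    "severity_profile",
    "observer_scores",
    "sample_time_course",
    "DEFAULT_PROFILE",
    "DEFAULT_SCHEDULE_MIN",
]

# video-sampling schedule: every 10 min from 10 min before injection to 100 after
DEFAULT_SCHEDULE_MIN: tuple[float, ...] = tuple(float(t) for t in range(-10, 101, 10))

DEFAULT_SIGMA_OBS = 0.3
DEFAULT_N_OBSERVERS = 4


@dataclass(frozen=True)
class SeverityProfile:
    """Latent attack-severity time course (minutes after injection).

    ``piecewise-linear``: linear rise from baseline to peak over
    [0, t_peak_min], then exponential decay back toward baseline with
    half-life ``decay_half_life_min``.  ``log-normal-pulse``: baseline plus
    a lognormal-shaped pulse peaking at ``t_peak_min``.
    """

    baseline_score: float = 1.57
    peak_score: float = 4.5
    t_peak_min: float = 30.0
    t_end_min: float = 150.0
    shape: str = "piecewise-linear"
    decay_half_life_min: float = 35.0

    def __post_init__(self) -> None:
        if not (0 <= self.baseline_score <= 5 and 0 <= self.peak_score <= 5):
            raise ParameterError("scores must lie in [0, 5]")
        if self.peak_score < self.baseline_score:
            raise ParameterError("peak_score must be >= baseline_score")
        if not self.t_peak_min > 0:
            raise ParameterError("t_peak_min must be > 0")
        if not self.t_end_min > self.t_peak_min:
            raise ParameterError("t_end_min must exceed t_peak_min")
        if self.shape not in ("piecewise-linear", "log-normal-pulse"):
            raise ParameterError("shape must be piecewise-linear or log-normal-pulse")


DEFAULT_PROFILE = SeverityProfile()


def severity_profile(t_min, profile: SeverityProfile = DEFAULT_PROFILE):
    """Latent severity at time ``t_min`` (scalar or array) after injection."""
    t = np.asarray(t_min, dtype=float)
    base, peak = profile.baseline_score, profile.peak_score
    amp = peak - base
    if profile.shape == "piecewise-linear":
        rise = base + amp * t / profile.t_peak_min
        decay = base + amp * np.exp2(-(t - profile.t_peak_min) / profile.decay_half_life_min)
        out = np.where(t <= 0, base, np.where(t <= profile.t_peak_min, rise, decay))
    else:  # log-normal-pulse
        sigma = 0.5
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.log(np.maximum(t, 1e-12) / profile.t_peak_min) / sigma
            pulse = np.exp(-0.5 * z * z)
        out = base + amp * np.where(t <= 0, 0.0, pulse)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DisabilityScore:
    """Per-observer integer ratings at one time point, with their average."""

    t_rel_injection_min: float
    observer_scores: tuple[int, ...]
    mean_score: float
    sem: float

    def __post_init__(self) -> None:
        if any(not 0 <= s <= 5 for s in self.observer_scores):
            raise ParameterError("observer scores must be integers in [0, 5]")


def observer_scores(
    latent: float,
    n_observers: int = DEFAULT_N_OBSERVERS,
    sigma_obs: float = DEFAULT_SIGMA_OBS,
    seed=None,
    t_rel_injection_min: float = 0.0,
) -> DisabilityScore:
    """Blinded multi-observer rating of one latent severity value."""
    if not 1 <= n_observers <= 10:
        raise ParameterError("n_observers must lie in [1, 10]")
    if sigma_obs < 0:
        raise ParameterError("sigma_obs must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = latent + rng.normal(0.0, sigma_obs, n_observers) if sigma_obs > 0 else np.full(n_observers, float(latent))
    scores = np.clip(np.rint(noisy), 0, 5).astype(int)
    mean = float(scores.mean())
    sem = float(scores.std(ddof=1) / np.sqrt(n_observers)) if n_observers > 1 else 0.0
    return DisabilityScore(
        t_rel_injection_min=t_rel_injection_min,
        observer_scores=tuple(int(s) for s in scores),
        mean_score=mean,
        sem=sem,
    )


def sample_time_course(
    profile: SeverityProfile = DEFAULT_PROFILE,
    schedule_min=DEFAULT_SCHEDULE_MIN,
    n_mice: int = 3,
    n_observers: int = DEFAULT_N_OBSERVERS,
    sigma_obs: float = DEFAULT_SIGMA_OBS,
    seed: int = 0,
):
    """Score table over the video schedule: one row per mouse x time point.

    Returns a pandas DataFrame with columns (mouse_id, t_rel_injection_min,
    mean_score, sem, score_obs0..).  The schedule must be sorted.
    """
    import pandas as pd

    sched = np.asarray(schedule_min, dtype=float)
    if np.any(np.diff(sched) < 0):
        raise ParameterError("schedule must be sorted")
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        for t in sched:
            latent = severity_profile(float(t), profile)
            ds = observer_scores(
                latent, n_observers, sigma_obs, rng, t_rel_injection_min=float(t)
            )
            row = {
                "mouse_id": f"m{m:02d}",
                "t_rel_injection_min": float(t),
                "mean_score": ds.mean_score,
                "sem": ds.sem,
            }
            row.update({f"score_obs{i}": s for i, s in enumerate(ds.observer_scores)})
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_time_course(scores) -> "object":
    """Mean +/- sem across mice per time point (mirrors the published plot)."""
    import pandas as pd

    g = scores.groupby("t_rel_injection_min")["mean_score"]
    out = pd.DataFrame(
        {
            "mean_score": g.mean(),
            "sem": g.std(ddof=1) / np.sqrt(g.count()),
            "n_mice": g.count(),
        }
    ).reset_index()
    return out
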