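"""Interspike-interval statistics for single spike trains.

The three summary statistics used throughout the package:

* mean firing rate — simple-spike count divided by recording duration;
* ISI CV — sample standard deviation of the interspike intervals divided
  by their mean (0 for a perfect clock, 1 for a Poisson process);
* predominant firing rate (PFR) — reciprocal of the mode of the ISI
  histogram; it tracks the dominant instantaneous rate, so burst firing
  inflates it even when the mean rate is unchanged.

Complex spikes are excluded from spike counts, and intervals spanning a
complex spike are dropped from the ISI sequence by default, so the simple-
spike statistics are not contaminated by the post-complex-spike pause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTrainError, InsufficientDataError, ParameterError
from .synthetic import SpikeTrain

__all__ = [
    "ISISequence",
    "ISIHistogram",
    "TrainSummary",
    "ECDF",
    "MetricOptions",
    "interspike_intervals",
    "mean_firing_rate",
    "isi_cv",
    "isi_histogram",
    "predominant_firing_rate",
    "isi_ecdf",
    "summarize_train",
]

DEFAULT_BIN_WIDTH_S = 0.001
DEFAULT_MAX_ISI_S = 1.0
DEFAULT_MIN_ISIS = 100


@dataclass(frozen=True)
class ISISequence:
    isis_s: np.ndarray
    source_cell: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.isis_s, dtype=float)
        object.__setattr__(self, "isis_s", arr)
        if arr.size and np.any(arr <= 0):
            raise ParameterError("interspike intervals must be > 0")

    @property
    def n(self) -> int:
        return int(self.isis_s.size)


@dataclass(frozen=True)
class ISIHistogram:
    bin_width_s: float
    max_isi_s: float
    edges: np.ndarray
    counts: np.ndarray
    n_overflow: int

    @property
    def centers_s(self) -> np.ndarray:
        return self.edges[:-1] + self.bin_width_s / 2.0


@dataclass(frozen=True)
class TrainSummary:
    """The statistic triplet plus bookkeeping for one train."""

    mean_rate_hz: float
    isi_cv: float
    pfr_hz: float
    n_spikes: int
    duration_s: float
    cell_id: str = ""
    condition: str = ""


@dataclass(frozen=True)
class ECDF:
    grid_s: np.ndarray
    cum_frac: np.ndarray


@dataclass(frozen=True)
class MetricOptions:
    """Shared knobs for the summary pipeline (defaults used package-wide)."""

    bin_width_s: float = DEFAULT_BIN_WIDTH_S
    max_isi_s: float = DEFAULT_MAX_ISI_S
    min_isis: int = DEFAULT_MIN_ISIS
    exclude_complex: bool = True


def interspike_intervals(train: SpikeTrain, exclude_complex: bool = True) -> ISISequence:
    """Consecutive simple-spike differences.

    With ``exclude_complex`` (the default), any interval with a complex
    spike strictly in its interior is dropped: those intervals include the
    post-complex-spike pause and would bias the simple-spike statistics.
    """
    ss = train.simple_spikes
    if ss.size < 2:
        raise DegenerateTrainError("need >= 2 simple spikes for ISIs")
    isis = np.diff(ss)
    if exclude_complex and train.complex_spikes.size:
        cs = train.complex_spikes
        idx = np.searchsorted(ss, cs, side="left")
        # CS lies strictly inside (ss[idx-1], ss[idx]) unless it equals ss[idx]
        interior = (idx > 0) & (idx < ss.size)
        interior[interior] &= cs[interior] != ss[idx[interior]]
        drop = np.unique(idx[interior] - 1)
        keep = np.ones(isis.size, dtype=bool)
        keep[drop] = False
        isis = isis[keep]
    return ISISequence(isis_s=isis, source_cell=train.cell_id)


def mean_firing_rate(train: SpikeTrain) -> float:
    """Simple-spike count divided by recording duration (spikes/s)."""
    if train.duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    return train.n_simple / train.duration_s


def isi_cv(isis: ISISequence, min_isis: int = DEFAULT_MIN_ISIS) -> float:
    """sd(ISI)/mean(ISI) with the sample (n-1) standard deviation."""
    if isis.n < min_isis:
        raise InsufficientDataError(
            f"need >= {min_isis} interspike intervals, got {isis.n}"
        )
    x = isis.isis_s
    if np.ptp(x) == 0:  # a perfect clock has CV exactly 0
        return 0.0
    return float(np.std(x, ddof=1) / np.mean(x))


def isi_histogram(
    isis: ISISequence,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    max_isi_s: float = DEFAULT_MAX_ISI_S,
) -> ISIHistogram:
    """Uniform left-closed right-open bins on [0, max_isi_s); overflow kept."""
    if bin_width_s <= 0:
        raise ParameterError("bin_width_s must be > 0")
    if max_isi_s <= bin_width_s:
        raise ParameterError("max_isi_s must exceed bin_width_s")
    n_bins = int(np.ceil(max_isi_s / bin_width_s - 1e-12))
    idx = np.floor(isis.isis_s / bin_width_s).astype(np.int64)
    overflow = int(np.count_nonzero(idx >= n_bins))
    counts = np.bincount(idx[idx < n_bins], minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width_s
    return ISIHistogram(
        bin_width_s=bin_width_s,
        max_isi_s=n_bins * bin_width_s,
        edges=edges,
        counts=counts,
        n_overflow=overflow,
    )


def predominant_firing_rate(hist: ISIHistogram) -> float:
    """Reciprocal of the modal bin center; ties go to the shortest ISI bin."""
    if not np.any(hist.counts):
        raise InsufficientDataError("all histogram bins empty")
    i = int(np.argmax(hist.counts))  # argmax takes the first (shortest) tie
    return 1.0 / ((i + 0.5) * hist.bin_width_s)


def isi_ecdf(isis: ISISequence, grid_s) -> ECDF:
    """Fraction of ISIs <= each grid point."""
    grid = np.asarray(grid_s, dtype=float)
    if grid.size == 0:
        raise ParameterError("grid must be non-empty")
    if np.any(np.diff(grid) < 0) or np.any(grid <= 0):
        raise ParameterError("grid must be sorted and positive")
    if isis.n == 0:
        raise InsufficientDataError("no interspike intervals")
    x = np.sort(isis.isis_s)
    frac = np.searchsorted(x, grid, side="right") / x.size
    return ECDF(grid_s=grid, cum_frac=frac)


def summarize_train(train: SpikeTrain, opts: MetricOptions = MetricOptions()) -> TrainSummary:
    """Mean rate, ISI CV and PFR for one train under shared options."""
    isis = interspike_intervals(train, exclude_complex=opts.exclude_complex)
    hist = isi_histogram(isis, opts.bin_width_s, opts.max_isi_s)
    return TrainSummary(
        mean_rate_hz=mean_firing_rate(train),
        isi_cv=isi_cv(isis, opts.min_isis),
        pfr_hz=predominant_firing_rate(hist),
        n_spikes=train.n_simple,
        duration_s=train.duration_s,
        cell_id=train.cell_id,
        condition=train.condition,
    )


def summarize_cohort(trains, opts: MetricOptions = MetricOptions()):
    """Per-train summaries as a pandas DataFrame (one row per cell)."""
    import pandas as pd

    rows = []
    for tr in trains:
        s = summarize_train(tr, opts)
        rows.append(
            {
                "cell_id": s.cell_id,
                "condition": s.condition,
                "mean_rate_hz": s.mean_rate_hz,
                "isi_cv": s.isi_cv,
                "pfr_hz": s.pfr_hz,
                "n_spikes": s.n_spikes,
                "duration_s": s.duration_s,
            }
        )
    return pd.DataFrame(rows)
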