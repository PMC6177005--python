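"""Prebuilt study designs: condition cohorts and the graded-attack experiment.

Thin composition layer used by the analysis drivers, the acceptance
script and the test suite, so every consumer runs the identical design.
"""

from __future__ import annotations

import pandas as pd

from .behavior import DEFAULT_PROFILE, SeverityProfile, sample_time_course
from .calibration import PRESET_TABLE, load_preset
from .metrics import MetricOptions, summarize_cohort
from .synthetic import CohortDataset, CohortDesign, GradedRegime, generate_cohort

__all__ = ["condition_cohort", "graded_experiment"]


def condition_cohort(
    name: str,
    seed: int,
    n_cells: int | None = None,
    duration_s: float = 300.0,
) -> CohortDataset:
    """Cohort for one packaged condition preset at the published n/N."""
    info = PRESET_TABLE[name]
    n = n_cells or info["n"]
    design = CohortDesign(
        n_cells=n,
        n_mice=min(info["N"], n),
        duration_s=duration_s,
        regimes={name: load_preset(name).params},
        master_seed=seed,
    )
    return generate_cohort(design)


def graded_experiment(
    seed: int,
    n_cells: int = 20,
    n_mice: int = 6,
    duration_s: float = 300.0,
    profile: SeverityProfile = DEFAULT_PROFILE,
    opts: MetricOptions = MetricOptions(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Graded-attack experiment: cells over 0-50 min plus a score table.

    Returns ``(summaries, scores)`` ready for
    :func:`pkjburst.analysis.severity_regression`: per-cell summary rows
    carry the recording-window midpoint as ``t_rel_injection_min``.
    """
    design = CohortDesign(
        n_cells=n_cells,
        n_mice=n_mice,
        duration_s=duration_s,
        regimes={
            "attack-graded": GradedRegime(
                load_preset("tottering-baseline").params,
                load_preset("tottering-attack").params,
            )
        },
        master_seed=seed,
    )
    ds = generate_cohort(design, profile)
    summaries = summarize_cohort(ds.trains, opts)
    summaries["t_rel_injection_min"] = ds.ground_truth["t_mid_min"].to_numpy()
    scores = sample_time_course(profile, n_mice=n_mice, seed=seed)
    return summaries, scores
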