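"""Simulate the six condition cohorts and summarize each cell.

One cohort per packaged preset, at the condition's published cell/mouse
counts and 300 s per cell.  Raw spike CSVs are bulky and land under
scratch/cohorts/<preset>/; the per-train summaries are collected in
results/condition_summaries.csv.

Run from the repository root:  python analysis/02_simulate_cohorts.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from pkjburst.calibration import PRESET_TABLE
from pkjburst.experiments import condition_cohort
from pkjburst.io import write_cohort
from pkjburst.metrics import summarize_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    frames = []
    for name in PRESET_TABLE:
        ds = condition_cohort(name, seed)
        write_cohort(ds, SCRATCH / "cohorts" / name)
        df = summarize_cohort(ds.trains)
        frames.append(df)
        m = df[["mean_rate_hz", "isi_cv", "pfr_hz"]].mean()
        print(
            f"{name:22s} n={len(df):2d}  rate={m.mean_rate_hz:6.2f}  "
            f"cv={m.isi_cv:5.3f}  pfr={m.pfr_hz:6.1f}"
        )
    pd.concat(frames).to_csv(RESULTS / "condition_summaries.csv", index=False,
                             float_format="%.9g")
    print(f"summaries written to {RESULTS/'condition_summaries.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
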