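"""Group statistics across the simulated conditions.

Reproduces the study's comparison structure on synthetic cohorts:

* baseline / attack / no-attack: one-way ANOVA with Tukey's HSD per
  statistic (the attack should separate from baseline on ISI CV and PFR
  but not mean rate; no-attack should not separate from baseline);
* baseline vs attack ISI cumulative distributions: two-way ANOVA with
  Sidak-adjusted per-grid-point contrasts (short-ISI excess in attack);
* vehicle vs cadmium: unpaired Student's t-tests per statistic.

Writes results/group_tests.json and pairwise tables under results/.

Run from the repository root:  python analysis/03_condition_statistics.py [seed]
"""

import json
import sys
from pathlib import Path

import pandas as pd

from pkjburst.analysis import (
    one_way_anova_tukey,
    two_way_anova_sidak,
    unpaired_t_test,
)
from pkjburst.experiments import condition_cohort
from pkjburst.metrics import interspike_intervals, isi_ecdf, summarize_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
ECDF_GRID_S = (0.005, 0.01, 0.02, 0.05)
STATS = ("mean_rate_hz", "isi_cv", "pfr_hz")


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohorts = {
        name: condition_cohort(name, seed)
        for name in (
            "tottering-baseline",
            "tottering-attack",
            "caffeine-no-attack",
            "wt-vehicle",
            "wt-cadmium",
        )
    }
    summaries = {k: summarize_cohort(v.trains) for k, v in cohorts.items()}
    out: dict = {}

    # three-condition comparison (Fig 1D-F structure)
    for stat in STATS:
        groups = {
            k: summaries[k][stat].to_numpy()
            for k in ("tottering-baseline", "tottering-attack", "caffeine-no-attack")
        }
        res = one_way_anova_tukey(groups)
        out[f"anova_tukey:{stat}"] = {
            "F": res.statistic, "df": list(res.df), "p": res.p_value,
        }
        res.pairwise.to_csv(RESULTS / f"tukey_{stat}.csv", index=False)
        sig = res.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        print(f"{stat:12s} F={res.statistic:8.2f} p={res.p_value:.2e}  "
              f"attack-vs-baseline p_adj={sig.get(('tottering-attack', 'tottering-baseline'), sig.get(('tottering-baseline', 'tottering-attack'))):.4f}")

    # ECDF short-ISI contrast, baseline vs attack (Fig 1G structure)
    rows = []
    for name in ("tottering-baseline", "tottering-attack"):
        for tr in cohorts[name].trains[:13]:  # balance the design
            e = isi_ecdf(interspike_intervals(tr), ECDF_GRID_S)
            rows += [{"condition": name, "bin": g, "value": f, "cell_id": tr.cell_id}
                     for g, f in zip(e.grid_s, e.cum_frac)]
    res = two_way_anova_sidak(pd.DataFrame(rows))
    res.pairwise.to_csv(RESULTS / "ecdf_sidak.csv", index=False)
    out["two_way_sidak:ecdf"] = {
        "F_condition": res.statistic, "df": list(res.df), "p": res.p_value,
        "p_adj_at_5ms": float(res.pairwise.set_index("bin")["p_adj"].loc[0.005]),
    }
    print("ECDF 5 ms Sidak p_adj:", out["two_way_sidak:ecdf"]["p_adj_at_5ms"])

    # vehicle vs cadmium (Fig 2H-J structure)
    for stat in STATS:
        res = unpaired_t_test(
            summaries["wt-vehicle"][stat], summaries["wt-cadmium"][stat]
        )
        out[f"t_test_vehicle_cadmium:{stat}"] = {
            "t": res.statistic, "df": list(res.df), "p": res.p_value,
        }
        print(f"vehicle vs cadmium {stat:12s} t={res.statistic:7.2f} p={res.p_value:.2e}")

    (RESULTS / "group_tests.json").write_text(json.dumps(out, indent=2))
    print(f"tests written to {RESULTS/'group_tests.json'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
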