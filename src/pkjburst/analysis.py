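"""Group statistics and the burstiness-versus-severity regression.

Conventions follow the study design being emulated: two-condition
comparisons use the unpaired (pooled-variance) Student's t-test,
three-condition comparisons a one-way ANOVA with Tukey's HSD, cumulative
ISI distributions a two-way ANOVA with Sidak-adjusted per-bin contrasts,
and all means are reported +/- s.e.m. with n = cells (electrophysiology)
or N = mice (behavior).

The severity regression pairs time-binned mean firing statistics with
time-binned mean disability scores (default 10 min bins, aligned to the
video-sampling schedule) and fits ordinary least squares on the bin means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, UnbalancedDesignError, ZeroVarianceError
from .metrics import ECDF, MetricOptions, interspike_intervals, isi_ecdf, summarize_cohort

__all__ = [
    "TestResult",
    "RegressionResult",
    "ExperimentReport",
    "unpaired_t_test",
    "one_way_anova_tukey",
    "two_way_anova_sidak",
    "severity_regression",
    "analyze_experiment",
]

DEFAULT_ECDF_GRID_S = (0.005, 0.01, 0.02, 0.05)
DEFAULT_REGRESSION_BIN_MIN = 10.0


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


@dataclass(frozen=True)
class ExperimentReport:
    summary_table: pd.DataFrame
    tests: dict
    regressions: dict
    ecdf_table: pd.DataFrame | None
    metadata: dict


def unpaired_t_test(a, b) -> TestResult:
    """Two-sided unpaired Student's t-test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ZeroVarianceError("all observations identical in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        statistic=float(t),
        df=(a.size + b.size - 2,),
        p_value=float(p),
        method="unpaired Student's t-test (pooled variance)",
    )


def one_way_anova_tukey(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """One-way ANOVA with Tukey's HSD pairwise comparisons (>= 3 groups)."""
    if len(groups) < 3:
        raise ParameterError("one-way ANOVA with Tukey requires >= 3 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs n >= 2")
    f, p = sps.f_oneway(*arrays)
    n_tot = sum(a.size for a in arrays)
    df = (len(arrays) - 1, n_tot - len(arrays))
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        f, p = 0.0, 1.0
    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return TestResult(
        statistic=float(f),
        df=df,
        p_value=float(p),
        method="one-way ANOVA with Tukey's HSD",
        pairwise=pd.DataFrame(rows),
    )


def two_way_anova_sidak(
    values: pd.DataFrame,
    condition_col: str = "condition",
    bin_col: str = "bin",
    value_col: str = "value",
) -> TestResult:
    """Balanced two-factor fixed-effects ANOVA with Sidak per-bin contrasts.

    ``values`` holds one row per replicate (cell) per condition x bin.
    Exactly two conditions are compared; per-bin contrasts use the
    residual mean square from the full two-way fit and are Sidak-adjusted
    with m = number of bins: p_adj = 1 - (1 - p)^m.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = values.rename(
        columns={condition_col: "cond", bin_col: "bin_", value_col: "val"}
    )[["cond", "bin_", "val"]].copy()
    conds = sorted(df["cond"].unique())
    bins = sorted(df["bin_"].unique())
    if len(conds) != 2:
        raise ParameterError("exactly two conditions required")
    if len(bins) < 1:
        raise ParameterError("at least one bin required")
    counts = df.groupby(["cond", "bin_"]).size()
    if counts.size != len(conds) * len(bins) or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "two-way ANOVA requires a balanced condition x bin design"
        )
    n_rep = int(counts.iloc[0])
    if n_rep < 2:
        raise ParameterError("need >= 2 replicates per design cell")
    formula = "val ~ C(cond) * C(bin_)" if len(bins) > 1 else "val ~ C(cond)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_cond = float(table.loc["C(cond)", "F"])
    p_cond = float(table.loc["C(cond)", "PR(>F)"])
    df_num = int(table.loc["C(cond)", "df"])
    df_res = int(table.loc["Residual", "df"])
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    if np.isnan(f_cond):  # zero residual and zero effect
        f_cond, p_cond = 0.0, 1.0
    m = len(bins)
    rows = []
    for b in bins:
        sub = df[df["bin_"] == b]
        m1 = sub.loc[sub["cond"] == conds[0], "val"].mean()
        m2 = sub.loc[sub["cond"] == conds[1], "val"].mean()
        se = np.sqrt(mse * 2.0 / n_rep)
        if se == 0:
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat = (m1 - m2) / se
            p_raw = 2.0 * sps.t.sf(abs(t_stat), df_res)
        p_adj = 1.0 - (1.0 - p_raw) ** m
        rows.append(
            {
                "bin": b,
                "mean_diff": float(m1 - m2),
                "t": float(t_stat),
                "p_raw": float(p_raw),
                "p_adj": float(min(p_adj, 1.0)),
            }
        )
    return TestResult(
        statistic=f_cond,
        df=(df_num, df_res),
        p_value=p_cond,
        method="two-way ANOVA with Sidak's multiple comparisons",
        pairwise=pd.DataFrame(rows),
    )


def severity_regression(
    summaries: pd.DataFrame,
    scores: pd.DataFrame,
    bin_width_min: float = DEFAULT_REGRESSION_BIN_MIN,
    stats: Sequence[str] = ("isi_cv", "pfr_hz", "mean_rate_hz"),
) -> dict[str, RegressionResult]:
    """OLS of time-binned mean firing statistics on binned disability means.

    ``summaries`` needs a ``t_rel_injection_min`` column plus the statistic
    columns; ``scores`` needs ``t_rel_injection_min`` and ``mean_score``.
    Cells and scores are binned into common ``bin_width_min`` bins centered
    on the video-schedule sampling times (bin b covers
    [b*w - w/2, b*w + w/2)), so a score taken at t = b*w is paired with the
    cells recorded around that time; only bins populated on both sides
    enter the fit.
    """
    if bin_width_min <= 0:
        raise ParameterError("bin_width_min must be > 0")
    s = summaries.copy()
    s["_bin"] = np.round(s["t_rel_injection_min"] / bin_width_min).astype(int)
    sc = scores.copy()
    sc["_bin"] = np.round(sc["t_rel_injection_min"] / bin_width_min).astype(int)
    stat_means = s.groupby("_bin")[list(stats)].mean()
    score_means = sc.groupby("_bin")["mean_score"].mean()
    common = stat_means.index.intersection(score_means.index)
    if len(common) < 3:
        raise ParameterError(
            f"need >= 3 populated time bins on both sides, got {len(common)}"
        )
    x = score_means.loc[common].to_numpy()
    out: dict[str, RegressionResult] = {}
    for stat in stats:
        y = stat_means.loc[common, stat].to_numpy()
        if np.ptp(y) == 0:
            out[stat] = RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(common))
            continue
        fit = sps.linregress(x, y)
        out[stat] = RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            p_value=float(fit.pvalue),
            n_points=int(len(common)),
        )
    return out


def _condition_summary(per_train: pd.DataFrame, mice: pd.DataFrame | None) -> pd.DataFrame:
    rows = []
    for cond, sub in per_train.groupby("condition"):
        row = {"condition": cond, "n_cells": int(len(sub))}
        if mice is not None:
            row["N_mice"] = int(
                mice.loc[mice["condition"] == cond, "mouse_id"].nunique()
            )
        for stat in ("mean_rate_hz", "isi_cv", "pfr_hz"):
            vals = sub[stat].to_numpy()
            row[f"{stat}_mean"] = float(vals.mean())
            row[f"{stat}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_experiment(
    cohort,
    scores: pd.DataFrame | None = None,
    opts: MetricOptions = MetricOptions(),
    ecdf_grid_s: Sequence[float] = DEFAULT_ECDF_GRID_S,
    bin_width_min: float = DEFAULT_REGRESSION_BIN_MIN,
) -> ExperimentReport:
    """Full report over a cohort: summaries, group tests, ECDFs, regressions.

    ``cohort`` is a :class:`pkjburst.synthetic.CohortDataset` or a plain
    sequence of trains.  With a single condition only summaries are
    produced; with two conditions a t-test per statistic and per-bin ECDF
    contrasts; with three or more a one-way ANOVA with Tukey's HSD.  When
    ``scores`` and per-cell injection times are available the severity
    regression is run as well.
    """
    trains = list(getattr(cohort, "trains", cohort))
    gt = getattr(cohort, "ground_truth", None)
    per_train = summarize_cohort(trains, opts)
    per_train["mouse_id"] = [tr.mouse_id for tr in trains]
    conds = sorted(per_train["condition"].unique())
    summary = _condition_summary(per_train, per_train[["condition", "mouse_id"]])

    tests: dict = {}
    if len(conds) == 2:
        for stat in ("mean_rate_hz", "isi_cv", "pfr_hz"):
            g = [per_train.loc[per_train["condition"] == c, stat] for c in conds]
            tests[f"t_test:{stat}"] = unpaired_t_test(g[0], g[1])
    elif len(conds) >= 3:
        for stat in ("mean_rate_hz", "isi_cv", "pfr_hz"):
            groups = {
                c: per_train.loc[per_train["condition"] == c, stat].to_numpy()
                for c in conds
            }
            tests[f"anova_tukey:{stat}"] = one_way_anova_tukey(groups)

    ecdf_rows = []
    for tr in trains:
        e = isi_ecdf(interspike_intervals(tr, opts.exclude_complex), ecdf_grid_s)
        for g, f in zip(e.grid_s, e.cum_frac):
            ecdf_rows.append(
                {"cell_id": tr.cell_id, "condition": tr.condition, "bin": g, "value": f}
            )
    ecdf_table = pd.DataFrame(ecdf_rows)
    if len(conds) == 2:
        n_per = per_train.groupby("condition").size()
        if n_per.nunique() == 1:
            tests["two_way_sidak:ecdf"] = two_way_anova_sidak(ecdf_table)

    regressions: dict = {}
    has_times = all(tr.t_injection_s is not None for tr in trains)
    if scores is not None and has_times and len(trains) >= 3:
        per_train = per_train.assign(
            t_rel_injection_min=[
                (tr.t_start_s + tr.duration_s / 2.0 - tr.t_injection_s) / 60.0
                for tr in trains
            ]
        )
        try:
            regressions = severity_regression(per_train, scores, bin_width_min)
        except ParameterError:
            regressions = {}

    metadata = {
        "n_cells": len(trains),
        "conditions": conds,
        "metric_options": vars(opts).copy() if hasattr(opts, "__dict__") else {
            "bin_width_s": opts.bin_width_s,
            "max_isi_s": opts.max_isi_s,
            "min_isis": opts.min_isis,
            "exclude_complex": opts.exclude_complex,
        },
        "ecdf_grid_s": list(ecdf_grid_s),
        "regression_bin_width_min": bin_width_min,
        "ground_truth_available": gt is not None,
    }
    return ExperimentReport(
        summary_table=summary,
        tests=tests,
        regressions=regressions,
        ecdf_table=ecdf_table,
        metadata=metadata,
    )
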