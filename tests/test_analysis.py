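"""Group tests against independent oracles; regression behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pkjburst.analysis import (
    analyze_experiment,
    one_way_anova_tukey,
    severity_regression,
    two_way_anova_sidak,
    unpaired_t_test,
)
from pkjburst.errors import ParameterError, UnbalancedDesignError, ZeroVarianceError


def _pooled_t_oracle(a, b):
    """Textbook pooled-variance t statistic, written out by hand."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def _anova_f_oracle(groups):
    """One-way fixed-effects F from raw sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestTTest:
    def test_hand_calculated_example(self):
        res = unpaired_t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=0.001)
        assert res.df == (4,)
        assert res.p_value == pytest.approx(0.0213, abs=0.001)

    def test_identical_groups(self):
        res = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ZeroVarianceError):
            unpaired_t_test([2.0, 2.0], [2.0, 2.0])

    def test_oracle_equivalence_random(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 12)))
            res = unpaired_t_test(a, b)
            t, p = _pooled_t_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-6)
            assert res.p_value == pytest.approx(p, abs=1e-6)


class TestOneWayAnovaTukey:
    def test_three_identical_groups(self):
        g = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        res = one_way_anova_tukey(g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert np.allclose(res.pairwise["p_adj"], 1.0)

    def test_one_shifted_group_detected(self, rng):
        g = {
            "a": rng.normal(0, 0.2, 8),
            "b": rng.normal(0, 0.2, 8),
            "c": rng.normal(10, 0.2, 8),
        }
        res = one_way_anova_tukey(g)
        pw = res.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        assert pw[("a", "c")] < 0.001 and pw[("b", "c")] < 0.001
        assert pw[("a", "b")] > 0.05

    def test_f_statistic_oracle(self, rng):
        for _ in range(100):
            groups = [
                rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(3, 10)))
                for _ in range(int(rng.integers(3, 5)))
            ]
            res = one_way_anova_tukey({str(i): g for i, g in enumerate(groups)})
            assert res.statistic == pytest.approx(
                _anova_f_oracle(groups), abs=1e-6
            )

    def test_tukey_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for _ in range(20):
            groups = {
                k: rng.normal(mu, 1, 6)
                for k, mu in zip("abc", rng.uniform(-2, 2, 3))
            }
            res = one_way_anova_tukey(groups)
            vals = np.concatenate(list(groups.values()))
            labels = np.repeat(list(groups), [len(v) for v in groups.values()])
            sm_res = pairwise_tukeyhsd(vals, labels)
            ours = res.pairwise.sort_values(["group_a", "group_b"])["p_adj"]
            assert np.allclose(ours, sm_res.pvalues, atol=1e-6)

    def test_requires_three_groups(self):
        with pytest.raises(ParameterError):
            one_way_anova_tukey({"a": [1, 2], "b": [3, 4]})


class TestTwoWayAnovaSidak:
    def _frame(self, vals_by_cond_bin):
        rows = []
        for (cond, b), vals in vals_by_cond_bin.items():
            rows += [{"condition": cond, "bin": b, "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_identical_conditions(self, rng):
        base = rng.normal(0, 1, 4)
        df = self._frame(
            {("x", b): base for b in (1, 2, 3)}
            | {("y", b): base for b in (1, 2, 3)}
        )
        res = two_way_anova_sidak(df)
        assert res.p_value > 0.999
        assert np.all(res.pairwise["p_adj"] > 0.999)

    def test_single_bin_sidak_is_identity(self, rng):
        df = self._frame({("x", 0): rng.normal(0, 1, 5),
                          ("y", 0): rng.normal(1, 1, 5)})
        res = two_way_anova_sidak(df)
        row = res.pairwise.iloc[0]
        assert row["p_adj"] == pytest.approx(row["p_raw"], rel=1e-12)

    def test_sidak_adjustment_monotone(self, rng):
        df = self._frame(
            {(c, b): rng.normal(0.3 * b if c == "y" else 0, 1, 5)
             for c in "xy" for b in range(4)}
        )
        res = two_way_anova_sidak(df)
        assert np.all(res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-15)

    def test_unbalanced_design_rejected(self, rng):
        df = self._frame({("x", 0): [1.0, 2.0], ("y", 0): [1.0, 2.0, 3.0]})
        with pytest.raises(UnbalancedDesignError):
            two_way_anova_sidak(df)

    def test_separated_conditions_significant(self, rng):
        df = self._frame(
            {("x", b): rng.normal(0, 0.3, 6) for b in range(3)}
            | {("y", b): rng.normal(2, 0.3, 6) for b in range(3)}
        )
        res = two_way_anova_sidak(df)
        assert np.all(res.pairwise["p_adj"] < 0.05)


class TestSeverityRegression:
    def _tables(self, y, x=None):
        t = np.arange(len(y)) * 10.0
        summaries = pd.DataFrame(
            {"t_rel_injection_min": t, "isi_cv": y,
             "pfr_hz": y, "mean_rate_hz": y}
        )
        scores = pd.DataFrame(
            {"t_rel_injection_min": t,
             "mean_score": x if x is not None else np.linspace(1, 4, len(y))}
        )
        return summaries, scores

    def test_perfect_linear(self):
        x = np.linspace(1, 4, 6)
        s, sc = self._tables(0.5 + 0.3 * x, x)
        res = severity_regression(s, sc)["isi_cv"]
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.3)

    def test_constant_statistic(self):
        s, sc = self._tables(np.full(6, 0.7))
        res = severity_regression(s, sc)["isi_cv"]
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_too_few_bins(self):
        s, sc = self._tables(np.array([0.5, 0.7]))
        with pytest.raises(ParameterError):
            severity_regression(s, sc)

    def test_r2_invariant_to_affine_score_rescale(self, rng):
        y = rng.normal(1.0, 0.2, 6)
        x = np.linspace(1, 4, 6)
        s, sc = self._tables(y, x)
        r1 = severity_regression(s, sc)["isi_cv"].r_squared
        sc2 = sc.assign(mean_score=3.0 * sc["mean_score"] - 1.0)
        r2 = severity_regression(s, sc2)["isi_cv"].r_squared
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestAnalyzeExperiment:
    @pytest.fixture(scope="class")
    def two_condition_cohort(self, presets):
        from pkjburst.synthetic import CohortDesign, generate_cohort

        design = CohortDesign(
            n_cells=8, n_mice=4, duration_s=300.0,
            regimes={
                "baseline": presets["tottering-baseline"].params,
                "attack": presets["tottering-attack"].params,
            },
            master_seed=21,
        )
        return generate_cohort(design)

    def test_single_condition_no_tests(self, presets):
        from pkjburst.synthetic import CohortDesign, generate_cohort

        design = CohortDesign(
            n_cells=3, n_mice=3, duration_s=300.0,
            regimes={"baseline": presets["tottering-baseline"].params},
            master_seed=5,
        )
        report = analyze_experiment(generate_cohort(design))
        assert report.tests == {}
        assert len(report.summary_table) == 1

    def test_two_conditions_get_t_tests_and_ecdf(self, two_condition_cohort):
        report = analyze_experiment(two_condition_cohort)
        assert "t_test:isi_cv" in report.tests
        assert "two_way_sidak:ecdf" in report.tests
        assert report.tests["t_test:isi_cv"].p_value < 0.001

    def test_report_deterministic(self, two_condition_cohort):
        r1 = analyze_experiment(two_condition_cohort)
        r2 = analyze_experiment(two_condition_cohort)
        assert r1.summary_table.equals(r2.summary_table)
        assert r1.tests["t_test:pfr_hz"].p_value == r2.tests["t_test:pfr_hz"].p_value
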