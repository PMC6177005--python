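"""Generator-level properties: renewal statistics, determinism, refractoriness."""

import numpy as np
import pytest

from pkjburst.errors import DegenerateTrainError, ParameterError
from pkjburst.metrics import interspike_intervals, summarize_train
from pkjburst.synthetic import (
    BurstParams,
    CohortDesign,
    GradedRegime,
    RegimeParams,
    SpikeTrain,
    TonicParams,
    burst_regime,
    generate_burst_train,
    generate_cohort,
    generate_tonic_train,
    insert_complex_spikes,
    interpolate_regime,
    tonic_regime,
)


class TestTonicGenerator:
    def test_deterministic_clock_limit(self):
        """Huge gamma shape approximates a perfect 20 ms clock."""
        train = generate_tonic_train(TonicParams(50.0, 1e6), 300.0, seed=0)
        isis = np.diff(train.simple_spikes)
        assert np.all(np.abs(isis - 0.02) < 0.001)
        assert np.std(isis, ddof=1) / np.mean(isis) < 0.01

    def test_gamma_renewal_cv_closed_form(self):
        """ISI CV converges to 1/sqrt(k) without drift (2% at 1e5 ISIs)."""
        train = generate_tonic_train(TonicParams(50.0, 4.0), 2000.0, seed=1)
        isis = np.diff(train.simple_spikes)
        assert isis.size > 9e4
        cv = np.std(isis, ddof=1) / np.mean(isis)
        assert cv == pytest.approx(0.5, rel=0.02)

    def test_expected_count(self):
        train = generate_tonic_train(TonicParams(50.0, 4.0), 300.0, seed=2)
        assert train.n_simple == pytest.approx(15000, rel=0.05)

    def test_rate_consistency_over_replicates(self):
        """Mean of realized rates over 100 trains within 2 SE of nominal."""
        p = TonicParams(50.0, 3.0, rate_drift_cv=0.2, slow_state_frac=0.2,
                        slow_rate_mult=0.5)
        rates = np.array(
            [generate_tonic_train(p, 300.0, seed=s).n_simple / 300.0
             for s in range(100)]
        )
        se = rates.std(ddof=1) / 10.0
        assert abs(rates.mean() - 50.0) < 2 * se + 0.15  # + truncation margin

    def test_reproducibility(self):
        p = TonicParams(50.0, 4.0, rate_drift_cv=0.3)
        a = generate_tonic_train(p, 120.0, seed=42)
        b = generate_tonic_train(p, 120.0, seed=42)
        c = generate_tonic_train(p, 120.0, seed=43)
        assert np.array_equal(a.simple_spikes, b.simple_spikes)
        assert not np.array_equal(a.simple_spikes, c.simple_spikes)

    def test_refractory_floor(self):
        p = TonicParams(200.0, 1.2, t_ref_s=0.003)
        train = generate_tonic_train(p, 60.0, seed=3)
        assert np.min(np.diff(train.simple_spikes)) >= 0.003 - 1e-12

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mean_rate_hz=-5.0, shape_k=4.0),
            dict(mean_rate_hz=50.0, shape_k=0.8),
            dict(mean_rate_hz=50.0, shape_k=4.0, rate_drift_cv=1.5),
            dict(mean_rate_hz=50.0, shape_k=4.0, t_ref_s=0.05),
            dict(mean_rate_hz=50.0, shape_k=4.0, slow_state_frac=1.2),
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ParameterError):
            TonicParams(**kwargs)

    def test_degenerate_duration(self):
        with pytest.raises(ParameterError):
            generate_tonic_train(TonicParams(50.0, 4.0), 0.5, seed=0)


class TestBurstGenerator:
    PARAMS = BurstParams(
        intra_burst_rate_hz=200.0,
        burst_shape_kb=25.0,
        mean_burst_size=5.0,
        pause_mean_s=0.15,
        pause_shape_kp=2.0,
    )

    def test_mixture_moments_oracle(self):
        """Realized ISI mean/variance match the closed forms within 3%."""
        train = generate_burst_train(self.PARAMS, 4000.0, seed=4)
        isis = np.diff(train.simple_spikes)
        assert isis.size > 9e4
        mean, var = self.PARAMS.mixture_moments()
        assert isis.mean() == pytest.approx(mean, rel=0.03)
        assert isis.var(ddof=1) == pytest.approx(var, rel=0.03)

    def test_single_spike_limit_is_pause_renewal(self):
        """mean_burst_size=1 degenerates to isolated spikes between pauses."""
        p = BurstParams(
            intra_burst_rate_hz=200.0,
            burst_shape_kb=25.0,
            mean_burst_size=1.0,
            pause_mean_s=0.02,
            pause_shape_kp=4.0,
        )
        train = generate_burst_train(p, 2000.0, seed=5)
        isis = np.diff(train.simple_spikes)
        cv = isis.std(ddof=1) / isis.mean()
        assert cv == pytest.approx(0.5, rel=0.03)  # pause gamma CV = 1/sqrt(4)

    def test_reproducibility_and_refractory(self):
        a = generate_burst_train(self.PARAMS, 200.0, seed=6)
        b = generate_burst_train(self.PARAMS, 200.0, seed=6)
        assert np.array_equal(a.simple_spikes, b.simple_spikes)
        assert np.min(np.diff(a.simple_spikes)) >= self.PARAMS.t_ref_s - 1e-12

    def test_invalid_pause_shorter_than_burst_isi(self):
        with pytest.raises(ParameterError):
            BurstParams(
                intra_burst_rate_hz=100.0,
                burst_shape_kb=25.0,
                mean_burst_size=3.0,
                pause_mean_s=0.005,
                pause_shape_kp=2.0,
            )


class TestComplexSpikes:
    def test_zero_rate_identity(self, tonic_train_50hz):
        out = insert_complex_spikes(tonic_train_50hz, 0.0, 0.02, seed=0)
        assert out is tonic_train_50hz

    def test_thinning_expectation(self, tonic_train_50hz):
        """~300 CS at 1 Hz over 300 s; deletions ~ cs_count x pause x rate."""
        out = insert_complex_spikes(tonic_train_50hz, 1.0, 0.02, seed=8)
        n_cs = out.complex_spikes.size
        assert n_cs == pytest.approx(300, abs=60)
        deleted = tonic_train_50hz.n_simple - out.n_simple
        assert deleted == pytest.approx(n_cs * 0.02 * 50.0, rel=0.25)

    def test_pause_window_empty(self, tonic_train_50hz):
        out = insert_complex_spikes(tonic_train_50hz, 1.0, 0.015, seed=9)
        for t_cs in out.complex_spikes:
            in_window = (out.simple_spikes > t_cs) & (
                out.simple_spikes <= t_cs + 0.015
            )
            assert not in_window.any()


class TestInterpolation:
    @pytest.fixture(scope="class")
    def endpoints(self, presets):
        return (
            presets["tottering-baseline"].params,
            presets["tottering-attack"].params,
        )

    def test_attack_endpoint_exact(self, endpoints):
        base, attack = endpoints
        assert interpolate_regime(base, attack, 1.0) is attack

    def test_baseline_endpoint_stats_match(self, endpoints):
        base, attack = endpoints
        rb, cvb, pb = base.predicted_stats()
        r0, cv0, p0 = interpolate_regime(base, attack, 0.0).predicted_stats()
        assert r0 == pytest.approx(rb, rel=0.02)
        assert cv0 == pytest.approx(cvb, rel=0.02)
        assert p0 == pytest.approx(pb, rel=0.02)

    def test_cv_monotone_and_between(self, endpoints):
        base, attack = endpoints
        cvb = base.predicted_stats()[1]
        cva = attack.predicted_stats()[1]
        cvs = [
            interpolate_regime(base, attack, f).predicted_stats()[1]
            for f in (0.25, 0.5, 0.75)
        ]
        assert cvb < cvs[0] < cvs[1] < cvs[2] < cva

    def test_burst_size_and_rate_monotone(self, endpoints):
        base, attack = endpoints
        regs = [interpolate_regime(base, attack, f) for f in (0.1, 0.5, 0.9)]
        mus = [r.burst.mean_burst_size for r in regs]
        rbs = [r.burst.intra_burst_rate_hz for r in regs]
        assert mus == sorted(mus) and rbs == sorted(rbs)

    def test_severity_out_of_range(self, endpoints):
        base, attack = endpoints
        with pytest.raises(ParameterError):
            interpolate_regime(base, attack, 1.5)


class TestCohorts:
    def _graded_design(self, window=(0.0, 50.0), seed=11, n=6):
        from pkjburst.calibration import load_preset

        return CohortDesign(
            n_cells=n,
            n_mice=3,
            duration_s=300.0,
            regimes={
                "graded": GradedRegime(
                    load_preset("tottering-baseline").params,
                    load_preset("tottering-attack").params,
                    window_min=window,
                )
            },
            master_seed=seed,
        )

    def test_master_seed_determinism(self, presets):
        from pkjburst.behavior import DEFAULT_PROFILE

        d = self._graded_design()
        a = generate_cohort(d, DEFAULT_PROFILE)
        b = generate_cohort(d, DEFAULT_PROFILE)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta.simple_spikes, tb.simple_spikes)
            assert np.array_equal(ta.complex_spikes, tb.complex_spikes)
        assert a.ground_truth.equals(b.ground_truth)

    def test_pre_injection_cells_are_baseline(self):
        from pkjburst.behavior import DEFAULT_PROFILE

        d = self._graded_design(window=(-40.0, -10.0))
        ds = generate_cohort(d, DEFAULT_PROFILE)
        assert (ds.ground_truth["severity_frac"] == 0.0).all()

    def test_severity_rises_within_rising_phase(self):
        from pkjburst.behavior import DEFAULT_PROFILE

        d = self._graded_design(window=(0.0, 30.0), n=6)
        ds = generate_cohort(d, DEFAULT_PROFILE)
        frac = ds.ground_truth["severity_frac"].to_numpy()
        assert np.all(np.diff(frac) > 0)

    def test_design_validation(self):
        with pytest.raises(ParameterError):
            CohortDesign(n_cells=2, n_mice=3, duration_s=300.0, regimes={"x": None})
        with pytest.raises(ParameterError):
            CohortDesign(n_cells=5, n_mice=3, duration_s=100.0, regimes={"x": None})
        with pytest.raises(ParameterError):
            CohortDesign(n_cells=5, n_mice=3, duration_s=300.0, regimes={})


class TestSpikeTrainType:
    def test_time_shift_equivariance(self, tonic_train_50hz):
        shifted = tonic_train_50hz.shifted(1000.0)
        s0 = summarize_train(tonic_train_50hz)
        s1 = summarize_train(shifted)
        assert s1.mean_rate_hz == s0.mean_rate_hz
        # shifting loses a few ulps in the spike differences
        assert s1.isi_cv == pytest.approx(s0.isi_cv, rel=1e-9)
        assert s1.pfr_hz == s0.pfr_hz

    def test_event_bounds_and_order_enforced(self):
        with pytest.raises(ParameterError):
            SpikeTrain("c", "m", "x", 0.0, 10.0, np.array([1.0, 11.0]))
        with pytest.raises(ParameterError):
            SpikeTrain("c", "m", "x", 0.0, 10.0, np.array([2.0, 1.0]))
        with pytest.raises(ParameterError):
            SpikeTrain(
                "c", "m", "x", 0.0, 10.0,
                np.array([1.0, 2.0]), np.array([2.0]),
            )

    def test_regime_params_tagged_union(self):
        t = TonicParams(50.0, 4.0)
        with pytest.raises(ParameterError):
            RegimeParams(kind="tonic")
        with pytest.raises(ParameterError):
            RegimeParams(kind="burst", tonic=t)
        assert tonic_regime(t).params is t
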