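"""Tests for the bespoke rate-model statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vipcircuit import metrics
from vipcircuit.ratenet import CellClass, RateTrajectory, StimulusTrace


def make_trajectory(pyr_rates, dt_ms=1.0):
    """Wrap a (T, P) Pyr rate array into a RateTrajectory (other classes 0)."""
    pyr = np.asarray(pyr_rates, float)
    T, P = pyr.shape
    rates = np.zeros((T, P, 4))
    rates[:, :, CellClass.PYR.value] = pyr
    times = np.arange(T) * dt_ms
    return RateTrajectory(times, rates, np.zeros_like(rates))


class TestSnr:
    def test_equal_rates_give_unity(self):
        traj = make_trajectory(np.full((1000, 7), 8.0))
        assert metrics.snr(traj) == pytest.approx(1.0)

    def test_ratio_of_means(self):
        pyr = np.full((1000, 7), 4.0)
        pyr[:, 3] = 6.0
        assert metrics.snr(make_trajectory(pyr)) == pytest.approx(1.5)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(5)
        pyr = rng.uniform(1, 10, size=(1000, 7))
        a = metrics.snr(make_trajectory(pyr))
        b = metrics.snr(make_trajectory(3.7 * pyr))
        assert a == pytest.approx(b)

    def test_zero_denominator_flagged(self):
        pyr = np.zeros((1000, 7))
        pyr[:, 3] = 1.0
        with pytest.raises(ZeroDivisionError):
            metrics.snr(make_trajectory(pyr))

    def test_window_outside_trajectory(self):
        with pytest.raises(ValueError):
            metrics.snr(make_trajectory(np.ones((100, 7))), window=(500, 1000))


class TestRelativeChange:
    @pytest.mark.parametrize(
        "stim,base,expected", [(6.0, 4.0, 0.5), (4.0, 4.0, 0.0), (2.0, 4.0, -0.5)]
    )
    def test_definition(self, stim, base, expected):
        assert metrics.relative_change(stim, base) == pytest.approx(expected)

    def test_zero_baseline(self):
        with pytest.raises(ZeroDivisionError):
            metrics.relative_change(1.0, 0.0)


class TestCorrOrCov:
    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 50)
        r = metrics.corr_or_cov(x, x)
        assert r.mode == "correlation" and r.value == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.linspace(0, 1, 50)
        r = metrics.corr_or_cov(x, -x)
        assert r.mode == "correlation" and r.value == pytest.approx(-1.0)

    def test_quiescent_fallback_to_covariance(self):
        rng = np.random.default_rng(0)
        x = 1e-6 * rng.random(100)
        y = 1e-6 * rng.random(100)
        r = metrics.corr_or_cov(x, y)
        assert r.mode == "covariance"
        assert abs(r.value) < 1e-7

    def test_threshold_applied_to_absolute_covariance(self):
        x = np.array([0.0, 1.0] * 50)
        r = metrics.corr_or_cov(x, -1e-3 * x)
        assert r.mode == "correlation"  # |cov| = 2.5e-7 >= 1e-7

    def test_constant_series_falls_back_to_covariance(self):
        # a constant series has zero covariance with anything, so the
        # quiescent-regime rule applies rather than an undefined correlation
        x = np.linspace(0, 1, 50)
        r = metrics.corr_or_cov(x, np.full(50, 1e3))
        assert r.mode == "covariance" and r.value == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=80)
        y = rng.normal(size=80) + 0.5 * x
        r0 = metrics.corr_or_cov(x, y)
        r1 = metrics.corr_or_cov(a * x + b, y)
        if r0.mode == "correlation" and r1.mode == "correlation":
            assert r1.value == pytest.approx(r0.value, rel=1e-9)


class TestOscillationMeasures:
    def test_known_sinusoid_frequency(self):
        t = np.arange(0, 1000.0)
        pyr = 10.0 + 2.0 * np.sin(2 * np.pi * 22.0 * t / 1000.0)
        traj = make_trajectory(np.tile(pyr[:, None], (1, 7)))
        f = metrics.oscillation_frequency(traj, population=4, window=(0, 1000))
        assert f == pytest.approx(22.0, abs=1.0)

    def test_constant_trace_has_no_peak(self):
        traj = make_trajectory(np.full((1000, 7), 5.0))
        assert metrics.oscillation_frequency(traj, 4, (0, 1000)) is None

    def test_amplitude_of_known_sinusoid(self):
        t = np.arange(0, 1000.0)
        pyr = 10.0 + 1.5 * np.sin(2 * np.pi * 20.0 * t / 1000.0)
        traj = make_trajectory(np.tile(pyr[:, None], (1, 7)))
        amp = metrics.oscillation_amplitude(traj, 4, (0, 1000))
        assert amp == pytest.approx(3.0, rel=0.05)

    def test_amplitude_ignores_slow_ramp(self):
        t = np.arange(0, 500.0)
        pyr = 5.0 + 10.0 * (1 - np.exp(-t / 80.0))  # smooth release transient
        traj = make_trajectory(np.tile(pyr[:, None], (1, 7)))
        assert metrics.oscillation_amplitude(traj, 4, (0, 500)) < 0.6

    def test_short_window_rejected(self):
        traj = make_trajectory(np.ones((40, 7)))
        with pytest.raises(ValueError):
            metrics.oscillation_frequency(traj, 4, (0, 10))


class TestInputOutputCorrelations:
    def test_output_proportional_to_input_gives_unity(self):
        edges = np.arange(0.0, 1001.0, 50.0)
        cur = np.zeros((20, 7))
        cur[6:10, 0] = 0.5
        stim = StimulusTrace(edges, cur)
        times = np.arange(0, 1000.0)
        inputs = stim.at(times)  # (T, 7)
        rates = np.zeros((1000, 7, 4))
        rates[:, :, 0] = 2.0 + 3.0 * inputs
        traj = RateTrajectory(times, rates, np.zeros_like(rates), stim)
        cs = metrics.input_output_correlations(traj)
        assert cs[0].mode == "correlation"
        assert cs[0].value == pytest.approx(1.0)
        # an undriven, constant population falls back to covariance 0
        assert cs[5].mode == "covariance"
        assert cs[5].value == pytest.approx(0.0, abs=1e-12)


class TestSweepPlumbing:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            metrics.parameter_sweep("nonsense", [1.0])

    def test_unknown_metric_rejected(self):
        with pytest.raises(KeyError):
            metrics.parameter_sweep("ipps", [0.0], metric="nonsense")

    def test_stability_scan_grid_bounds(self):
        with pytest.raises(ValueError):
            metrics.stability_scan([0.0], [10.0])
        with pytest.raises(ValueError):
            metrics.stability_scan([10.0], [200.0])
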