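import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaphos.errors import (
    ArrhythmicError,
    InsufficientReplicatesError,
    ParameterError,
)
from circaphos.rhythm import (
    LuminescenceTrace,
    RhythmFit,
    compare_periods,
    detrend,
    estimate_period,
    estimate_phase,
    fit_harmonics,
)
from circaphos.synthdata import TraceParams, simulate_trace


def _trace(values, times=None):
    t = np.arange(len(values), dtype=float) if times is None else times
    return LuminescenceTrace(t, np.asarray(values, dtype=float))


def _cosine_trace(period=24.0, phase=0.0, amplitude=300.0, baseline=0.0,
                  slope=0.0, duration=120.0):
    t = np.arange(0.0, duration + 0.5, 1.0)
    y = baseline + slope * t + amplitude * np.cos(2 * np.pi * (t - phase) / period)
    return LuminescenceTrace(t, y)


class TestDetrend:
    def test_constant_trace_becomes_zero(self):
        out = detrend(_trace(np.full(24, 7.0)))
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_pure_line_becomes_zero(self):
        t = np.arange(30.0)
        out = detrend(_trace(3.0 + 0.5 * t, t))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_cosine_plus_line_recovers_cosine(self):
        t = np.arange(0.0, 120.5, 1.0)
        cos = 100.0 * np.cos(2 * np.pi * t / 24.0)
        out = detrend(LuminescenceTrace(t, cos + 50.0 + 2.0 * t))
        r = np.corrcoef(out.values, cos)[0, 1]
        assert r > 0.999

    def test_none_is_identity(self):
        tr = _cosine_trace()
        out = detrend(tr, method="none")
        assert np.array_equal(out.values, tr.values)


class TestFitHarmonics:
    def test_noiseless_cosine_at_true_period(self):
        tr = _cosine_trace(period=24.0, amplitude=250.0)
        coef, rss = fit_harmonics(tr, 24.0, n_harmonics=1)
        assert rss == pytest.approx(0.0, abs=1e-12)
        assert coef[1] == pytest.approx(250.0)  # cosine coefficient

    def test_rss_larger_at_wrong_period(self):
        tr = _cosine_trace(period=24.0)
        _, rss_true = fit_harmonics(tr, 24.0)
        _, rss_wrong = fit_harmonics(tr, 30.0)
        assert rss_wrong > rss_true

    def test_rss_bounded_by_total_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=121)
        tr = _trace(y)
        for T in (18.0, 24.0, 32.0):
            _, rss = fit_harmonics(tr, T)
            assert rss <= y.size * y.var() + 1e-9

    def test_too_many_coefficients_rejected(self):
        tr = _trace(np.arange(16.0))
        with pytest.raises(ParameterError):
            fit_harmonics(tr, 24.0, n_harmonics=10)


class TestEstimatePeriod:
    def test_recovers_24h_period_and_phase(self):
        p = TraceParams(noise_sd=0.0, period=24.0, phase=6.0, damping_rate=0.0)
        fit = estimate_period(simulate_trace(p, 0))
        assert fit.period == pytest.approx(24.0, abs=0.05)
        assert fit.phase == pytest.approx(6.0, abs=0.1)
        assert fit.rhythmic_flag

    def test_recovers_long_period(self):
        # 24 h plus the largest pharmacological lengthening of interest
        p = TraceParams(noise_sd=0.0, period=31.7, phase=3.0, damping_rate=0.0)
        fit = estimate_period(simulate_trace(p, 0))
        assert fit.period == pytest.approx(31.7, abs=0.1)

    def test_constant_trace_is_arrhythmic_not_error(self):
        fit = estimate_period(_trace(np.full(120, 42.0)))
        assert not fit.rhythmic_flag
        assert np.isnan(fit.period) or fit.amplitude == 0.0

    def test_white_noise_is_arrhythmic(self):
        rng = np.random.default_rng(5)
        fit = estimate_period(_trace(rng.normal(1000.0, 50.0, size=121)))
        assert not fit.rhythmic_flag

    @pytest.mark.parametrize("true_T", [20.0, 24.0, 28.0, 32.0])
    def test_noiseless_damped_recovery_across_window(self, true_T):
        p = TraceParams(noise_sd=0.0, period=true_T, phase=6.0,
                        damping_rate=0.01, duration=max(120.0, 2 * true_T))
        fit = estimate_period(simulate_trace(p, 0))
        assert fit.period == pytest.approx(true_T, abs=0.1)  # 2x grid step

    def test_invariance_to_offset_and_scale(self):
        p = TraceParams(noise_sd=40.0, period=26.0, phase=4.0)
        tr = simulate_trace(p, 8)
        ref = estimate_period(tr).period
        shifted = LuminescenceTrace(tr.times, 3.7 * tr.values + 5000.0)
        # agreement to the optimiser's period tolerance
        assert estimate_period(shifted).period == pytest.approx(ref, abs=5e-3)

    def test_time_reversed_cosine_same_period(self):
        tr = _cosine_trace(period=26.0, phase=5.0)
        rev = LuminescenceTrace(tr.times, tr.values[::-1].copy())
        a = estimate_period(tr).period
        b = estimate_period(rev).period
        assert a == pytest.approx(b, abs=0.1)

    def test_monte_carlo_recovery_noisy(self):
        # noise at 20% of amplitude; mean estimate within 0.1 h of truth
        ests = []
        for s in range(60):
            p = TraceParams(noise_sd=60.0, amplitude=300.0, period=24.0,
                            phase=6.0)
            ests.append(estimate_period(simulate_trace(p, 20_000 + s)).period)
        ests = np.array(ests)
        assert abs(ests.mean() - 24.0) < 0.1
        assert ests.std() < 0.5

    def test_burn_in_discards_transient(self):
        p = TraceParams(noise_sd=0.0, period=24.0, phase=6.0, duration=144.0)
        tr = simulate_trace(p, 0)
        spiked = tr.values.copy()
        spiked[:10] += 5000.0  # release transient
        fit = estimate_period(LuminescenceTrace(tr.times, spiked), burn_in=24.0)
        assert fit.period == pytest.approx(24.0, abs=0.1)


class TestEstimatePhase:
    def test_peak_at_zero(self):
        fit = estimate_period(_cosine_trace(phase=0.0))
        assert min(estimate_phase(fit), fit.period - estimate_phase(fit)) < 0.05

    def test_shifted_by_six_hours(self):
        fit = estimate_period(_cosine_trace(phase=6.0))
        assert estimate_phase(fit) == pytest.approx(6.0, abs=0.1)

    def test_wrap_invariance_full_period_shift(self):
        f1 = estimate_period(_cosine_trace(phase=5.0))
        f2 = estimate_period(_cosine_trace(phase=5.0 + 24.0))
        assert estimate_phase(f1) == pytest.approx(estimate_phase(f2), abs=0.05)

    def test_reference_subtracted(self):
        fit = estimate_period(_cosine_trace(phase=6.0))
        assert estimate_phase(fit, reference=2.0) == pytest.approx(4.0, abs=0.1)

    def test_arrhythmic_fit_raises(self):
        fit = estimate_period(_trace(np.full(120, 1.0)))
        with pytest.raises(ArrhythmicError):
            estimate_phase(fit)


def _fit(period):
    return RhythmFit(period, 0.0, 100.0, np.zeros(7), 0.0, True, 3)


class TestComparePeriods:
    def test_identical_groups(self):
        g = [_fit(24.0 + 0.1 * i) for i in range(4)]
        cmp = compare_periods(g, list(g))
        assert cmp.mean_difference == 0.0
        assert cmp.p_value == pytest.approx(1.0)

    def test_zero_variance_policy(self):
        a = [_fit(24.0)] * 4
        b = [_fit(26.0)] * 4
        cmp = compare_periods(a, b)
        assert cmp.mean_difference == pytest.approx(2.0)
        assert np.isnan(cmp.p_value)  # undefined under zero variance

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = [_fit(x) for x in rng.normal(24, 0.3, 6)]
        b = [_fit(x) for x in rng.normal(26, 0.3, 6)]
        ab = compare_periods(a, b)
        ba = compare_periods(b, a)
        assert ab.mean_difference == pytest.approx(-ba.mean_difference)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.p_value < 0.001

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            compare_periods([_fit(24.0)], [_fit(25.0), _fit(25.1)])

    def test_type_i_error_calibration(self):
        # null simulation: rejection rate at alpha=0.05 near nominal
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 4000
        for _ in range(n_sim):
            a = [_fit(x) for x in rng.normal(24.0, 0.5, 8)]
            b = [_fit(x) for x in rng.normal(24.0, 0.5, 8)]
            if compare_periods(a, b).p_value < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_sim <= 0.06


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    offset=st.floats(-1e4, 1e4),
    scale=st.floats(0.01, 100.0),
    period=st.floats(20.0, 30.0),
)
def test_period_invariant_under_affine_rescaling(offset, scale, period):
    """Period estimates ignore units and baseline of the reporter signal."""
    t = np.arange(0.0, 120.5, 1.0)
    y = 200.0 * np.cos(2 * np.pi * t / period) + 1000.0
    ref = estimate_period(LuminescenceTrace(t, y)).period
    est = estimate_period(LuminescenceTrace(t, scale * y + offset)).period
    assert est == pytest.approx(ref, abs=5e-3)
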