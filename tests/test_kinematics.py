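import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import limbkine as lk
from limbkine.kinematics import _variability

from conftest import make_recording


def raised_cosine_recording(amplitude, period, n_cycles=6, sample_rate=100.0):
    """Recording that is a pure raised-cosine tapping signal with cycle
    boundaries exactly on the sample grid, plus the matching events."""
    n = int(round(n_cycles * period * sample_rate)) + 1
    pad = int(round(2.0 * sample_rate))
    t = np.arange(n + 2 * pad) / sample_rate
    t0 = pad / sample_rate
    pitch = -amplitude * (1 - np.cos(2 * np.pi * (t - t0) / period)) / 2
    pitch[t < t0] = 0.0
    pitch[t > t0 + n_cycles * period + 1e-9] = 0.0
    rec = make_recording(pitch=pitch, sample_rate=sample_rate)
    events = [
        lk.CycleEvent(
            t_start=t0 + k * period, t_end=t0 + (k + 1) * period,
            t_up=t0 + (k + 0.5) * period,
            value_start=0.0, value_up=-amplitude,
        )
        for k in range(n_cycles)
    ]
    return rec, events


class TestCycleFrequency:
    @pytest.mark.parametrize("duration,expected", [(1.0, 1.0), (0.357, 2.80)])
    def test_reciprocal_duration(self, duration, expected):
        e = lk.CycleEvent(t_start=0.0, t_end=duration)
        assert lk.cycle_frequency(e) == pytest.approx(expected, abs=0.005)

    def test_frequency_times_duration_is_one(self, la_noiseless_trial):
        rec, _ = la_noiseless_trial
        for e in lk.detect_la_cycles(rec):
            assert abs(lk.cycle_frequency(e) * e.duration - 1.0) < 1e-12

    def test_la_fixture_frequencies_near_configured_rate(self, la_noiseless_trial):
        rec, _ = la_noiseless_trial
        freqs = [lk.cycle_frequency(e) for e in lk.detect_la_cycles(rec)]
        # 1-sample quantization of a 2.6 Hz cycle moves 1/T by ~0.07 Hz
        assert np.all(np.abs(np.array(freqs) - 2.6) < 0.08)


class TestCycleAngle:
    def test_definition(self):
        e = lk.CycleEvent(t_start=0, t_end=0.4, t_up=0.2,
                          value_start=0.0, value_up=-16.0)
        assert lk.cycle_angle(e) == 16.0

    def test_missing_t_up_rejected(self):
        with pytest.raises(ValueError):
            lk.cycle_angle(lk.CycleEvent(t_start=0, t_end=0.4))

    def test_noiseless_fixture_recovers_true_amplitude(self):
        params = lk.TTGenParams().noiseless(angle_slope=0.0)
        rec, gt = lk.generate_tt_trial(params, seed=0)
        cs = lk.detect_tt_cycles(rec)
        angles = np.array([lk.cycle_angle(e) for e in cs])
        # sampling quantization keeps the measured excursion within 0.05 deg
        assert np.all(np.abs(angles - 17.41) < 0.05)


class TestDimensionlessJerk:
    @pytest.mark.parametrize("amplitude,period", [
        (16.0, 0.36), (5.0, 0.36), (16.0, 0.5), (30.0, 0.25), (8.0, 0.4),
    ])
    def test_raised_cosine_closed_form(self, amplitude, period):
        """DLJ of a raised-cosine cycle is (2 pi)^6 / 8 for any A, T."""
        rec, events = raised_cosine_recording(amplitude, period)
        for e in events[1:-1]:
            dlj = lk.cycle_dlj(e, rec)
            assert dlj == pytest.approx(lk.RAISED_COSINE_DLJ, rel=0.01)

    @given(scale_t=st.floats(0.75, 2.0), scale_a=st.floats(0.3, 3.0))
    def test_scale_invariance(self, scale_t, scale_a):
        """Rescaling time and amplitude together leaves DLJ unchanged
        (periods kept within the physiological tapping range, where 100-Hz
        discretization error is well below 0.1%)."""
        base_rec, base_events = raised_cosine_recording(10.0, 0.4)
        rec, events = raised_cosine_recording(10.0 * scale_a, 0.4 * scale_t)
        d0 = lk.cycle_dlj(base_events[2], base_rec)
        d1 = lk.cycle_dlj(events[2], rec)
        assert d1 == pytest.approx(d0, rel=1e-3)

    def test_too_short_cycle_is_missing(self):
        rec, events = raised_cosine_recording(10.0, 0.4)
        e = lk.CycleEvent(t_start=events[0].t_start,
                          t_end=events[0].t_start + 0.04,
                          t_up=events[0].t_start + 0.02,
                          value_start=0.0, value_up=-1.0)
        assert np.isnan(lk.cycle_dlj(e, rec))


class TestLogDimensionlessJerk:
    def test_matches_log(self):
        assert lk.cycle_ldlj(1.0) == 0.0
        assert lk.cycle_ldlj(7061.9) == pytest.approx(np.log(7061.9))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lk.cycle_ldlj(0.0)

    def test_median_commutes_with_log(self):
        """ln is monotonic, so median(LDLJ) = ln(median(DLJ))."""
        rng = np.random.default_rng(1)
        dlj = rng.lognormal(8.8, 1.0, size=101)
        assert np.median(np.log(dlj)) == pytest.approx(np.log(np.median(dlj)))


class TestVerticalAcceleration:
    def test_flat_segment_returns_baseline(self):
        rec = make_recording(acc_z=np.full(2000, 9.81), task="LA")
        e = lk.CycleEvent(t_start=1.0, t_end=1.4)
        assert lk.cycle_max_vert_acc(e, rec) == pytest.approx(9.81)

    def test_noiseless_pulse_height_recovered(self, la_noiseless_trial):
        rec, gt = la_noiseless_trial
        cs = lk.detect_la_cycles(rec)
        vals = [lk.cycle_max_vert_acc(e, rec) for e in cs]
        # grid sampling of the 20-ms pulse can shave a few percent
        assert np.median(vals) == pytest.approx(123.0, abs=4.0)


class TestIAV:
    def test_zero_free_acceleration(self):
        rec = make_recording(acc_z=np.full(2000, 9.81), task="LA")
        e = lk.CycleEvent(t_start=1.0, t_end=1.4)
        assert lk.cycle_iav(e, rec) == pytest.approx(0.0, abs=1e-9)

    def test_constant_free_magnitude(self):
        """|free acc| = 16 m/s^2 over a 0.385-s cycle integrates to 6.16."""
        acc = np.zeros((2000, 3))
        acc[:, 2] = 9.81
        # free acceleration only inside the cycle, so the per-trial static
        # median stays (0, 0, 9.81)
        acc[500:539, 0] = 16.0
        rec = make_recording(acc_z=np.zeros(2000), task="LA")
        rec = rec.replace(acc=acc)
        e = lk.CycleEvent(t_start=5.0, t_end=5.385)
        assert lk.cycle_iav(e, rec) == pytest.approx(16.0 * 0.385, rel=0.02)

    def test_unknown_gravity_mode_rejected(self):
        rec = make_recording(task="LA")
        with pytest.raises(ValueError):
            lk.cycle_iav(lk.CycleEvent(0.0, 0.4), rec, gravity_mode="bogus")


class TestTrialFeatures:
    def test_identical_cycles_have_zero_variability(self):
        rec, events = raised_cosine_recording(16.0, 0.4, n_cycles=10)
        cs = lk.CycleSet(events=tuple(events), signal_kind="pitch",
                         task="TT", participant_id="T01", leg="right",
                         trial_index=1)
        tf = lk.trial_features(rec, cs, window=(0.0, rec.duration))
        assert tf.n_taps == 10
        assert tf.variability["frequency"] == pytest.approx(0.0, abs=1e-9)
        assert tf.variability["angle"] == pytest.approx(0.0, abs=1e-9)

    def test_variability_formula(self):
        """Spread {2.5, 2.8, 3.0} -> 100 * 0.5 / 2.8 = 17.9%."""
        assert _variability(np.array([2.5, 2.8, 3.0])) == pytest.approx(
            100 * 0.5 / 2.8)

    def test_empty_window_yields_missing_features(self, tt_noiseless_trial):
        rec, _ = tt_noiseless_trial
        cs = lk.detect_tt_cycles(rec)
        tf = lk.trial_features(rec, cs, window=(19.9, 19.95))
        assert tf.n_taps == 0
        assert all(np.isnan(v) for v in tf.medians.values())

    def test_default_trial_tap_count(self):
        rec, _ = lk.generate_tt_trial(lk.TTGenParams(), seed=4)
        cs = lk.detect_tt_cycles(rec)
        tf = lk.trial_features(rec, cs)
        assert tf.n_taps in (27, 28, 29)
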