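"""Trace quantification rules: contraction, rate, fluorescence, force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optocontract.errors import (
    DegenerateInputError,
    FitFailureError,
    UndefinedRatioError,
    UsageError,
)
from optocontract.flowcore import MotionTrace
from optocontract.synthdata import gen_beats
from optocontract.traces import (
    BeatSeries,
    EventAmplitudes,
    StimulusEvent,
    StimulusProtocol,
    contractility_change,
    decay_half_time,
    detect_contractions,
    dff0,
    eb_response,
    flag_extrasystoles,
    force_response,
    frequency_timecourse,
    girk_modulation,
    heart_rate_increase,
    melanopsin_change,
)


def _pacing_protocol(n, period=1.0, light_at=None):
    events = [StimulusEvent(t_on=k * period, duration=0.002, kind="pacing") for k in range(n)]
    if light_at is not None:
        events.append(
            StimulusEvent(t_on=light_at, duration=0.1, kind="light", wavelength_nm=385)
        )
    return StimulusProtocol(events)


def _bump_trace(pacing_times, amps, fs=100.0, t_end=None, width=0.05):
    t_end = t_end or (max(pacing_times) + 1.0)
    t = np.arange(1, int(t_end * fs) + 1) / fs
    v = np.zeros_like(t)
    for pt, a in zip(pacing_times, amps):
        v += a * np.exp(-((t - pt - 0.15) ** 2) / (2 * width**2))
    return MotionTrace(t=t, v=v)


class TestDetectContractions:
    def test_flat_trace_zero_amplitudes(self):
        trace = MotionTrace(t=np.arange(1, 301) / 100, v=np.zeros(300))
        events = detect_contractions(trace, _pacing_protocol(3))
        assert len(events) == 3
        assert all(e.amplitude == 0 for e in events)

    def test_recovers_bump_amplitudes(self):
        times = [0.0, 1.0, 2.0, 3.0]
        trace = _bump_trace(times, [2.0] * 4, t_end=4.0)
        events = detect_contractions(trace, _pacing_protocol(4))
        assert len(events) == 4
        assert np.allclose([e.amplitude for e in events], 2.0, atol=0.05)

    def test_missing_bump_detected_as_zero(self):
        times = [0.0, 1.0, 2.0, 3.0]
        trace = _bump_trace(times, [2.0, 2.0, 0.0, 2.0], t_end=4.0)
        amps = [e.amplitude for e in detect_contractions(trace, _pacing_protocol(4))]
        assert amps[2] < 0.1 and min(amps[0], amps[1], amps[3]) > 1.9

    def test_no_pacing_raises(self):
        trace = _bump_trace([0.0], [1.0])
        with pytest.raises(UsageError):
            detect_contractions(trace, StimulusProtocol([]))

    def test_short_trace_raises(self):
        trace = MotionTrace(t=np.arange(1, 21) / 100, v=np.zeros(20))
        with pytest.raises(DegenerateInputError):
            detect_contractions(trace, _pacing_protocol(3))


class TestContractilityChange:
    def _events(self, pre, post, t_light=5.0):
        evs = [EventAmplitudes(t_peak=0.5 + k, amplitude=a) for k, a in enumerate(pre)]
        evs += [
            EventAmplitudes(t_peak=t_light + 0.5 + k, amplitude=a)
            for k, a in enumerate(post)
        ]
        return evs

    def test_no_change_is_zero(self):
        light = StimulusEvent(t_on=5.0, duration=0.1)
        evs = self._events([2.0] * 5, [2.0] * 5)
        assert contractility_change(evs, light) == 0.0

    def test_fifty_percent_increase(self):
        light = StimulusEvent(t_on=5.0, duration=0.1)
        evs = self._events([2.0] * 5, [3.0] * 5)
        assert contractility_change(evs, light) == pytest.approx(50.0)

    def test_scaled_post_amplitudes(self):
        rng = np.random.default_rng(1)
        pre = 2.0 + 0.05 * rng.standard_normal(5)
        light = StimulusEvent(t_on=5.0, duration=0.1)
        evs = self._events(pre, pre * 1.3)
        assert contractility_change(evs, light) == pytest.approx(30.0, abs=0.5)

    def test_zero_pre_mean_raises(self):
        light = StimulusEvent(t_on=5.0, duration=0.1)
        evs = self._events([0.0] * 5, [1.0] * 5)
        with pytest.raises(UndefinedRatioError):
            contractility_change(evs, light)


class TestFrequencyTimecourse:
    def test_constant_rate(self):
        beats = BeatSeries(np.arange(20) * 0.5)
        t, bpm = frequency_timecourse(beats)
        assert len(bpm) == 19
        assert np.allclose(bpm, 120.0)

    def test_ramp_is_monotone(self):
        rr = np.linspace(1.0, 0.5, 30)
        beats = BeatSeries(np.concatenate([[0.0], np.cumsum(rr)]))
        _, bpm = frequency_timecourse(beats)
        assert np.all(np.diff(bpm) > 0)

    def test_time_dilation_covariance(self):
        times = np.cumsum(np.abs(np.random.default_rng(0).normal(0.5, 0.05, 30)))
        _, bpm = frequency_timecourse(BeatSeries(times))
        _, bpm_k = frequency_timecourse(BeatSeries(times * 2.0))
        assert np.allclose(bpm_k, bpm / 2.0)

    def test_too_few_beats(self):
        with pytest.raises(DegenerateInputError):
            frequency_timecourse(BeatSeries(np.array([0.0])))


class TestEbResponse:
    def test_step_increase(self):
        # 60 bpm baseline; plateau of 96 bpm (RR 0.625 s, binary-exact)
        # starting 5 s after light onset at t = 40 s
        pre = np.arange(0, 46, 1.0)
        post = 45.0 + 0.625 * np.arange(1, 25)
        beats = BeatSeries(np.concatenate([pre, post]))
        res = eb_response(beats, StimulusEvent(t_on=40.0, duration=5.0))
        assert res["max_frequency_increase"] == pytest.approx(36.0)
        assert res["time_to_peak"] == pytest.approx(5.625)

    def test_no_change_zero_increase(self):
        beats = BeatSeries(np.arange(0, 80, 0.5))
        res = eb_response(beats, StimulusEvent(t_on=40.0, duration=5.0))
        assert res["max_frequency_increase"] == pytest.approx(0.0)
        assert res["time_to_peak"] >= 0

    def test_fast_step_peaks_before_slow_ramp(self):
        step, _ = gen_beats(base_rate_bpm=60, delta_bpm=30, t_light_s=60, tau_s=1.0,
                            duration_s=120, seed=0)
        ramp, _ = gen_beats(base_rate_bpm=60, delta_bpm=30, t_light_s=60, tau_s=25.0,
                            duration_s=120, seed=0)
        ev = StimulusEvent(t_on=60.0, duration=5.0)
        assert eb_response(step, ev)["time_to_peak"] < eb_response(ramp, ev)["time_to_peak"]


class TestFlagExtrasystoles:
    def test_regular_series_unflagged(self):
        flagged = flag_extrasystoles(BeatSeries(np.arange(30) * 0.2))
        assert not flagged.flags.any()

    def test_premature_beat_flagged(self):
        times = list(np.arange(10) * 0.2)
        times.insert(5, times[4] + 0.5 * 0.2)  # RR at 50% of the local median
        flagged = flag_extrasystoles(BeatSeries(np.array(times)))
        assert flagged.flags[5]
        assert flagged.flags.sum() == 1

    def test_small_jitter_unflagged(self):
        rng = np.random.default_rng(2)
        rr = 0.2 * (1 + 0.05 * rng.uniform(-1, 1, 40))
        flagged = flag_extrasystoles(BeatSeries(np.concatenate([[0], np.cumsum(rr)])))
        assert not flagged.flags.any()

    def test_idempotent(self):
        times = list(np.arange(10) * 0.2)
        times.insert(5, times[4] + 0.1)
        once = flag_extrasystoles(BeatSeries(np.array(times)))
        twice = flag_extrasystoles(once)
        assert np.array_equal(once.flags, twice.flags)


class TestHeartRateIncrease:
    def test_constant_rate_zero(self):
        beats = BeatSeries(np.arange(40) * 0.2)
        assert heart_rate_increase(beats, StimulusEvent(t_on=4.0, duration=1.0)) == \
            pytest.approx(0.0)

    def test_twenty_five_percent(self):
        pre = np.arange(10) * 0.2
        post = pre[-1] + np.cumsum([0.16] * 12)
        beats = BeatSeries(np.concatenate([pre, post]))
        res = heart_rate_increase(beats, StimulusEvent(t_on=1.9, duration=1.0))
        assert res == pytest.approx(25.0, abs=0.5)

    def test_invariant_to_flagged_extrasystoles(self):
        pre = np.arange(10) * 0.2
        post = pre[-1] + np.cumsum([0.16] * 12)
        clean = np.concatenate([pre, post])
        ev = StimulusEvent(t_on=1.9, duration=1.0)
        base = heart_rate_increase(BeatSeries(clean), ev)
        # inject two premature beats inside the post window
        times = sorted(list(clean) + [post[2] + 0.05, post[5] + 0.06])
        flags = np.isin(times, [post[2] + 0.05, post[5] + 0.06])
        noisy = BeatSeries(np.array(times), flags)
        assert heart_rate_increase(noisy, ev) == pytest.approx(base)

    def test_insufficient_beats_raise(self):
        with pytest.raises(DegenerateInputError):
            heart_rate_increase(
                BeatSeries(np.arange(5) * 0.2), StimulusEvent(t_on=0.5, duration=1.0)
            )


class TestMelanopsinChange:
    def test_no_change_zero(self):
        beats = BeatSeries(np.arange(0, 120, 0.5))
        assert melanopsin_change(beats, StimulusEvent(t_on=60.0, duration=1.0)) == \
            pytest.approx(0.0)

    def test_bradycardia_is_negative(self):
        series, truth = gen_beats(
            base_rate_bpm=360, delta_bpm=-36, t_light_s=60, tau_s=3.0,
            duration_s=120, seed=0
        )
        change = melanopsin_change(series, StimulusEvent(t_on=60.0, duration=1.0))
        assert change == pytest.approx(-10.0, abs=2.0)


class TestGirkAndDff0:
    def test_girk_trivials(self):
        assert girk_modulation(-100.0, -100.0) == 1.0
        assert girk_modulation(-50.0, -100.0) == 0.5
        with pytest.raises(UndefinedRatioError):
            girk_modulation(-50.0, 0.0)

    def test_dff0_constant_trace(self):
        assert np.allclose(dff0(np.full(50, 100.0)), 0.0)

    def test_dff0_peak_arithmetic(self):
        F = np.full(50, 100.0)
        F[25] = 150.0
        assert dff0(F).max() == pytest.approx(0.5)
        # with background: F0_raw=150, bg=50, peak_raw=250 -> peak 1.0
        F = np.full(50, 150.0)
        F[25] = 250.0
        assert dff0(F, background=50.0).max() == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(gain=st.floats(0.1, 10.0))
    def test_dff0_gain_invariance(self, gain):
        rng = np.random.default_rng(0)
        F = 100 + np.abs(rng.standard_normal(40)) * 10
        ref = dff0(F, background=20.0)
        assert np.allclose(dff0(gain * F, background=gain * 20.0), ref)

    def test_dff0_nonpositive_f0_raises(self):
        with pytest.raises(UndefinedRatioError):
            dff0(np.full(20, 10.0), background=10.0)


class TestDecayHalfTime:
    def test_exact_exponential(self):
        t = np.linspace(0, 60, 200)
        y = np.exp(-t / 10.0)
        assert decay_half_time(t, y, t_event=0.0) == pytest.approx(6.93, abs=0.01)

    def test_noisy_tau_sweep(self):
        """ln(2)*tau recovered within 5% at 1% noise across tau in [5, 100] s."""
        rng = np.random.default_rng(0)
        for tau in [5.0, 20.0, 100.0]:
            t = np.linspace(0, 3 * tau, 80)
            y = np.exp(-t / tau) + 0.01 * rng.standard_normal(t.size)
            est = decay_half_time(t, y, t_event=0.0)
            assert est == pytest.approx(np.log(2) * tau, rel=0.05)

    def test_flat_trace_fails(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(FitFailureError):
            decay_half_time(t, np.ones_like(t), t_event=0.0)

    def test_linear_option(self):
        t = np.linspace(0, 10, 50)
        y = 100.0 - 5.0 * t
        assert decay_half_time(t, y, t_event=0.0, method="linear") == pytest.approx(10.0)


class TestForceResponse:
    def _triangle(self, peak_at, peak=5.0, baseline=1.0, t_end=40.0, fs=20.0):
        t = np.arange(0, t_end, 1 / fs)
        y = np.full_like(t, baseline)
        y += np.maximum(0, (peak - baseline) * (1 - np.abs(t - peak_at) / 1.0))
        return t, y

    def test_flat_trace_zero(self):
        t = np.arange(0, 40, 0.05)
        stim = StimulusEvent(t_on=10.0, duration=2.0)
        assert force_response(t, np.ones_like(t), stim) == pytest.approx(0.0)

    def test_triangular_peak_minus_baseline(self):
        t, y = self._triangle(peak_at=11.0)
        stim = StimulusEvent(t_on=10.0, duration=2.0)
        assert force_response(t, y, stim) == pytest.approx(4.0, abs=0.05)

    def test_post_window_edge_rule(self):
        stim = StimulusEvent(t_on=10.0, duration=2.0)  # window ends at 22 s
        t, y = self._triangle(peak_at=21.0)  # t_off + 9 s: counted
        assert force_response(t, y, stim) == pytest.approx(4.0, abs=0.05)
        t, y = self._triangle(peak_at=23.0)  # t_off + 11 s: not counted
        assert force_response(t, y, stim) < 1.0

    def test_bath_kind_max_difference(self):
        t = np.arange(0, 60, 0.05)
        y = np.where(t < 30, 2.0, 7.0)
        stim = StimulusEvent(t_on=30.0, duration=0.0, kind="drug")
        assert force_response(t, y, stim, kind="bath") == pytest.approx(5.0)

    def test_window_outside_trace_raises(self):
        t = np.arange(0, 5, 0.05)
        with pytest.raises(DegenerateInputError):
            force_response(t, np.ones_like(t), StimulusEvent(t_on=4.0, duration=2.0))
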