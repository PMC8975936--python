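"""Quantification rules for motion, force, fluorescence, beat and current traces.

Covers the readouts used around optogenetic Gq stimulation experiments:
contraction amplitudes during pacing and their light-induced change, beat-rate
responses of spontaneously beating preparations (with premature-beat
exclusion), RR-interval analysis for inhibitory receptors, GIRK current
ratios, ΔF/F0 normalization, luminescence decay half-times, and isometric
force response windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateInputError,
    FitFailureError,
    UndefinedRatioError,
    UsageError,
    ValidationError,
)
from .flowcore import MotionTrace

__all__ = [
    "StimulusEvent",
    "StimulusProtocol",
    "BeatSeries",
    "EventAmplitudes",
    "detect_contractions",
    "contractility_change",
    "frequency_timecourse",
    "eb_response",
    "heart_rate_increase",
    "flag_extrasystoles",
    "melanopsin_change",
    "girk_modulation",
    "dff0",
    "decay_half_time",
    "force_response",
    "beat_frequency",
]


@dataclass
class StimulusEvent:
    """One timed stimulus: pacing pulse, light flash, drug application or EFS."""

    t_on: float
    duration: float
    kind: str = "light"
    wavelength_nm: float | None = None
    intensity_uw_mm2: float | None = None
    label: str | None = None

    def __post_init__(self):
        if self.duration < 0:
            raise ValidationError("event duration must be >= 0")
        if self.intensity_uw_mm2 is not None and self.intensity_uw_mm2 < 0:
            raise ValidationError("intensity must be >= 0")
        if self.kind not in ("pacing", "light", "drug", "EFS"):
            raise ValidationError(f"unknown event kind {self.kind!r}")

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration


@dataclass
class StimulusProtocol:
    """Time-sorted list of stimulus events."""

    events: list[StimulusEvent]

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.t_on)

    def of_kind(self, kind: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.kind == kind]


@dataclass
class BeatSeries:
    """Strictly increasing beat times with per-beat sinus/premature labels."""

    beat_times: np.ndarray
    flags: np.ndarray | None = None  # True = premature

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1:
            raise ValidationError("beat_times must be 1D")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat_times must be strictly increasing")
        if self.flags is None:
            self.flags = np.zeros(self.beat_times.shape, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.beat_times.shape:
                raise ValidationError("flags must match beat_times in length")

    @property
    def rr(self) -> np.ndarray:
        return np.diff(self.beat_times)

    def sinus(self) -> "BeatSeries":
        """Beats with premature-flagged ones removed."""
        keep = ~self.flags
        if keep.sum() < 2:
            raise DegenerateInputError("fewer than 2 sinus beats")
        return BeatSeries(self.beat_times[keep], np.zeros(int(keep.sum()), bool))


@dataclass
class EventAmplitudes:
    """Amplitude of one contraction event after baseline subtraction."""

    t_peak: float
    amplitude: float
    cycle_index: int | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValidationError("amplitudes must be >= 0 after baseline subtraction")


def detect_contractions(
    trace: MotionTrace,
    protocol: StimulusProtocol,
    baseline_window_s: float = 0.2,
) -> list[EventAmplitudes]:
    """One contraction amplitude per pacing cycle of a motion trace.

    The amplitude of cycle *i* is the peak |V| between pacing pulses *i* and
    *i+1*, minus a per-cycle baseline taken as the 10th percentile of |V| in
    the ``baseline_window_s`` before the pacing pulse (robust to slow drift).
    Negative differences are clipped to zero.
    """
    pacing = protocol.of_kind("pacing")
    if not pacing:
        raise UsageError("protocol contains no pacing events")
    t, v = trace.t, trace.v
    if len(pacing) >= 2:
        period = pacing[1].t_on - pacing[0].t_on
    else:
        period = t[-1] - pacing[0].t_on
    if t[-1] - t[0] < period:
        raise DegenerateInputError("trace shorter than one pacing cycle")

    events: list[EventAmplitudes] = []
    for i, ev in enumerate(pacing):
        t0, t1 = ev.t_on, ev.t_on + period
        if t1 > t[-1] + 1e-9:
            break  # cycle not fully covered
        in_cycle = (t >= t0) & (t < t1)
        if not in_cycle.any():
            continue
        pre = (t >= t0 - baseline_window_s) & (t < t0)
        baseline = float(np.percentile(v[pre], 10)) if pre.any() else 0.0
        idx = np.flatnonzero(in_cycle)
        k = idx[np.argmax(v[idx])]
        amp = max(float(v[k] - baseline), 0.0)
        events.append(EventAmplitudes(t_peak=float(t[k]), amplitude=amp, cycle_index=i))
    if not events:
        raise DegenerateInputError("no fully covered pacing cycle in the trace")
    return events


def contractility_change(
    events: list[EventAmplitudes],
    light_event: StimulusEvent,
    n_pre: int = 5,
    n_post: int = 5,
) -> float:
    """Percent change of mean contraction amplitude after a light pulse.

    ``100 * (mean of the first n_post amplitudes after the light pulse -
    mean of the last n_pre amplitudes before it) / pre mean``.
    """
    pre = [e.amplitude for e in events if e.t_peak < light_event.t_on]
    post = [e.amplitude for e in events if e.t_peak >= light_event.t_off]
    if len(pre) < n_pre or len(post) < n_post:
        raise DegenerateInputError(
            f"need >= {n_pre} events before and {n_post} after the light pulse"
        )
    pre_mean = float(np.mean(pre[-n_pre:]))
    post_mean = float(np.mean(post[:n_post]))
    if pre_mean <= 0:
        raise UndefinedRatioError("pre-light mean amplitude is zero")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def frequency_timecourse(
    beats: BeatSeries, window_s: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous rate 60/RR at each beat, optionally box-smoothed.

    Returns ``(t, bpm)`` with one sample per RR interval, timestamped at the
    later beat.  ``window_s > 0`` applies a centered moving average over that
    time span.
    """
    if beats.beat_times.size < 2:
        raise DegenerateInputError("need at least 2 beats")
    t = beats.beat_times[1:]
    bpm = 60.0 / beats.rr
    if window_s > 0:
        sm = np.empty_like(bpm)
        for i, ti in enumerate(t):
            sel = np.abs(t - ti) <= window_s / 2
            sm[i] = bpm[sel].mean()
        bpm = sm
    return t, bpm


def eb_response(
    beats: BeatSeries,
    light_event: StimulusEvent,
    baseline_s: float = 30.0,
) -> dict[str, float]:
    """Maximum frequency increase and time-to-peak after a stimulus.

    Baseline is the mean instantaneous rate over ``baseline_s`` before light
    onset; the peak is the (first) maximum rate after onset.  Used for
    spontaneously beating preparations such as cardiomyocyte embryoid bodies.
    """
    t, bpm = frequency_timecourse(beats)
    pre = (t >= light_event.t_on - baseline_s) & (t < light_event.t_on)
    post = t >= light_event.t_on
    if pre.sum() < 3:
        raise DegenerateInputError("need >= 3 beats in the baseline window")
    if not post.any():
        raise DegenerateInputError("no beats after stimulus onset")
    baseline = float(bpm[pre].mean())
    idx = np.flatnonzero(post)
    k = idx[np.argmax(bpm[idx])]
    return {
        "max_frequency_increase": float(bpm[k] - baseline),
        "time_to_peak": float(t[k] - light_event.t_on),
    }


def flag_extrasystoles(
    beats: BeatSeries, threshold: float = 0.7, window: int = 7
) -> BeatSeries:
    """Flag premature beats whose RR undercuts the local median.

    Sequential rule: each beat's RR is measured from the previous *sinus*
    beat and compared with ``threshold`` times the running median of the
    last ``window`` sinus RR intervals.  Measuring from the last sinus beat
    means the compensatory interval after an extrasystole is not itself
    flagged.  Idempotent: flags are computed from beat times only.
    """
    if beats.beat_times.size < 5:
        raise DegenerateInputError("need at least 5 beats")
    t = beats.beat_times
    flags = np.zeros(t.size, dtype=bool)
    recent: list[float] = []
    last_sinus = 0
    for i in range(1, t.size):
        rr = t[i] - t[last_sinus]
        if len(recent) >= 3 and rr < threshold * float(np.median(recent[-window:])):
            flags[i] = True
            continue
        recent.append(rr)
        last_sinus = i
    return BeatSeries(t.copy(), flags)


def heart_rate_increase(
    beats: BeatSeries, light_event: StimulusEvent, n_beats: int = 7
) -> float:
    """Percent heart-rate increase from 7-beat sinus averages.

    The pre value averages the RR intervals of the last ``n_beats`` sinus
    beats before illumination; the post value averages ``n_beats`` sinus
    beats centered on the fastest sinus beat after light onset.  Premature
    beats are removed before windowing, so the windows extend across excluded
    extrasystoles to the next sinus beat.
    """
    sinus = beats.sinus()
    t = sinus.beat_times
    rr = sinus.rr
    pre_idx = np.flatnonzero(t < light_event.t_on)
    if pre_idx.size < n_beats:
        raise DegenerateInputError(f"need >= {n_beats} sinus beats before light")
    pre_beats = pre_idx[-n_beats:]
    pre_rr = rr[pre_beats[0] : pre_beats[-1]]  # intervals between those beats
    pre_rate = 60.0 / pre_rr.mean()

    post_idx = np.flatnonzero(t >= light_event.t_on)
    if post_idx.size < n_beats:
        raise DegenerateInputError(f"need >= {n_beats} sinus beats after light")
    post_rr_idx = post_idx[post_idx >= 1] - 1  # RR intervals ending at post beats
    fastest = post_rr_idx[np.argmin(rr[post_rr_idx])]
    half = n_beats // 2
    lo = max(fastest - half, 0)
    hi = min(lo + n_beats - 1, rr.size)  # n_beats beats -> n_beats-1 intervals
    lo = max(hi - (n_beats - 1), 0)
    post_rate = 60.0 / rr[lo:hi].mean()
    return 100.0 * (post_rate - pre_rate) / pre_rate


def melanopsin_change(
    beats: BeatSeries,
    light_event: StimulusEvent,
    window_s: float = 30.0,
    smooth_s: float = 1.0,
) -> float:
    """Normalized frequency change for inhibitory (rate-slowing) stimulation.

    RR traces are smoothed by averaging over ``smooth_s`` bins; the statistic
    is the minimum frequency within ``window_s`` after illumination relative
    to the minimum frequency within ``window_s`` before, as a signed percent
    (negative = rate decrease).
    """
    t, bpm = frequency_timecourse(beats, window_s=smooth_s)
    pre = (t >= light_event.t_on - window_s) & (t < light_event.t_on)
    post = (t >= light_event.t_on) & (t < light_event.t_on + window_s)
    if not pre.any() or not post.any():
        raise DegenerateInputError("empty pre or post window")
    pre_min = float(bpm[pre].min())
    post_min = float(bpm[post].min())
    return 100.0 * (post_min - pre_min) / pre_min


def girk_modulation(i_uv: float, i_green: float) -> float:
    """Ratio of inward current during UV vs green illumination (at -80 mV).

    A ratio below 1 means UV light reduced the inward current magnitude,
    i.e. Gq-mediated GIRK inhibition rather than Gi-mediated activation.
    """
    if i_green == 0:
        raise UndefinedRatioError("green-light current is zero")
    if i_uv * i_green < 0:
        raise ValidationError("currents must share the same sign convention")
    return float(i_uv / i_green)


def dff0(
    F: np.ndarray, background: float | np.ndarray = 0.0, f0_samples: int = 5
) -> np.ndarray:
    """Background-subtracted fluorescence normalized to its starting level.

    F0 is the mean of the first ``f0_samples`` background-subtracted samples;
    the returned trace is ``(F - bg - F0) / F0`` so its first samples are ~0.
    """
    F = np.asarray(F, dtype=float)
    corrected = F - np.asarray(background, dtype=float)
    f0 = float(corrected[:f0_samples].mean())
    if f0 <= 0:
        raise UndefinedRatioError("F0 (background-subtracted start level) must be > 0")
    return (corrected - f0) / f0


def decay_half_time(
    t: np.ndarray,
    y: np.ndarray,
    t_event: float,
    method: str = "exponential",
) -> float:
    """Time for a luminescence trace to fall to 50% of its value at ``t_event``.

    ``method='exponential'`` fits ``y = A·exp(-(t-t0)/tau)`` to the samples
    after ``t_event`` and returns ``ln(2)·tau``; ``method='linear'`` fits a
    straight line and returns the time at which it crosses half the fitted
    start value.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = t >= t_event
    if sel.sum() < 5:
        raise DegenerateInputError("need >= 5 samples after t_event")
    ts = t[sel] - t_event
    ys = y[sel]
    slope = np.polyfit(ts, ys, 1)[0]
    if slope >= 0 or np.allclose(ys, ys[0]):
        raise FitFailureError("trace is not decaying after t_event")
    if method == "linear":
        m, b = np.polyfit(ts, ys, 1)
        return float(-0.5 * b / m)
    if method != "exponential":
        raise UsageError(f"unknown method {method!r}")
    a0 = float(ys[0])
    tau0 = max(float(ts[-1]) / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            ts,
            ys,
            p0=(a0, tau0),
            bounds=([0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitFailureError(str(exc)) from exc
    return float(np.log(2.0) * popt[1])


def force_response(
    t: np.ndarray,
    force: np.ndarray,
    stim: StimulusEvent,
    kind: str = "pulse",
    post_window_s: float = 10.0,
) -> float:
    """Force response to a stimulus, in trace units (typically mN).

    ``kind='pulse'`` (light/EFS): maximal force between stimulus onset and
    ``post_window_s`` after its end, minus the pre-stimulus baseline.
    ``kind='bath'`` (drug/K+ application): difference between the maximum
    force after and the maximum force before application.
    """
    t = np.asarray(t, dtype=float)
    force = np.asarray(force, dtype=float)
    if kind == "pulse":
        t_end = stim.t_off + post_window_s
        if stim.t_on < t[0] or t_end > t[-1] + 1e-9:
            raise DegenerateInputError("response window extends beyond the trace")
        window = (t >= stim.t_on) & (t <= t_end)
        pre = t < stim.t_on
        baseline = float(force[pre].mean()) if pre.any() else 0.0
        return float(force[window].max() - baseline)
    if kind == "bath":
        pre = t < stim.t_on
        post = t >= stim.t_on
        if not pre.any() or not post.any():
            raise DegenerateInputError("trace must cover both sides of application")
        return float(force[post].max() - force[pre].max())
    raise UsageError(f"unknown response kind {kind!r}")


def beat_frequency(trace: MotionTrace) -> float:
    """Beat frequency of a periodic motion trace via autocorrelation.

    The |V| signal of a contraction has a shortening and a re-lengthening
    velocity lobe per beat, so naive peak counting can double-count; the
    repeat period of the whole pattern is instead read off the first
    prominent maximum of the autocorrelation.
    """
    v = trace.v - trace.v.mean()
    if np.allclose(v, 0):
        raise DegenerateInputError("motion trace is flat")
    n = v.size
    ac = np.correlate(v, v, mode="full")[n - 1 :]
    ac /= ac[0]
    # strongest positive-lag local maximum: intra-beat lobe spacings also
    # produce maxima, but only the full beat period realigns the whole pattern
    cand = [
        k
        for k in range(1, n - 1)
        if ac[k] >= ac[k - 1] and ac[k] >= ac[k + 1] and ac[k] > 0.2
    ]
    if not cand:
        raise FitFailureError("no periodicity detected in the motion trace")
    lag = max(cand, key=lambda k: ac[k])
    dt = float(np.mean(np.diff(trace.t)))
    return 1.0 / (lag * dt)
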