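"""Seeded generators for every input class the toolkit consumes.

Each generator returns its output together with a ground-truth record so
that round-trip tests (generate -> analyze -> compare) can assert parameter
recovery.  All randomness flows through ``numpy.random.default_rng(seed)``:
identical seeds give byte-identical outputs.

The generators emulate the *shape* of the experimental data — textured
contracting cells, Hill-shaped dose ladders, pigment-template spectra,
force summation with receptor desensitization, beat series with premature
extrasystoles, dual-channel screening plates — not the underlying
photocycle or excitation-contraction biophysics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import ValidationError
from .flowcore import FrameStack
from .respmodels import DoseResponse, SpectralResponse, govardovskii_template
from .traces import BeatSeries

__all__ = [
    "gen_contracting_video",
    "gen_dose_response",
    "gen_spectrum",
    "gen_force_train",
    "gen_beats",
    "gen_plate",
]


def _raised_cosine_weight(t: np.ndarray, beat_rate_hz: float, duty: float) -> np.ndarray:
    """Periodic raised-cosine contraction time course in [0, 1]."""
    phase = np.mod(t * beat_rate_hz, 1.0)
    w = np.zeros_like(t)
    active = phase < duty
    w[active] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[active] / duty))
    return w


def gen_contracting_video(
    shape: tuple[int, int] = (80, 80),
    fps: float = 50.0,
    beat_rate_hz: float = 1.0,
    peak_displacement_px: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int | None = None,
    duty: float = 0.4,
) -> tuple[FrameStack, dict]:
    """Movie of a textured elliptical cell contracting radially.

    The whole frame is warped by a time-dependent radial scaling about the
    cell center; the boundary point on the semi-major axis moves by
    ``peak_displacement_px`` at full contraction, following a raised-cosine
    time course occupying ``duty`` of each beat cycle.  Band-limited noise
    texture inside (strong) and outside (weak) the cell gives the flow
    estimator structure to track.

    Returns the stack (with the cell ellipse as ``roi_mask``) and a truth
    dict with the analytic per-frame-pair mean displacement over the ROI
    (``mean_disp``) and over the full frame (``mean_disp_frame``).
    """
    H, W = shape
    if peak_displacement_px < 0 or peak_displacement_px > min(H, W) / 8:
        raise ValidationError("peak_displacement must lie in [0, min(shape)/8]")
    if not (0 < beat_rate_hz < fps / 4):
        raise ValidationError("beat_rate must be positive and < fps/4")
    if n_frames is None:
        n_frames = int(round(2 * fps / beat_rate_hz))  # two beats by default
    rng = np.random.default_rng(seed)

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    a, b = 0.38 * W, 0.28 * H  # semi-axes (x, y)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    ellipse = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    texture = ndimage.gaussian_filter(rng.standard_normal((H, W)), 1.5)
    texture /= np.abs(texture).max()
    base = 0.15 * texture + np.where(ellipse, 0.6 + 0.6 * texture, 0.1)

    t = np.arange(n_frames) / fps
    w = _raised_cosine_weight(t, beat_rate_hz, duty)
    scales = 1.0 - (peak_displacement_px / a) * w

    frames = np.empty((n_frames, H, W))
    for i, s in enumerate(scales):
        sy = cy + (yy - cy) / s
        sx = cx + (xx - cx) / s
        frames[i] = ndimage.map_coordinates(base, [sy, sx], order=3, mode="nearest")
    if noise_sd > 0:
        frames += noise_sd * rng.standard_normal(frames.shape)

    roi = ((xx - cx) / (0.85 * a)) ** 2 + ((yy - cy) / (0.85 * b)) ** 2 <= 1.0
    r = np.hypot(xx - cx, yy - cy)
    mean_r_roi = float(r[roi].mean())
    mean_r_frame = float(r.mean())
    ratio = np.abs(scales[1:] / scales[:-1] - 1.0)
    truth = {
        "beat_rate_hz": beat_rate_hz,
        "scales": scales,
        "mean_disp": ratio * mean_r_roi,
        "mean_disp_frame": ratio * mean_r_frame,
        "peak_displacement_px": peak_displacement_px,
    }
    return FrameStack(frames=frames, frame_interval_s=1.0 / fps, roi_mask=roi), truth


def gen_dose_response(
    half_max: float,
    doses: np.ndarray,
    slope: float = 1.0,
    bottom: float = 0.0,
    top: float = 1.0,
    noise_sd: float = 0.0,
    reps: int = 1,
    seed: int = 0,
    units: str = "uW/mm^2",
    log_axis: bool = True,
) -> tuple[DoseResponse, dict]:
    """4PL-shaped dose-response data with additive Gaussian noise."""
    rng = np.random.default_rng(seed)
    doses = np.repeat(np.asarray(doses, dtype=float), reps)
    resp = bottom + (top - bottom) / (1.0 + (half_max / doses) ** slope)
    if noise_sd > 0:
        resp = resp + noise_sd * rng.standard_normal(resp.shape)
    truth = {"half_max": half_max, "slope": slope, "top": top, "bottom": bottom}
    return DoseResponse(dose=doses, response=resp, units=units, log_axis=log_axis), truth


def gen_spectrum(
    lambda_max_nm: float,
    wavelengths_nm: np.ndarray,
    noise_sd: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
) -> tuple[SpectralResponse, dict]:
    """Action-spectrum data from the Govardovskii A1 template."""
    rng = np.random.default_rng(seed)
    lam = np.asarray(wavelengths_nm, dtype=float)
    resp = scale * govardovskii_template(lam, lambda_max_nm)
    if noise_sd > 0:
        resp = resp + noise_sd * rng.standard_normal(resp.shape)
    truth = {"lambda_max_nm": lambda_max_nm, "scale": scale}
    return SpectralResponse(wavelength_nm=lam, response=resp), truth


def gen_force_train(
    pulse_len_s: float,
    rate_hz: float,
    duration_s: float = 10.0,
    tau_act_s: float = 0.06,
    tau_deact_s: float = 1.0,
    desens_tau_s: float = 8.0,
    recovery_tau_s: float = 6.0,
    kernel_tau_s: float = 0.8,
    dt: float = 0.005,
    noise_sd: float = 0.0,
    seed: int = 0,
    pulse_times: np.ndarray | None = None,
    total_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Isometric-force trace for a pulsed illumination pattern.

    Two first-order state variables drive the force: an activation state A
    that rises during light (``tau_act_s``) and decays in the dark
    (``tau_deact_s``), and a desensitization resource D that depletes in
    proportion to the receptor drive (``desens_tau_s``) and recovers while
    the receptor is idle (``recovery_tau_s``).  The contractile drive
    ``A * D`` is convolved with an alpha-function force kernel.  Because A
    outlasts short pulses, pulse trains summate toward the
    continuous-illumination bound, which is the saturating maximum, and
    paired-pulse amplitude ratios approach ``1 - exp(-dt/recovery_tau)``
    once the first pulse has depleted D.

    Either a regular ``(pulse_len_s, rate_hz, duration_s)`` pattern or
    explicit ``pulse_times`` (all of length ``pulse_len_s``) can be given.
    Continuous illumination is the special case ``pulse_len_s >= 1/rate_hz``.
    Returns ``(t, force, truth)`` with the state trajectories in ``truth``.
    """
    if pulse_len_s <= 0 or (pulse_times is None and rate_hz <= 0):
        raise ValidationError("pulse length and rate must be positive")
    for tau in (tau_act_s, tau_deact_s, desens_tau_s, recovery_tau_s, kernel_tau_s):
        if tau <= 0:
            raise ValidationError("all time constants must be positive")
    rng = np.random.default_rng(seed)
    if pulse_times is None:
        interval = 1.0 / rate_hz
        pulse_times = np.arange(0.0, duration_s, interval)
        end = duration_s
    else:
        pulse_times = np.asarray(pulse_times, dtype=float)
        end = float(pulse_times.max()) + pulse_len_s
    total = total_s if total_s is not None else end + 6.0 * kernel_tau_s
    t = np.arange(0.0, total, dt)

    light = np.zeros_like(t, dtype=bool)
    for p in pulse_times:
        light |= (t >= p) & (t < p + pulse_len_s)

    A = np.zeros_like(t)
    D = np.ones_like(t)
    for i in range(1, t.size):
        if light[i - 1]:
            A[i] = A[i - 1] + dt * (1.0 - A[i - 1]) / tau_act_s
        else:
            A[i] = A[i - 1] - dt * A[i - 1] / tau_deact_s
        # resource depletes in proportion to receptor drive, recovers when idle
        D[i] = D[i - 1] + dt * (
            -D[i - 1] * A[i - 1] / desens_tau_s
            + (1.0 - D[i - 1]) * (1.0 - A[i - 1]) / recovery_tau_s
        )

    drive = A * D
    tk = np.arange(0.0, 6.0 * kernel_tau_s, dt)
    kernel = (tk / kernel_tau_s) * np.exp(1.0 - tk / kernel_tau_s)
    force = fftconvolve(drive, kernel)[: t.size] * dt / kernel_tau_s
    if noise_sd > 0:
        force = force + noise_sd * rng.standard_normal(force.shape)
    truth = {
        "pulse_times": pulse_times,
        "pulse_len_s": pulse_len_s,
        "A": A,
        "D": D,
        "recovery_tau_s": recovery_tau_s,
        "desens_tau_s": desens_tau_s,
    }
    return t, force, truth


def gen_beats(
    base_rate_bpm: float = 300.0,
    delta_bpm: float = 0.0,
    t_light_s: float = 60.0,
    onset_s: float = 0.0,
    tau_s: float = 2.0,
    duration_s: float = 120.0,
    rr_jitter: float = 0.0,
    extrasystole_prob: float = 0.0,
    seed: int = 0,
) -> tuple[BeatSeries, dict]:
    """Beat series with an exponential rate response to a light pulse.

    The instantaneous rate is ``base_rate_bpm`` before ``t_light_s`` and
    approaches ``base + delta_bpm`` with time constant ``tau_s`` after
    ``t_light_s + onset_s`` (negative ``delta_bpm`` models bradycardia).
    Premature extrasystoles are inserted after sinus beats with probability
    ``extrasystole_prob`` at 45% of the local RR, without resetting the
    sinus schedule.  Truth labels mark the inserted beats.
    """
    if base_rate_bpm <= 0 or duration_s <= 0:
        raise ValidationError("base rate and duration must be positive")
    rng = np.random.default_rng(seed)

    def rate(tt: float) -> float:
        if tt < t_light_s + onset_s or delta_bpm == 0:
            return base_rate_bpm
        return base_rate_bpm + delta_bpm * (1.0 - np.exp(-(tt - t_light_s - onset_s) / tau_s))

    times = [0.0]
    while times[-1] < duration_s:
        rr = 60.0 / rate(times[-1])
        if rr_jitter > 0:
            rr *= 1.0 + rr_jitter * rng.standard_normal()
        times.append(times[-1] + rr)
    sinus_times = np.array(times)

    beat_times = []
    premature = []
    for i, bt in enumerate(sinus_times):
        beat_times.append(bt)
        premature.append(False)
        if i + 1 < sinus_times.size and extrasystole_prob > 0:
            if rng.random() < extrasystole_prob:
                beat_times.append(bt + 0.45 * (sinus_times[i + 1] - bt))
                premature.append(True)
    beat_times = np.array(beat_times)
    premature = np.array(premature)
    truth = {
        "base_rate_bpm": base_rate_bpm,
        "delta_bpm": delta_bpm,
        "t_light_s": t_light_s,
        "premature": premature,
        "sinus_times": sinus_times,
    }
    return BeatSeries(beat_times=beat_times), truth


def gen_plate(
    n_compounds: int = 1000,
    mixture: dict | None = None,
    hit_inhibition_mean: float = 80.0,
    hit_inhibition_sd: float = 8.0,
    inactive_sd: float = 4.0,
    read_noise_sd: float = 0.02,
    wells_per_plate: int = 320,
    multiplicative_noise: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Raw dual-channel screening plates with embedded inhibitor classes.

    Each compound is drawn from ``mixture`` (category probabilities for
    ``double``, ``agonist_only``, ``light_only``, ``inactive``) and given a
    true % inhibition per channel; the raw well signal is the DMSO level
    scaled by ``1 - inhibition/100`` plus read noise (additive Gaussian by
    default, multiplicative log-normal when ``multiplicative_noise``).
    Every plate carries 16 DMSO wells, 2 full-block and 2 receptor-block
    control wells.  Returns the long-format raw frame (ready for
    ``hts.normalize_plate``) and the truth labels per compound.
    """
    mixture = mixture or {
        "double": 0.002,
        "agonist_only": 0.013,
        "light_only": 0.0,
        "inactive": 0.985,
    }
    cats = list(mixture)
    probs = np.array([mixture[c] for c in cats], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValidationError("mixture probabilities must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    dmso_level = 1.0

    def raw_signal(inh: np.ndarray) -> np.ndarray:
        sig = dmso_level * (1.0 - inh / 100.0)
        if multiplicative_noise:
            return sig * np.exp(read_noise_sd * rng.standard_normal(sig.shape))
        return sig + read_noise_sd * rng.standard_normal(sig.shape)

    categories = rng.choice(len(cats), size=n_compounds, p=probs)
    inh_light = np.where(
        np.isin(categories, [cats.index("double"), cats.index("light_only")]
                if "light_only" in cats else [cats.index("double")]),
        rng.normal(hit_inhibition_mean, hit_inhibition_sd, n_compounds),
        rng.normal(0.0, inactive_sd, n_compounds),
    )
    inh_ago = np.where(
        np.isin(categories, [cats.index("double"), cats.index("agonist_only")]),
        rng.normal(hit_inhibition_mean, hit_inhibition_sd, n_compounds),
        rng.normal(0.0, inactive_sd, n_compounds),
    )

    rows = []
    n_controls = 20
    test_per_plate = wells_per_plate - n_controls
    n_plates = int(np.ceil(n_compounds / test_per_plate))
    ci = 0
    for p in range(n_plates):
        plate = f"P{p + 1:03d}"
        for w in range(16):
            rows.append((plate, f"DMSO{w:02d}", "DMSO", "dmso", 0.0,
                         float(raw_signal(np.zeros(1))[0]),
                         float(raw_signal(np.zeros(1))[0])))
        for w in range(2):
            rows.append((plate, f"BLK{w:02d}", "SAR7334", "pos_channel_block", 3e-6,
                         float(raw_signal(np.full(1, 100.0))[0]),
                         float(raw_signal(np.full(1, 100.0))[0])))
        for w in range(2):
            rows.append((plate, f"RB{w:02d}", "atropine", "pos_receptor_block", 6e-6,
                         float(raw_signal(np.zeros(1))[0]),
                         float(raw_signal(np.full(1, 100.0))[0])))
        for w in range(test_per_plate):
            if ci >= n_compounds:
                break
            rows.append((plate, f"T{w:03d}", f"CMPD{ci:06d}", "test", 6e-6,
                         float(raw_signal(np.array([inh_light[ci]]))[0]),
                         float(raw_signal(np.array([inh_ago[ci]]))[0])))
            ci += 1
    frame = pd.DataFrame(
        rows,
        columns=["plate", "well", "compound_id", "role", "concentration_M",
                 "resp_light", "resp_agonist"],
    )
    truth = {
        "category": np.array([cats[k] for k in categories]),
        "inhibition_light": inh_light,
        "inhibition_agonist": inh_ago,
        "mixture": mixture,
    }
    return frame, truth
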