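"""Parametric stimulus-response models.

Four-parameter logistic (Hill) fits on intensity, duration, duty-cycle and
concentration axes (eLi50, half-maximal pulse duration/duty cycle, IC50 and
pIC50), visual-pigment action-spectrum fitting with the Govardovskii A1
alpha-band template, paired-pulse desensitization and one-phase recovery
kinetics, and the light energy dose (intensity x duration) bookkeeping used
to compare sensitivity across stimulation modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .errors import (
    FitFailureError,
    UndefinedRatioError,
    UsageError,
    ValidationError,
)

__all__ = [
    "DoseResponse",
    "HillFit",
    "SpectralResponse",
    "GovFit",
    "RecoveryFit",
    "hill_fit",
    "pic50",
    "govardovskii_template",
    "fit_spectrum",
    "inhibition_percent",
    "paired_pulse_ratio",
    "recovery_fit",
    "desensitization",
    "duty_cycle_analysis",
    "energy_dose",
]

DOSE_UNITS = ("uW/mm^2", "ms", "% duty", "mol/L")


@dataclass
class DoseResponse:
    """Paired (dose, response) arrays with axis semantics.

    ``units`` tags the dose axis (one of ``uW/mm^2``, ``ms``, ``% duty``,
    ``mol/L``); ``log_axis`` marks responses as sigmoidal in log10(dose),
    the usual presentation for light intensities and concentrations.
    """

    dose: np.ndarray
    response: np.ndarray
    units: str = "uW/mm^2"
    log_axis: bool = True

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dose.shape != self.response.shape or self.dose.ndim != 1:
            raise ValidationError("dose and response must be equal-length 1D arrays")
        if not (np.all(np.isfinite(self.dose)) and np.all(np.isfinite(self.response))):
            raise ValidationError("dose and response must be finite")
        if self.log_axis and np.any(self.dose <= 0):
            raise ValidationError("doses must be > 0 on a log axis")
        if self.units not in DOSE_UNITS:
            raise ValidationError(f"units must be one of {DOSE_UNITS}")


@dataclass
class HillFit:
    """4PL parameters: R(d) = bottom + (top-bottom) / (1 + (half/d)^slope)."""

    half_max_dose: float
    hill_slope: float
    top: float
    bottom: float
    r2: float
    units: str = "uW/mm^2"
    se_half_max: float = float("nan")

    def __post_init__(self):
        if self.half_max_dose <= 0:
            raise ValidationError("half_max_dose must be positive")
        if self.top < self.bottom:
            raise ValidationError("top must be >= bottom")
        if self.r2 > 1 + 1e-12:
            raise ValidationError("r2 cannot exceed 1")

    def predict(self, dose: np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.half_max_dose / dose) ** self.hill_slope
        )


@dataclass
class SpectralResponse:
    """Response amplitude (or % inhibition) per stimulation wavelength."""

    wavelength_nm: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.wavelength_nm.shape != self.response.shape or self.wavelength_nm.ndim != 1:
            raise ValidationError("wavelength and response must be equal-length 1D")
        if np.any(self.wavelength_nm < 300) or np.any(self.wavelength_nm > 700):
            raise ValidationError("wavelengths must lie in [300, 700] nm")
        if np.unique(self.wavelength_nm).size != self.wavelength_nm.size:
            raise ValidationError("wavelengths must be distinct")


@dataclass
class GovFit:
    """Fitted action-spectrum template: peak wavelength and amplitude scale."""

    lambda_max_nm: float
    scale: float
    r2: float


@dataclass
class RecoveryFit:
    """One-phase exponential recovery toward a plateau."""

    tau_s: float
    half_recovery_s: float
    plateau: float
    r2: float
    included: bool = True

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValidationError("tau_s must be positive")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def hill_fit(data: DoseResponse) -> HillFit:
    """Least-squares 4PL fit on the declared dose axis.

    On a log axis the model is parameterized in log10(half) so the optimizer
    works on the plotted coordinate.  Initialization: slope 1 (sign taken
    from the data trend), half at the geometric median dose, top/bottom from
    the response extremes; half is bounded to [min dose/10, max dose*10].
    A monotone-beyond-noise violation only triggers a warning.
    """
    if np.unique(data.dose).size < 4:
        raise ValidationError("need >= 4 distinct doses for a 4-parameter fit")
    d, y = data.dose, data.response
    if np.allclose(y, y[0]):
        raise FitFailureError("responses are constant; dose dependence unidentifiable")
    order = np.argsort(d)
    rising = y[order][-2:].mean() >= y[order][:2].mean()
    top0, bot0 = float(y.max()), float(y.min())
    half0 = float(np.exp(np.median(np.log(d)))) if data.log_axis else float(np.median(d))
    slope0 = 1.0 if rising else -1.0

    if data.log_axis:
        x = np.log10(d)
        lo, hi = np.log10(d.min() / 10.0), np.log10(d.max() * 10.0)

        def model(xx, logh, s, top, bot):
            return bot + (top - bot) / (1.0 + 10.0 ** ((logh - xx) * s))

        p0 = (np.log10(half0), slope0, top0, bot0)
        bounds = ([lo, -50, -np.inf, -np.inf], [hi, 50, np.inf, np.inf])
    else:
        x = d
        lo, hi = d.min() / 10.0, d.max() * 10.0

        def model(xx, h, s, top, bot):
            return bot + (top - bot) / (1.0 + (h / xx) ** s)

        p0 = (half0, slope0, top0, bot0)
        bounds = ([lo, -50, -np.inf, -np.inf], [hi, 50, np.inf, np.inf])

    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"4PL fit did not converge: {exc}") from exc
    yhat = model(x, *popt)
    r2 = _r2(y, yhat)
    if r2 < 0.5:
        warnings.warn("dose-response poorly described by a 4PL (r2 < 0.5)", stacklevel=2)

    half = float(10.0 ** popt[0]) if data.log_axis else float(popt[0])
    slope, top, bot = float(popt[1]), float(popt[2]), float(popt[3])
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    if data.log_axis and np.isfinite(se):
        se = half * np.log(10.0) * se  # delta method back to the dose scale
    if top < bot:  # normalize the equivalent (top/bottom swap, slope sign) form
        top, bot, slope = bot, top, -slope
    return HillFit(
        half_max_dose=half,
        hill_slope=slope,
        top=top,
        bottom=bot,
        r2=r2,
        units=data.units,
        se_half_max=se,
    )


def pic50(fit: HillFit) -> float:
    """-log10 of a half-maximal inhibitory concentration in mol/L."""
    if fit.units != "mol/L":
        raise UsageError("pIC50 requires a concentration fit (units 'mol/L')")
    return float(-np.log10(fit.half_max_dose))


# A1 visual-pigment alpha-band template constants (Govardovskii et al. 2000).
_GOV_A, _GOV_B, _GOV_b, _GOV_C, _GOV_c, _GOV_D = 69.7, 28.0, 0.922, -14.9, 1.104, 0.674


def govardovskii_template(wavelength_nm, lambda_max_nm: float) -> np.ndarray:
    """A1 pigment alpha-band sensitivity at the given wavelengths.

    ``S(x) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)`` with
    ``x = lambda_max / lambda`` and ``a`` weakly dependent on lambda_max.
    The template peaks (value ~1) at ``lambda = lambda_max``.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValidationError("wavelengths must be positive")
    if lambda_max_nm <= 0:
        raise ValidationError("lambda_max must be positive")
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    x = lambda_max_nm / lam
    denom = (
        np.exp(_GOV_A * (a - x))
        + np.exp(_GOV_B * (_GOV_b - x))
        + np.exp(_GOV_C * (_GOV_c - x))
        + _GOV_D
    )
    return 1.0 / denom


def fit_spectrum(
    data: SpectralResponse,
    grid_nm: tuple[float, float] = (350.0, 600.0),
) -> GovFit:
    """Fit (lambda_max, scale) of the Govardovskii template by least squares.

    lambda_max is seeded on a 1 nm grid and refined by bounded scalar
    minimization; for each candidate lambda_max the amplitude scale has the
    closed-form linear least-squares solution.  A boundary warning is issued
    when the fitted peak falls outside the sampled wavelength range.
    """
    if data.wavelength_nm.size < 5:
        raise ValidationError("need >= 5 wavelengths spanning the peak")
    lam, y = data.wavelength_nm, data.response

    def sse(lmax: float) -> tuple[float, float]:
        s = govardovskii_template(lam, lmax)
        denom = float(np.sum(s * s))
        scale = float(np.sum(s * y)) / denom if denom > 0 else 0.0
        return float(np.sum((y - scale * s) ** 2)), scale

    grid = np.arange(grid_nm[0], grid_nm[1] + 0.5, 1.0)
    errs = np.array([sse(g)[0] for g in grid])
    best = grid[int(np.argmin(errs))]
    res = minimize_scalar(
        lambda l: sse(l)[0],
        bounds=(max(best - 2.0, grid_nm[0]), min(best + 2.0, grid_nm[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lmax = float(res.x)
    err, scale = sse(lmax)
    r2 = _r2(y, scale * govardovskii_template(lam, lmax))
    if not (lam.min() <= lmax <= lam.max()):
        warnings.warn("fitted lambda_max lies outside the sampled wavelengths", stacklevel=2)
    return GovFit(lambda_max_nm=lmax, scale=scale, r2=r2)


def inhibition_percent(amp_paired: float, amp_uv_only: float) -> float:
    """Percent inhibition of a response by a paired deactivating pulse."""
    if amp_uv_only <= 0:
        raise UndefinedRatioError("reference (UV-only) amplitude must be > 0")
    return 100.0 * (1.0 - amp_paired / amp_uv_only)


def paired_pulse_ratio(first_amp: float, second_amp: float) -> float:
    """Second response amplitude normalized to the first (desensitization)."""
    if first_amp <= 0:
        raise UndefinedRatioError("first amplitude must be > 0")
    return float(second_amp / first_amp)


def recovery_fit(
    intervals_s: np.ndarray,
    ratios: np.ndarray,
    r2_threshold: float = 0.7,
) -> RecoveryFit:
    """One-phase exponential fit of paired-pulse ratio vs interpulse interval.

    Model: ``ratio(t) = plateau - (plateau - y0) * exp(-t / tau)``; the
    half-maximal recovery time is ``ln(2) * tau`` by identity.  Fits with
    r2 at or below ``r2_threshold`` are marked excluded (``included=False``)
    mirroring the usual quality filter, but their parameters are returned.
    """
    t = np.asarray(intervals_s, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if t.size < 4:
        raise ValidationError("need >= 4 interpulse intervals")
    if t.shape != y.shape:
        raise ValidationError("intervals and ratios must have equal length")

    def model(tt, tau, plateau, y0):
        return plateau - (plateau - y0) * np.exp(-tt / tau)

    span = float(t.max() - t.min()) or 1.0
    p0 = (span / 3.0, float(np.clip(y.max(), 0.1, 1.2)), float(y.min()))
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"recovery fit did not converge: {exc}") from exc
    tau, plateau = float(popt[0]), float(popt[1])
    r2 = _r2(y, model(t, *popt))
    return RecoveryFit(
        tau_s=tau,
        half_recovery_s=float(np.log(2.0) * tau),
        plateau=plateau,
        r2=r2,
        included=bool(r2 > r2_threshold),
    )


def desensitization(t: np.ndarray, force: np.ndarray, stim) -> float:
    """Relative force decline during a sustained light pulse.

    ``(peak - end-of-pulse value) / peak``, computed inside the pulse window;
    0 for a flat plateau, approaching 1 for complete desensitization.
    """
    t = np.asarray(t, dtype=float)
    force = np.asarray(force, dtype=float)
    window = (t >= stim.t_on) & (t <= stim.t_off)
    if not window.any():
        raise ValidationError("trace does not cover the pulse window")
    fw = force[window]
    peak = float(fw.max())
    if peak <= 0:
        raise UndefinedRatioError("peak force during the pulse must be > 0")
    end = float(fw[-1])
    return float(np.clip((peak - end) / peak, 0.0, 1.0))


def duty_cycle_analysis(
    peak_forces: np.ndarray,
    patterns: list[dict],
    continuous_ref: float,
    baseline: float = 0.0,
) -> tuple[DoseResponse, HillFit]:
    """Normalized force vs illumination duty cycle, with a Hill fit.

    ``patterns`` holds ``{"pulse_len": s, "rate": Hz}`` per tested pattern;
    duty cycle is their product as a percentage.  Peak forces are first
    reduced by ``baseline`` (the mean cyclic height of the endogenous
    contraction pattern before illumination) and then normalized to the
    continuous-illumination reference, so continuous light maps to 1.0.
    Returns the dose-response on the % duty axis and the 4PL fit whose
    ``half_max_dose`` is the half-maximal duty cycle.
    """
    peak_forces = np.asarray(peak_forces, dtype=float)
    if len(patterns) != peak_forces.size:
        raise ValidationError("one pattern per peak force required")
    ref = continuous_ref - baseline
    if ref <= 0:
        raise UndefinedRatioError("continuous-illumination reference must exceed baseline")
    duty = np.array([100.0 * p["pulse_len"] * p["rate"] for p in patterns])
    if np.any(duty <= 0) or np.any(duty > 100.0 + 1e-9):
        raise ValidationError("duty cycles must lie in (0, 100] %")
    norm = (peak_forces - baseline) / ref
    data = DoseResponse(dose=duty, response=norm, units="% duty", log_axis=True)
    return data, hill_fit(data)


def energy_dose(
    intensity_uw_mm2: float, duration: float, duration_unit: str = "s"
) -> float:
    """Light energy dose in µW·s/mm² (intensity x duration).

    ``duration_unit`` may be ``"s"`` or ``"ms"`` (auto-converted).
    """
    if intensity_uw_mm2 < 0 or duration < 0:
        raise ValidationError("intensity and duration must be >= 0")
    if duration_unit == "ms":
        duration = duration / 1000.0
    elif duration_unit != "s":
        raise UsageError(f"unknown duration unit {duration_unit!r}")
    return float(intensity_uw_mm2 * duration)
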