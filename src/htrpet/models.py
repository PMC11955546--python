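"""Forward kinetic models.

The adiabatic approximation to the tissue-homogeneity (AATH) model has the
closed-form impulse response

    R(t) = CBF                      for 0 <= t < Tc   (vascular phase)
    R(t) = K1 * exp(-k2 (t - Tc))   for t >= Tc       (tissue phase)

where Tc is the mean vascular transit time.  The tissue time-activity curve
is the delayed arterial input convolved with R, which expands into two
cumulative whole-blood integrals (the intravascular component, scaled by
CBF) plus an exponential convolution of the parent plasma input (the
extravascular component, scaled by K1).  The standard one-tissue compartment
(S1TC) model is the Tc -> 0 limit with CBF = vb/Tc: a vb-weighted delta plus
K1*exp(-k2 t).

All curve generation happens on a fine time grid (default 0.05 s) with
fractional-second delay/transit shifts applied by linear interpolation; the
input is zero before t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (
    AATHParams,
    CoverageError,
    DerivedParams,
    FrameSchedule,
    InputFunction,
    S1TCParams,
    TimeSeriesCurve,
)

__all__ = [
    "ModelCurveDecomposition",
    "aath_impulse_response",
    "s1tc_impulse_response",
    "generate_aath_tac",
    "generate_s1tc_tac",
    "decompose_aath_tac",
    "derive_parameters",
    "extraction_to_ps",
    "ps_to_extraction",
    "fine_time_grid",
    "cumulative_input_integral",
    "exp_convolution",
    "sample_shifted",
]

DEFAULT_FINE_DT = 0.05
MAX_FINE_DT = 0.25


@dataclass
class ModelCurveDecomposition:
    """AATH curve split into intravascular (CBF term) and extravascular (K1 term)."""

    total: TimeSeriesCurve
    intravascular: TimeSeriesCurve
    extravascular: TimeSeriesCurve


def aath_impulse_response(params: AATHParams, t: float | np.ndarray) -> float | np.ndarray:
    """AATH impulse response (ml/min/cm^3) at time(s) t >= 0 seconds.

    The boundary t = Tc belongs to the tissue phase.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    k2_s = params.k2 / 60.0
    out = np.where(tt < params.tc, params.cbf, params.k1 * np.exp(-k2_s * np.maximum(tt - params.tc, 0.0)))
    return float(out) if np.isscalar(t) else out


def s1tc_impulse_response(params: S1TCParams, t: float | np.ndarray) -> float | np.ndarray:
    """S1TC impulse response for t > 0: K1*exp(-k2 t) (ml/min/cm^3).

    At t = 0 the response is the delta component vb*delta(t), which is not a
    finite sample; those entries are returned as NaN and handled as a direct
    whole-blood term in curve generation.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    k2_s = params.k2 / 60.0
    out = np.where(tt > 0, params.k1 * np.exp(-k2_s * tt), np.nan)
    return float(out) if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# Fine-grid machinery shared with the basis-function fitter


def fine_time_grid(end_time: float, fine_dt: float = DEFAULT_FINE_DT) -> np.ndarray:
    if not 0 < fine_dt <= MAX_FINE_DT:
        raise ValueError(f"fine_dt must be in (0, {MAX_FINE_DT}] s")
    n = int(round(end_time / fine_dt))
    return np.arange(n + 1) * fine_dt


def cumulative_input_integral(t_fine: np.ndarray, c_fine: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral of an input curve on the fine grid."""
    return cumulative_trapezoid(c_fine, t_fine, initial=0.0)


def exp_convolution(t_fine: np.ndarray, c_fine: np.ndarray, k2_per_s: float) -> np.ndarray:
    """y(t) = int_0^t c(tau) exp(-k2 (t - tau)) dtau on a uniform fine grid.

    Uses the exponential integrator that is exact for piecewise-linear c:
    y[i+1] = a*y[i] + w0*c[i] + w1*c[i+1] with a = exp(-k2 dt),
    w1 = 1/k2 - (1-a)/(k2^2 dt) and w0 = (1-a)/k2 - w1, so arbitrarily
    fast kernels (e.g. dispersion rates) remain stable and accurate.
    """
    from scipy.signal import lfilter

    dt = float(t_fine[1] - t_fine[0])
    k = float(k2_per_s)
    if k == 0.0:
        a, w0, w1 = 1.0, dt / 2.0, dt / 2.0
    else:
        a = np.exp(-k * dt)
        w1 = 1.0 / k - (1.0 - a) / (k * k * dt)
        w0 = (1.0 - a) / k - w1
    y = lfilter([w1, w0], [1.0, -a], c_fine)
    if c_fine[0] != 0.0:  # enforce y(0) = 0 exactly
        y = y - w1 * c_fine[0] * a ** np.arange(c_fine.size)
    else:
        y[0] = 0.0
    return y


def sample_shifted(t_fine: np.ndarray, table: np.ndarray, times: np.ndarray, shift: float) -> np.ndarray:
    """Linear interpolation of a fine-grid table at ``times - shift``.

    Query times before zero return 0 (inputs vanish before injection; the
    tables are cumulative quantities that are 0 at t = 0).
    """
    q = np.asarray(times, dtype=float) - shift
    return np.where(q > 0, np.interp(np.clip(q, 0.0, None), t_fine, table), 0.0)


def _prepare_input(
    input_function: InputFunction, schedule: FrameSchedule, fine_dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if input_function.coverage_end() + 1e-6 < schedule.end_time:
        raise CoverageError(
            f"input function covers {input_function.coverage_end():g} s "
            f"but the schedule extends to {schedule.end_time:g} s"
        )
    t_fine = fine_time_grid(schedule.end_time, fine_dt)
    c_wb, c_p = input_function.sample_fine(t_fine)
    return t_fine, c_wb, c_p


def _frame_average(t_fine: np.ndarray, q_fine: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    out = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.frame_start, schedule.frame_duration)):
        sel = (t_fine >= s - 1e-12) & (t_fine <= s + d + 1e-12)
        out[i] = np.trapezoid(q_fine[sel], t_fine[sel]) / (t_fine[sel][-1] - t_fine[sel][0])
    return out


def _aath_components(
    params: AATHParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    fine_dt: float,
    frame_average: bool,
) -> tuple[np.ndarray, np.ndarray]:
    t_fine, c_wb, c_p = _prepare_input(input_function, schedule, fine_dt)
    cum_wb = cumulative_input_integral(t_fine, c_wb)
    conv = exp_convolution(t_fine, c_p, params.k2 / 60.0)
    times = t_fine if frame_average else schedule.mid_times
    vasc = (params.cbf / 60.0) * (
        sample_shifted(t_fine, cum_wb, times, params.td) - sample_shifted(t_fine, cum_wb, times, params.td + params.tc)
    )
    extra = (params.k1 / 60.0) * sample_shifted(t_fine, conv, times, params.td + params.tc)
    if frame_average:
        vasc = _frame_average(t_fine, vasc, schedule)
        extra = _frame_average(t_fine, extra, schedule)
    return vasc, extra


def generate_aath_tac(
    params: AATHParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    fine_dt: float = DEFAULT_FINE_DT,
    frame_average: bool = False,
) -> TimeSeriesCurve:
    """Noiseless AATH tissue curve sampled at frame mid-times.

    ``frame_average=True`` instead averages the fine-grid model curve within
    each frame (simulation realism; fitting uses mid-time sampling).
    """
    vasc, extra = _aath_components(params, input_function, schedule, fine_dt, frame_average)
    return TimeSeriesCurve(schedule, vasc + extra, label="aath_model")


def generate_s1tc_tac(
    params: S1TCParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    fine_dt: float = DEFAULT_FINE_DT,
    frame_average: bool = False,
) -> TimeSeriesCurve:
    """Noiseless S1TC tissue curve: vb*C_wb(t-td) + K1*(parent plasma (*) exp(-k2 t))."""
    t_fine, c_wb, c_p = _prepare_input(input_function, schedule, fine_dt)
    conv = exp_convolution(t_fine, c_p, params.k2 / 60.0)
    times = t_fine if frame_average else schedule.mid_times
    vasc = params.vb * sample_shifted(t_fine, c_wb, times, params.td)
    extra = (params.k1 / 60.0) * sample_shifted(t_fine, conv, times, params.td)
    if frame_average:
        vasc = _frame_average(t_fine, vasc, schedule)
        extra = _frame_average(t_fine, extra, schedule)
    return TimeSeriesCurve(schedule, vasc + extra, label="s1tc_model")


def decompose_aath_tac(
    params: AATHParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    fine_dt: float = DEFAULT_FINE_DT,
) -> ModelCurveDecomposition:
    """Split the fitted AATH curve into its intravascular (CBF-term) and
    extravascular tissue (K1-term) components; their sum is the total curve."""
    vasc, extra = _aath_components(params, input_function, schedule, fine_dt, frame_average=False)
    return ModelCurveDecomposition(
        total=TimeSeriesCurve(schedule, vasc + extra, label="total"),
        intravascular=TimeSeriesCurve(schedule, vasc, label="intravascular"),
        extravascular=TimeSeriesCurve(schedule, extra, label="extravascular"),
    )


# ---------------------------------------------------------------------------
# Derived parameters (Renkin-Crone)


def extraction_to_ps(e: float | np.ndarray, cbf: float | np.ndarray) -> float | np.ndarray:
    """PS = -CBF * ln(1 - E); indeterminate (inf) at E = 1."""
    e = np.asarray(e, dtype=float)
    with np.errstate(divide="ignore"):
        out = -np.asarray(cbf, dtype=float) * np.log1p(-e)
    return float(out) if out.ndim == 0 else out


def ps_to_extraction(ps: float | np.ndarray, cbf: float | np.ndarray) -> float | np.ndarray:
    """E = 1 - exp(-PS/CBF) (Renkin-Crone)."""
    out = -np.expm1(-np.asarray(ps, dtype=float) / np.asarray(cbf, dtype=float))
    return float(out) if out.ndim == 0 else out


def derive_parameters(params: AATHParams) -> DerivedParams:
    """Extraction fraction, PS, blood volume and distribution volume from an AATH fit.

    PS is flagged indeterminate when E == 1 (freely diffusible tracer), where
    the Renkin-Crone relation has no finite solution.
    """
    if params.cbf <= 0:
        raise ValueError("CBF must be positive to derive E and PS")
    e = params.k1 / params.cbf
    if e > 1 + 1e-9:
        raise ValueError("E = K1/CBF must not exceed 1")
    e = min(e, 1.0)
    indeterminate = e >= 1.0
    ps = float("inf") if indeterminate else float(extraction_to_ps(e, params.cbf))
    vb = params.cbf * params.tc / 60.0  # ml/min/cm^3 * s -> ml/cm^3
    ve = params.k1 / params.k2 if params.k2 > 0 else None
    return DerivedParams(e=e, ps=ps, vb=vb, ve=ve, ps_indeterminate=indeterminate)
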