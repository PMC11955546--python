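"""Michaelis-Menten facilitative-transporter kinetics linking PS to glucose.

For a glucose-competitive tracer such as FDG, the blood-brain-barrier PS
follows a non-saturable Michaelis-Menten transport model

    PS = Vmax / (Km + (Km/Km_glc) [Glc]) + Kd

with Vmax the maximal transport rate (umol/min/cm^3), Km the tracer half-
saturation constant (mmol/l), Km/Km_glc the ratio of half-saturation
constants between the tracer and glucose, [Glc] the blood glucose
concentration (mmol/l) and Kd the non-saturable (diffusive) transport rate
(ml/min/cm^3).  Note the unit coherence: 1 umol/min/cm^3 divided by
1 mmol/l equals 1 ml/min/cm^3.  Kd is fixed (default 0.022 ml/min/cm^3)
because clinical glucose ranges are too narrow to identify it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["MMParams", "glucose_mgdl_to_mmoll", "mm_model", "fit_mm"]

GLUCOSE_MOLAR_MASS = 180.182  # g/mol


def glucose_mgdl_to_mmoll(value: float | np.ndarray) -> float | np.ndarray:
    """Convert blood glucose from mg/dl to mmol/l (divide by 18.0182)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glucose concentration must be >= 0")
    out = arr / (GLUCOSE_MOLAR_MASS / 10.0)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass(frozen=True)
class MMParams:
    """Fitted Michaelis-Menten transport parameters."""

    vmax: float  # umol/min/cm^3
    km: float  # mmol/l
    km_ratio: float  # Km / Km,glc, unitless
    kd: float = 0.022  # ml/min/cm^3, fixed

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0 or self.km_ratio <= 0:
            raise ValueError("Vmax, Km and Km_ratio must be positive")
        if self.kd < 0:
            raise ValueError("Kd must be >= 0")


def mm_model(params: MMParams, glc: float | np.ndarray) -> float | np.ndarray:
    """PS (ml/min/cm^3) at blood glucose ``glc`` (mmol/l).

    Monotone nonincreasing in glucose with asymptote Kd; at glc = 0 the
    saturable term peaks at Vmax/Km.
    """
    g = np.asarray(glc, dtype=float)
    if np.any(g < 0):
        raise ValueError("glucose concentration must be >= 0")
    out = params.vmax / (params.km + params.km_ratio * g) + params.kd
    return float(out) if np.isscalar(glc) or g.ndim == 0 else out


@dataclass
class MMFit:
    """Fit outcome: estimated parameters plus diagnostics."""

    params: MMParams
    residuals: np.ndarray
    rss: float
    converged: bool
    n_iterations: int


def fit_mm(
    ps_values: np.ndarray,
    glc_values: np.ndarray,
    fixed_kd: float = 0.022,
    init: tuple[float, float, float] = (1.0, 5.0, 1.0),
    max_iter: int = 100,
) -> MMFit:
    """Least-squares fit of (Vmax, Km, Km_ratio) with Kd fixed.

    A Levenberg-Marquardt solver starts from (1.0 umol/min/cm^3, 5.0 mmol/l,
    1.0) and runs at most ``max_iter`` function evaluations.  Note that the
    model is invariant under a common rescaling of (Vmax, Km, Km_ratio), so
    only the ratios Vmax/Km (the zero-glucose saturable transport) and
    Km/Km_ratio (the glucose half-saturation constant Km_glc) are
    structurally identifiable; the absolute scale of the reported triple is
    set by the initial values, as in the reference procedure.
    Non-convergence is flagged in the result, not raised.
    """
    ps = np.asarray(ps_values, dtype=float)
    glc = np.asarray(glc_values, dtype=float)
    if ps.shape != glc.shape or ps.ndim != 1:
        raise ValueError("ps_values and glc_values must be 1-D and equal-length")
    if ps.size < 4:
        raise ValueError("at least 4 observations are required to fit 3 parameters")
    if np.ptp(glc) <= 1e-12:
        raise ValueError("glucose values are degenerate (all equal); Km is unidentifiable")

    def residual(p: np.ndarray) -> np.ndarray:
        vmax, km, ratio = p
        return vmax / (km + ratio * glc) + fixed_kd - ps

    sol = least_squares(residual, np.asarray(init, dtype=float), method="lm", max_nfev=max_iter)
    vmax, km, ratio = sol.x
    if min(vmax, km, ratio) <= 0:
        raise ValueError("fit left the physical domain (nonpositive Vmax, Km or Km_ratio)")
    params = MMParams(vmax=float(vmax), km=float(km), km_ratio=float(ratio), kd=fixed_kd)
    res = residual(sol.x)
    return MMFit(
        params=params,
        residuals=res,
        rss=float(np.sum(res**2)),
        converged=bool(sol.status > 0),
        n_iterations=int(sol.nfev),
    )
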