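"""Time-correlation analysis: DLS cumulants, two-mode stretched fits, NSE.

DLS measures the intensity autocorrelation g₂(q,t), related to the field
correlation by the Siegert relation g₂ = b + a·g₁².  All fit models here are
written for g₁ and squared inside the fit, so contrast a and baseline b are
determined in the same error-weighted least-squares step as the physical
parameters:

* second-order cumulant fit  g₁ = exp(−t/τ₀ + µt²/2), polydispersity
  σ* = sqrt(µ)·τ₀;
* single-exponential fit for robust gradient-diffusion rates;
* two-mode stretched-exponential (KWW) fit for crowded samples with a fast
  collective mode and a slow structural mode.

NSE supplies the normalized intermediate scattering function I(q,t)/I(q,0)
directly; its initial slope gives the short-time diffusion function
D(q) = 1/(τ_s q²).

Units: DLS lag times in µs, NSE times in ns, q in nm⁻¹ (1 Å⁻¹ = 10 nm⁻¹),
temperatures in K, viscosities in mPa·s, diffusivities in m²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann as KB
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

__all__ = [
    "Correlogram",
    "ISFCurve",
    "CumulantFit",
    "TwoModeFit",
    "FitError",
    "is_nonergodic",
    "scattering_vector",
    "cumulant_fit",
    "truncation_scan",
    "plateau_region",
    "rate_to_diffusion",
    "stokes_einstein_radius",
    "stokes_einstein_diffusion",
    "single_exponential_fit",
    "kd_regression",
    "double_stretched_fit",
    "kww_mean_time",
    "nse_initial_slope",
    "band_average_diffusion",
    "HIGH_Q_BAND_NM",
]

#: high-q band for the self-diffusion plateau, nm⁻¹ (0.18–0.22 Å⁻¹)
HIGH_Q_BAND_NM = (1.8, 2.2)

#: conversion (rate [µs⁻¹]) / (q [nm⁻¹])² → D [m²/s]
_RATE_Q_TO_M2S = 1e-12

#: baseline window; slightly above 1 tolerated for correlator artifacts
_BASELINE_BOUNDS = (0.98, 1.05)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; message carries diagnostics."""


@dataclass
class Correlogram:
    """DLS intensity correlation g₂(q,t) with instrument metadata."""

    lag_times: np.ndarray        # µs, strictly increasing
    g2_values: np.ndarray
    errors: np.ndarray
    q: float                     # nm⁻¹
    temperature: float = 298.15  # K
    solvent_viscosity: float = 1.095  # mPa·s (D₂O buffer at 25 °C)

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.g2_values = np.asarray(self.g2_values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.errors <= 0):
            raise ValueError("errors must be positive")


@dataclass
class ISFCurve:
    """Normalized NSE intermediate scattering function at one q."""

    times: np.ndarray            # ns
    isf_values: np.ndarray       # I(q,t)/I(q,0)
    errors: np.ndarray
    q: float                     # nm⁻¹

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.isf_values = np.asarray(self.isf_values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)


@dataclass
class CumulantFit:
    contrast: float
    baseline: float
    mean_rate: float             # 1/τ₀, µs⁻¹
    second_cumulant: float       # µ, µs⁻²
    sigma_star: float
    truncation_time: float
    negative_mu_clipped: bool = False

    @property
    def tau0(self) -> float:
        return 1.0 / self.mean_rate


@dataclass
class TwoModeFit:
    contrast: float
    baseline: float
    fast_fraction: float         # c
    tau1: float                  # µs
    alpha1: float
    tau2: float                  # µs
    alpha2: float
    mode_collapse: bool = False

    @property
    def mean_slow_time(self) -> float:
        return kww_mean_time(self.tau2, self.alpha2)


def is_nonergodic(
    corr: Correlogram,
    min_intercept: float = 0.3,
    max_baseline_offset: float = 0.05,
) -> bool:
    """Heuristic flag for samples at the onset of dynamical arrest.

    A nonergodic DLS sample shows a low intercept (frozen-in speckle) and a
    baseline that never settles to 1 within the measured lag range; such
    correlograms must be excluded from ergodic fitting.  Checks the apparent
    intercept g₂(t→0) − 1 against ``min_intercept`` and the mean of the last
    decade of lags against 1 ± ``max_baseline_offset``.
    """
    intercept = float(np.median(corr.g2_values[:5])) - 1.0
    tail = corr.g2_values[corr.lag_times >= corr.lag_times[-1] / 10.0]
    baseline_offset = abs(float(np.mean(tail)) - 1.0)
    return intercept < min_intercept or baseline_offset > max_baseline_offset


def scattering_vector(theta_deg: float, wavelength_nm: float, refractive_index: float = 1.33) -> float:
    """q = 4πn·sin(θ/2)/λ in nm⁻¹ for scattering angle θ in degrees."""
    if not (0.0 < theta_deg < 180.0):
        raise ValueError("scattering angle must be in (0, 180) degrees")
    return 4.0 * math.pi * refractive_index * math.sin(math.radians(theta_deg) / 2.0) / wavelength_nm


def _weighted_fit(model, x0, bounds, t, y, sigma, label):
    def resid(p):
        return (model(p, t) - y) / sigma

    best = None
    for start in x0 if isinstance(x0, list) else [x0]:
        try:
            res = least_squares(resid, start, bounds=bounds, max_nfev=20000)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError(f"{label}: no converged solution")
    return best


def cumulant_fit(corr: Correlogram, truncation_time: float) -> CumulantFit:
    """Second-order cumulant analysis of g₂ truncated at ``truncation_time``.

    Error-weighted least squares of b + a·exp(−t/τ₀ + µt²/2)² on
    t ≤ truncation_time.  A negative second cumulant is clipped to σ* = 0
    and flagged rather than propagated as an imaginary width.
    """
    mask = corr.lag_times <= truncation_time
    if mask.sum() < 10:
        raise ValueError("need ≥ 10 points below the truncation time")
    t = corr.lag_times[mask]
    y = corr.g2_values[mask]
    s = corr.errors[mask]

    # log-linear initialization for the rate
    amp0 = max(y[0] - 1.0, 0.05)
    decayed = y - 1.0
    pos = decayed > 0.05 * amp0
    slope = np.polyfit(t[pos], np.log(decayed[pos]), 1)[0] if pos.sum() > 2 else -1.0 / t[-1]
    rate0 = max(-0.5 * slope, 1e-6 / t[-1])

    def model(p, tt):
        a, b, rate, mu = p
        arg = 2.0 * (-rate * tt + 0.5 * mu * tt**2)
        return b + a * np.exp(np.clip(arg, -700.0, 50.0))

    lo = [1e-4, _BASELINE_BOUNDS[0], rate0 * 1e-3, -10.0 * rate0**2]
    hi = [1.3, _BASELINE_BOUNDS[1], rate0 * 1e3, 10.0 * rate0**2]
    starts = [[amp0, 1.0, rate0 * f, 0.01 * rate0**2] for f in (0.5, 1.0, 2.0)]
    res = _weighted_fit(model, starts, (lo, hi), t, y, s, "cumulant_fit")
    a, b, rate, mu = res.x
    clipped = mu < 0
    sigma_star = 0.0 if clipped else math.sqrt(mu) / rate
    return CumulantFit(a, b, rate, mu, sigma_star, truncation_time, clipped)


def truncation_scan(corr: Correlogram, truncation_times) -> list[CumulantFit]:
    """Cumulant fit at each truncation time (the robustness scan)."""
    truncation_times = np.asarray(truncation_times, dtype=float)
    if len(truncation_times) < 3:
        raise ValueError("need at least 3 truncation times")
    return [cumulant_fit(corr, tc) for tc in truncation_times]


def plateau_region(fits: list[CumulantFit], rel_tol: float = 0.10) -> tuple[float, float] | None:
    """Truncation window where σ* is stable within ``rel_tol`` over a factor 2.

    Returns (t_lo, t_hi) of the widest such window, or None if σ* never
    plateaus (e.g. a second decay keeps inflating the apparent width).
    """
    times = np.array([f.truncation_time for f in fits])
    sig = np.array([f.sigma_star for f in fits])
    best = None
    for i in range(len(times)):
        for j in range(i + 1, len(times)):
            if times[j] < 2.0 * times[i]:
                continue
            window = sig[i : j + 1]
            mid = np.median(window)
            if mid > 0 and np.all(np.abs(window - mid) <= rel_tol * mid):
                if best is None or times[j] / times[i] > best[1] / best[0]:
                    best = (times[i], times[j])
    return best


def rate_to_diffusion(rate_per_us: float, q_nm: float) -> float:
    """D = rate/q² with rate in µs⁻¹ and q in nm⁻¹, returned in m²/s."""
    if not q_nm > 0:
        raise ValueError("q must be positive")
    return rate_per_us / q_nm**2 * _RATE_Q_TO_M2S


def stokes_einstein_radius(d_m2s: float, temperature_k: float, eta_mpas: float) -> float:
    """Hydrodynamic radius R_h = k_BT/(6πηD) in nm."""
    if min(d_m2s, temperature_k, eta_mpas) <= 0:
        raise ValueError("all arguments must be positive")
    r_m = KB * temperature_k / (6.0 * math.pi * eta_mpas * 1e-3 * d_m2s)
    return r_m * 1e9


def stokes_einstein_diffusion(radius_nm: float, temperature_k: float, eta_mpas: float) -> float:
    """Inverse of :func:`stokes_einstein_radius`: D in m²/s from R_h in nm."""
    if min(radius_nm, temperature_k, eta_mpas) <= 0:
        raise ValueError("all arguments must be positive")
    return KB * temperature_k / (6.0 * math.pi * eta_mpas * 1e-3 * radius_nm * 1e-9)


def single_exponential_fit(corr: Correlogram) -> tuple[float, float, float]:
    """Fit g₂ = b + a·exp(−2t/τ₁); returns (rate 1/τ₁ [µs⁻¹], a, b)."""
    t, y, s = corr.lag_times, corr.g2_values, corr.errors
    amp0 = max(y[0] - 1.0, 0.05)
    decayed = y - 1.0
    pos = decayed > 0.05 * amp0
    slope = np.polyfit(t[pos], np.log(decayed[pos]), 1)[0] if pos.sum() > 2 else -1.0 / t[-1]
    rate0 = max(-0.5 * slope, 1e-6 / t[-1])

    def model(p, tt):
        a, b, rate = p
        return b + a * np.exp(-2.0 * rate * tt)

    lo = [1e-4, _BASELINE_BOUNDS[0], rate0 * 1e-3]
    hi = [1.3, _BASELINE_BOUNDS[1], rate0 * 1e3]
    starts = [[amp0, 1.0, rate0 * f] for f in (0.3, 1.0, 3.0)]
    res = _weighted_fit(model, starts, (lo, hi), t, y, s, "single_exponential_fit")
    a, b, rate = res.x
    return rate, a, b


def kd_regression(concentrations, diffusivities, errors=None) -> dict:
    """Linear virial fit D = D₀(1 + K_d·c).

    Returns D₀ [m²/s], K_d [mL/mg] and the 1σ confidence interval on K_d
    from the weighted regression covariance (delta method for the ratio
    slope/intercept).
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(diffusivities, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    w = np.ones_like(d) if errors is None else 1.0 / np.asarray(errors) ** 2
    # weighted linear regression d = p0 + p1 c
    a_mat = np.column_stack([np.ones_like(c), c])
    wa = a_mat * w[:, None]
    cov = np.linalg.inv(a_mat.T @ wa)
    p = cov @ (wa.T @ d)
    resid = d - a_mat @ p
    dof = max(len(c) - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = cov * s2 if errors is None else cov
    d0, slope = p
    kd = slope / d0
    var_kd = (
        cov[1, 1] / d0**2
        - 2.0 * slope * cov[0, 1] / d0**3
        + slope**2 * cov[0, 0] / d0**4
    )
    err = math.sqrt(max(var_kd, 0.0))
    return {"D0": float(d0), "Kd": float(kd), "Kd_err": err}


def double_stretched_fit(corr: Correlogram, pin_alpha1: bool = True) -> TwoModeFit:
    """Two-mode stretched-exponential fit of g₂ for crowded samples.

    g₂ = b + a·(c·exp[−(t/τ₁)^α₁] + (1−c)·exp[−(t/τ₂)^α₂])², error-weighted,
    initialized from a grid of log-spaced rate splits.  The fast exponent α₁
    is pinned to 1 by default (the fast collective mode is diffusive); pass
    ``pin_alpha1=False`` to free it.  Fits where the two times collapse
    (τ₂/τ₁ < 3) are flagged ``mode_collapse``.
    """
    t, y, s = corr.lag_times, corr.g2_values, corr.errors
    span = t[-1] / t[0]
    if span < 1e4:
        raise ValueError("correlogram must span at least 4 decades in lag time")
    amp0 = max(y[0] - 1.0, 0.05)

    # crude overall decay time for initialization
    decayed = (y - 1.0) / amp0
    half = t[np.searchsorted(-decayed, -0.5)] if np.any(decayed < 0.5) else t[len(t) // 2]

    def model(p, tt):
        a, b, c, lt1, a1, lt2, a2 = p
        g1 = c * np.exp(-((tt / 10.0**lt1) ** a1)) + (1 - c) * np.exp(
            -((tt / 10.0**lt2) ** a2)
        )
        return b + a * g1**2

    a1_lo, a1_hi = (1.0 - 1e-9, 1.0 + 1e-9) if pin_alpha1 else (0.3, 2.0)
    lo = [1e-4, _BASELINE_BOUNDS[0], 0.0, math.log10(t[0]), a1_lo, math.log10(t[0]), 0.2]
    hi = [1.3, _BASELINE_BOUNDS[1], 1.0, math.log10(t[-1]), a1_hi, math.log10(t[-1]) + 1, 2.0]
    starts = []
    for split in (0.5, 1.5, 2.5):
        starts.append(
            [amp0, 1.0, 0.5, math.log10(half) - split / 2, 1.0, math.log10(half) + split, 0.7]
        )
    for frac in (0.3, 0.7):
        starts.append(
            [amp0, 1.0, frac, math.log10(half) - 1.0, 1.0, math.log10(half) + 1.5, 0.7]
        )
    res = _weighted_fit(model, starts, (lo, hi), t, y, s, "double_stretched_fit")
    a, b, c, lt1, a1, lt2, a2 = res.x
    tau1, tau2 = 10.0**lt1, 10.0**lt2
    if tau2 < tau1:  # canonical ordering: mode 2 is the slow one
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
        c = 1.0 - c
    collapse = tau2 / tau1 < 3.0
    return TwoModeFit(a, b, c, tau1, 1.0 if pin_alpha1 else a1, tau2, a2, collapse)


def kww_mean_time(tau: float, alpha: float) -> float:
    """Mean relaxation time of exp[−(t/τ)^α]: τ̄ = (τ/α)·Γ(1/α)."""
    if not alpha > 0:
        raise ValueError("stretching exponent must be positive")
    return tau / alpha * gamma_fn(1.0 / alpha)


def nse_initial_slope(isf: ISFCurve, t_max: float = 50.0) -> tuple[float, float]:
    """Initial-slope relaxation time and D(q) from an NSE curve.

    Single-exponential fit A·exp(−t/τ_s) restricted to t < ``t_max`` (ns);
    returns (τ_s [ns], D(q) [m²/s]) with D = 1/(τ_s q²) for q in nm⁻¹.
    """
    mask = isf.times < t_max
    if mask.sum() < 5:
        raise ValueError(f"need ≥ 5 points below t_max={t_max} ns")
    t = isf.times[mask]
    y = isf.isf_values[mask]
    s = isf.errors[mask]

    def model(p, tt):
        amp, rate = p
        return amp * np.exp(-rate * tt)

    pos = y > 0.05
    slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0] if pos.sum() > 2 else -0.01
    rate0 = max(-slope, 1e-5)
    res = _weighted_fit(
        model, [[1.0, rate0]], ([0.5, rate0 * 1e-3], [1.5, rate0 * 1e3]),
        t, y, s, "nse_initial_slope",
    )
    amp, rate = res.x
    tau_s = 1.0 / rate
    d = rate / isf.q**2 * 1e-9  # nm²/ns → m²/s
    return tau_s, d


def band_average_diffusion(q_values, d_values, d_errors, q_band) -> tuple[float, float]:
    """Inverse-variance-weighted mean of D(q) over a q band.

    ``q_band`` is (q_lo, q_hi) in the same units as ``q_values``; returns the
    weighted mean and its standard error.
    """
    q = np.asarray(q_values, dtype=float)
    d = np.asarray(d_values, dtype=float)
    e = np.asarray(d_errors, dtype=float)
    mask = (q >= q_band[0]) & (q <= q_band[1])
    if mask.sum() < 1:
        raise ValueError("no points in the requested q band")
    w = 1.0 / e[mask] ** 2
    mean = float(np.sum(w * d[mask]) / np.sum(w))
    err = float(1.0 / math.sqrt(np.sum(w)))
    return mean, err
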