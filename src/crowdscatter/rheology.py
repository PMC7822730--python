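"""Tracer microrheology, viscosity divergence, and voluminosity estimates.

Large sterically stabilized tracer beads (300 nm polystyrene) dominate the
DLS signal in a protein solution; their diffusion gives the zero-shear
viscosity of the surrounding medium through Stokes–Einstein.  The relative
viscosity η_r = η₀/η_s diverges toward dynamical arrest as a power law

    η_r = (1 − c/c*)^(−γ),

whose critical concentration c* and exponent γ are fitted in log space.
Normalized slow DLS relaxation times τ̄/τ₀ collapse onto the same law and
may be fitted alongside the microrheology data.

The effective voluminosity ν_eff (mL/g), converting weight concentration to
volume fraction φ = c·ν_eff, is estimated two ways: from random close
packing at the arrest concentration (0.64/c*), and from the z-average
hydrodynamic radius with the Schulz moment relations and the molar mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro
from scipy.optimize import least_squares

from .correlations import (
    Correlogram,
    rate_to_diffusion,
    single_exponential_fit,
    stokes_einstein_radius,
)
from .schulz import SchulzDistribution, intensity_avg_rh, schulz_moment

__all__ = [
    "ViscositySeries",
    "ArrestFit",
    "tracer_viscosity",
    "relative_viscosity",
    "arrest_powerlaw_fit",
    "voluminosity_estimates",
    "ARREST_VOLUME_FRACTION",
    "TRACER_RADIUS_NM",
]

#: random-close-packing volume fraction where mildly attractive spheres arrest
ARREST_VOLUME_FRACTION = 0.64

#: default DLS tracer radius (300 nm diameter polystyrene beads), nm
TRACER_RADIUS_NM = 150.0


@dataclass
class ViscositySeries:
    """Relative viscosity η_r(c) with 1σ errors."""

    concentrations: np.ndarray   # mg/mL
    relative_viscosities: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.relative_viscosities = np.asarray(self.relative_viscosities, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if np.any(self.relative_viscosities < 1.0 - 1e-6):
            raise ValueError("relative viscosity below 1 is unphysical")


@dataclass
class ArrestFit:
    c_star: float                # mg/mL
    gamma: float
    c_star_err: float
    gamma_err: float

    @property
    def near_hard_sphere(self) -> bool:
        """γ < 3 is the hard-sphere-like arrest signature; larger exponents
        indicate significantly increased attraction."""
        return self.gamma < 3.0


def tracer_viscosity(
    corr: Correlogram,
    tracer_radius_nm: float = TRACER_RADIUS_NM,
) -> float:
    """Zero-shear viscosity (mPa·s) from a tracer-bead correlogram.

    Single-exponential fit → tracer diffusivity → Stokes–Einstein with the
    known tracer radius.  A poor single-exponential residual (two-mode
    signature from protein scattering leaking past the tracers) raises
    ValueError.
    """
    rate, a, b = single_exponential_fit(corr)
    model = b + a * np.exp(-2.0 * rate * corr.lag_times)
    chi2 = float(np.mean(((corr.g2_values - model) / corr.errors) ** 2))
    if chi2 > 25.0:
        raise ValueError(
            f"correlogram is not single-mode (reduced χ² = {chi2:.1f}); "
            "protein scattering may dominate the tracer signal"
        )
    d = rate_to_diffusion(rate, corr.q)
    # η from R_h = k_BT/(6πηD) inverted for η
    return (
        stokes_einstein_radius(d, corr.temperature, 1.0) / tracer_radius_nm
    )


def relative_viscosity(eta0: float, eta_s: float) -> float:
    """η_r = η₀/η_s (any common unit)."""
    if min(eta0, eta_s) <= 0:
        raise ValueError("viscosities must be positive")
    return eta0 / eta_s


def arrest_powerlaw_fit(
    series: ViscositySeries,
    c_star_guess: float | None = None,
) -> ArrestFit:
    """Fit the arrest power law η_r = (1 − c/c*)^(−γ) in log space.

    Both c* and γ are free; fitting log η_r = −γ·log(1 − c/c*) with errors
    propagated to log space stabilizes the divergence.  Normalized slow
    relaxation times τ̄/τ₀ may be passed as η_r-equivalent data.
    """
    c = series.concentrations
    y = series.relative_viscosities
    if len(c) < 5:
        raise ValueError("need at least 5 concentrations")
    if y.max() / max(y.min(), 1e-12) < 10.0:
        raise ValueError("viscosity series must span at least a decade")
    c_max = float(c.max())
    if c_star_guess is None:
        c_star_guess = 1.1 * c_max
    if c_star_guess <= c_max:
        raise ValueError("initial c* must exceed the largest concentration")
    log_y = np.log(y)
    sigma_log = series.errors / y

    def resid(p):
        c_star, gamma = p
        return (-gamma * np.log1p(-c / c_star) - log_y) / np.maximum(sigma_log, 1e-12)

    res = least_squares(
        resid,
        [c_star_guess, 2.5],
        bounds=([c_max * 1.0000001, 0.1], [c_max * 10.0, 10.0]),
        max_nfev=10000,
    )
    c_star, gamma = res.x
    # 1σ errors from the Jacobian
    dof = max(len(c) - 2, 1)
    cost = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * cost
        errs = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        errs = np.array([float("nan"), float("nan")])
    return ArrestFit(float(c_star), float(gamma), float(errs[0]), float(errs[1]))


def voluminosity_estimates(
    c_arrest: float,
    dist: SchulzDistribution,
    rh_z: float,
    mw_kda: float,
    chosen: float = 1.7,
) -> dict:
    """Two independent voluminosity estimates and the adopted value (mL/g).

    * packing estimate: arrest at random close packing, ν = 0.64/c*;
    * hydrodynamic estimate: scale the Schulz distribution so its z-average
      hydrodynamic radius ⟨R⁶⟩/⟨R⁵⟩ equals ``rh_z`` (nm), take the mean
      sphere volume V = (4π/3)⟨R³⟩, and divide by the molar mass:
      ν = V·N_A/M_w.

    Returns the two estimates, the mean sphere volume in nm³, and the chosen
    intermediate ν_eff (default 1.7 mL/g).
    """
    if min(c_arrest, rh_z, mw_kda) <= 0:
        raise ValueError("all inputs must be positive")
    packing = ARREST_VOLUME_FRACTION / c_arrest * 1000.0  # (mg/mL)⁻¹ → mL/g

    unit = SchulzDistribution(1.0, dist.sigma_star)
    mean_r = rh_z / intensity_avg_rh(unit)
    scaled = SchulzDistribution(mean_r, dist.sigma_star)
    v_nm3 = 4.0 * math.pi / 3.0 * schulz_moment(scaled, 3)
    # nm³ → mL: 1 nm³ = 1e-21 mL; M_w in g/mol
    hydro = v_nm3 * 1e-21 * Avogadro / (mw_kda * 1000.0)
    return {
        "packing_mL_g": packing,
        "hydrodynamic_mL_g": hydro,
        "mean_volume_nm3": v_nm3,
        "chosen_mL_g": chosen,
    }
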