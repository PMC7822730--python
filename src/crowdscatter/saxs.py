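"""SAXS-side analysis: Guinier radius, experimental S(q), form-factor fits.

The dilute-solution curve I₀(q) gives the form factor; dividing a crowded
curve by it (concentration-normalized) gives the experimental structure
factor S(q) = [I(q)/I₀(q)]·(c₀/c_p).  Its low-q average estimates S(0), the
reduced isothermal compressibility.  The form factor itself is fitted with
Schulz-polydisperse spheres under the constraint that the model's
intensity-averaged R_g equals the Guinier value, leaving only σ*, a scale
and a flat background free.

q is handled internally in nm⁻¹; curves declare their unit ("nm^-1" or
"A^-1", 1 Å⁻¹ = 10 nm⁻¹) in the file header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import read_columns, write_columns
from .schulz import (
    FormFactorModel,
    SchulzDistribution,
    intensity_avg_rg,
    mean_radius_from_rg,
    polydisperse_form_intensity,
)

__all__ = [
    "ScatteringCurve",
    "guinier_rg",
    "experimental_structure_factor",
    "forward_scattering",
    "constrained_form_factor_fit",
    "read_scattering_curve",
    "write_scattering_curve",
]


@dataclass
class ScatteringCurve:
    """1-D scattering curve (q, I, σ_I) with concentration metadata."""

    q: np.ndarray               # nm⁻¹, strictly increasing
    intensity: np.ndarray
    sigma: np.ndarray
    concentration: float | None = None  # mg/mL
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma_I must be positive")


def guinier_rg(curve: ScatteringCurve, qmax_rg: float = 1.0, max_iter: int = 50) -> float:
    """Radius of gyration from the Guinier law ln I = ln I(0) − q²R_g²/3.

    The fit window q·R_g ≤ ``qmax_rg`` is iterated to self-consistency.
    Non-monotone low-q data (an aggregation signature) raise ValueError.
    """
    q, i_vals = curve.q, curve.intensity
    head = i_vals[: max(4, len(q) // 10)]
    if head[0] < head[-1] and (head.argmax() not in (0, 1)):
        raise ValueError("low-q intensity rises with q: aggregation signature")
    rg = None
    mask = q <= q[max(9, len(q) // 5)]
    for _ in range(max_iter):
        if mask.sum() < 4:
            raise ValueError("too few points in the Guinier window")
        if np.any(i_vals[mask] <= 0):
            raise ValueError("non-positive intensity in the Guinier window")
        slope = np.polyfit(q[mask] ** 2, np.log(i_vals[mask]), 1)[0]
        if slope >= 0:
            raise ValueError("non-decaying low-q intensity; no Guinier regime")
        rg_new = math.sqrt(-3.0 * slope)
        new_mask = q * rg_new <= qmax_rg
        if rg is not None and abs(rg_new - rg) <= 1e-10 * rg:
            return rg_new
        if new_mask.sum() == mask.sum() and rg is not None:
            return rg_new
        rg, mask = rg_new, new_mask
    return rg


def experimental_structure_factor(
    curve: ScatteringCurve,
    formfactor_curve: ScatteringCurve,
    c_p: float | None = None,
    c0: float | None = None,
) -> ScatteringCurve:
    """Experimental structure factor S(q) = [I(q)/I₀(q)]·(c₀/c_p).

    The form-factor curve is interpolated onto the sample grid (linear in
    log I); errors from both curves propagate in quadrature.  Concentrations
    default to the curves' metadata.
    """
    c_p = curve.concentration if c_p is None else c_p
    c0 = formfactor_curve.concentration if c0 is None else c0
    if not (c_p and c0):
        raise ValueError("both concentrations must be known")
    if np.any(formfactor_curve.intensity <= 0):
        raise ValueError("form factor has non-positive intensities")
    log_i0 = np.interp(curve.q, formfactor_curve.q, np.log(formfactor_curve.intensity))
    i0 = np.exp(log_i0)
    rel_e0 = np.interp(
        curve.q,
        formfactor_curve.q,
        formfactor_curve.sigma / formfactor_curve.intensity,
    )
    s = curve.intensity / i0 * (c0 / c_p)
    sigma = np.abs(s) * np.sqrt((curve.sigma / curve.intensity) ** 2 + rel_e0**2)
    return ScatteringCurve(curve.q.copy(), s, sigma, concentration=c_p,
                           label=f"S(q) {curve.label}")


def forward_scattering(sq_curve: ScatteringCurve, n_points: int = 5) -> tuple[float, float]:
    """S(0) as the mean over the ``n_points`` lowest-q values, with std. error.

    Mirrors the simulation-side low-q plateau convention.  A low-q upturn
    (S rising toward q → 0 beyond 3σ) is flagged as an aggregation signature.
    """
    if len(sq_curve.q) < n_points:
        raise ValueError(f"need ≥ {n_points} points, curve has {len(sq_curve.q)}")
    vals = sq_curve.intensity[:n_points]
    errs = sq_curve.sigma[:n_points]
    slope = np.polyfit(sq_curve.q[:n_points], vals, 1)[0]
    dq = sq_curve.q[n_points - 1] - sq_curve.q[0]
    if slope * dq < -5.0 * float(np.mean(errs)):
        raise ValueError("low-q upturn: aggregation suspected")
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_points))


def constrained_form_factor_fit(
    curve: ScatteringCurve,
    rg_constraint: float,
    q_fit_max: float = 2.0,
) -> FormFactorModel:
    """Schulz-sphere form-factor fit constrained to a measured R_g.

    Free parameters: σ*, intensity scale, flat background.  At every step the
    number-average radius is tied to σ* so the model's intensity-averaged R_g
    equals ``rg_constraint`` (nm) exactly.  Fit range q ≤ ``q_fit_max`` nm⁻¹
    (0.2 Å⁻¹ by default), error-weighted.
    """
    mask = curve.q <= q_fit_max
    if mask.sum() < 10:
        raise ValueError("fit range contains fewer than 10 points")
    q = curve.q[mask]
    y = curve.intensity[mask]
    s = curve.sigma[mask]

    def build(sigma_star: float, scale: float, background: float) -> FormFactorModel:
        mean_r = mean_radius_from_rg(sigma_star, rg_constraint)
        return FormFactorModel(SchulzDistribution(mean_r, sigma_star), scale, background)

    def resid(p):
        sigma_star, log_scale, background = p
        model = build(sigma_star, 10.0**log_scale, background)
        return (polydisperse_form_intensity(model, q) - y) / s

    # initialize the scale from the q→0 level of a mid-σ* model
    probe = build(0.3, 1.0, 0.0)
    i0 = polydisperse_form_intensity(probe, q[:1])[0]
    scale0 = math.log10(max(y[0] / i0, 1e-30))
    best = None
    for s0 in (0.15, 0.3, 0.45):
        res = least_squares(
            resid,
            [s0, scale0, 0.0],
            bounds=([0.03, scale0 - 6, 0.0], [0.7, scale0 + 6, max(1e-12, y.min())]),
            max_nfev=4000,
        )
        if best is None or res.cost < best.cost:
            best = res
    sigma_star, log_scale, background = best.x
    model = build(sigma_star, 10.0**log_scale, background)
    assert abs(intensity_avg_rg(model.distribution) - rg_constraint) < 1e-8
    return model


def write_scattering_curve(path, curve: ScatteringCurve, q_unit: str = "nm^-1") -> None:
    q = curve.q / 10.0 if q_unit == "A^-1" else curve.q
    write_columns(
        path,
        {"q": q, "I": curve.intensity, "sigma_I": curve.sigma},
        {
            "q_unit": q_unit,
            "concentration_mg_ml": curve.concentration,
            "label": curve.label,
        },
    )


def read_scattering_curve(path) -> ScatteringCurve:
    cols, meta = read_columns(path)
    names = list(cols)
    q = cols.get("q", cols[names[0]])
    i_vals = cols.get("I", cols[names[1]])
    s = cols.get("sigma_I", cols[names[2]])
    unit = meta.get("q_unit", "nm^-1")
    if unit.lower() in ("a^-1", "å^-1", "ang^-1"):
        q = q * 10.0
    conc = meta.get("concentration_mg_ml")
    conc = None if conc in (None, "None") else float(conc)
    return ScatteringCurve(q, i_vals, s, concentration=conc, label=meta.get("label", ""))
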