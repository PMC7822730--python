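"""Synthetic-data generators with known ground truth.

Every input the analysis chain consumes can be generated here as the exact
forward model of its analysis counterpart, so noiseless generate → fit round
trips recover the truth to optimizer tolerance:

* DLS correlograms: intensity-weighted sums of exponentials over a
  discretized Schulz ensemble of diffusing spheres, squared through the
  Siegert relation, with multiplicative noise;
* two-mode stretched-exponential correlograms for crowded samples;
* SAXS curves: polydisperse sphere form factor, optionally multiplied by a
  theoretical or simulated structure factor;
* NSE curves: single-exponential decays with a configurable D(q) profile
  over the instrument's three time windows;
* viscosity series following the arrest power law, with companion tracer
  correlograms.

All randomness flows from the seed passed to each generator; regeneration
with the same arguments is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .correlations import Correlogram, ISFCurve, stokes_einstein_diffusion
from .interactions import InteractionModel, sw_structure_factor_mono
from .saxs import ScatteringCurve
from .schulz import FormFactorModel, SchulzDistribution, polydisperse_form_intensity
from .rheology import TRACER_RADIUS_NM, ViscositySeries

__all__ = [
    "GroundTruth",
    "synth_dls_correlogram",
    "synth_two_mode_correlogram",
    "synth_saxs_curve",
    "synth_nse_set",
    "synth_viscosity_series",
    "synth_tracer_correlogram",
    "NSE_SETTINGS",
]

#: NSE instrument windows: (τ_max [ns]); q-range 0.25–2.1 nm⁻¹ overall
NSE_SETTINGS = (
    {"tau_max_ns": 91.0, "q_range_nm": (1.0, 2.1)},
    {"tau_max_ns": 248.0, "q_range_nm": (0.5, 1.2)},
    {"tau_max_ns": 598.0, "q_range_nm": (0.25, 0.8)},
)


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameter set, serialized next to every synthetic dataset."""

    distribution: SchulzDistribution = SchulzDistribution(2.51, 0.475)
    d0_m2s: float = 3.04e-11
    interaction: InteractionModel = InteractionModel(
        stickiness_tau=0.774, well_depth=0.289, well_width=1.25, voluminosity=1.7
    )
    c_star: float = 360.0        # mg/mL
    gamma: float = 2.8
    temperature: float = 298.15  # K
    solvent_viscosity: float = 1.095  # mPa·s
    noise: float = 0.002         # multiplicative, dimensionless
    seed: int = 0

    def to_json(self) -> str:
        d = {
            "mean_radius_nm": self.distribution.mean_radius,
            "sigma_star": self.distribution.sigma_star,
            "d0_m2s": self.d0_m2s,
            "stickiness_tau": self.interaction.stickiness_tau,
            "well_depth_kbt": self.interaction.well_depth,
            "well_width": self.interaction.well_width,
            "voluminosity_ml_g": self.interaction.voluminosity,
            "c_star_mg_ml": self.c_star,
            "gamma": self.gamma,
            "temperature_k": self.temperature,
            "solvent_viscosity_mpas": self.solvent_viscosity,
            "noise": self.noise,
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            distribution=SchulzDistribution(d["mean_radius_nm"], d["sigma_star"]),
            d0_m2s=d["d0_m2s"],
            interaction=InteractionModel(
                stickiness_tau=d["stickiness_tau"],
                well_depth=d["well_depth_kbt"],
                well_width=d["well_width"],
                voluminosity=d["voluminosity_ml_g"],
            ),
            c_star=d["c_star_mg_ml"],
            gamma=d["gamma"],
            temperature=d["temperature_k"],
            solvent_viscosity=d["solvent_viscosity_mpas"],
            noise=d["noise"],
            seed=d["seed"],
        )


def _correlogram_noise(rng, g1_sq: np.ndarray, contrast: float, noise: float):
    """Lag-dependent multiplicative noise with a correlator floor."""
    sigma = noise * (contrast * g1_sq + 0.05 * contrast)
    return rng.standard_normal(len(g1_sq)) * sigma, np.maximum(sigma, 1e-8)


def synth_dls_correlogram(
    truth: GroundTruth,
    q_nm: float = 0.0229,
    n_points: int = 200,
    t_min_us: float = 0.1,
    t_max_us: float = 1e5,
    contrast: float = 0.95,
    baseline: float = 1.0,
    n_species: int = 64,
    noise: float | None = None,
    seed: int | None = None,
) -> Correlogram:
    """DLS correlogram of a Schulz ensemble of freely diffusing spheres.

    g₁(t) = Σ_k w_k exp(−D_k q² t) with intensity weights w_k ∝ P(R_k)·R_k⁶
    over an equal-probability discretization of the radius distribution and
    D_k from Stokes–Einstein in the solvent; g₂ = b + a·g₁² plus
    multiplicative Gaussian noise whose per-point σ is reported as the error
    column (emulating triplicate-measurement standard deviations).
    """
    noise = truth.noise if noise is None else noise
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    t = np.geomspace(t_min_us, t_max_us, n_points)

    dist = truth.distribution
    if dist.is_monodisperse:
        radii = np.array([dist.mean_radius])
        weights = np.array([1.0])
    else:
        # equal-probability bins with exact intensity (R⁶) masses; the bin's
        # representative radius is its own z-average E[R⁶]/E[R⁵], so the
        # intensity-weighted mean decay rate of the mixture matches the
        # analytic z-average ⟨R⁵⟩/⟨R⁶⟩ exactly
        from scipy.stats import gamma as _gamma_dist

        c, b = dist.shape_c, dist.scale_b
        edges = dist.quantile(np.linspace(0.0, 1.0, n_species + 1))
        edges[0], edges[-1] = 0.0, np.inf
        f5 = np.diff(_gamma_dist.cdf(edges, a=c + 5.0, scale=b))
        f6 = np.diff(_gamma_dist.cdf(edges, a=c + 6.0, scale=b))
        from .schulz import schulz_moment

        m5, m6 = schulz_moment(dist, 5), schulz_moment(dist, 6)
        radii = (m6 * f6) / (m5 * f5)
        weights = f6 / f6.sum()
    d_k = np.array(
        [
            stokes_einstein_diffusion(r, truth.temperature, truth.solvent_viscosity)
            for r in radii
        ]
    )
    rates = d_k * q_nm**2 * 1e12  # m²/s·nm⁻² → µs⁻¹
    g1 = weights @ np.exp(-np.outer(rates, t))
    g2 = baseline + contrast * g1**2
    eps, sigma = _correlogram_noise(rng, g1**2, contrast, noise)
    return Correlogram(
        t, g2 + eps, sigma, q=q_nm,
        temperature=truth.temperature, solvent_viscosity=truth.solvent_viscosity,
    )


def synth_two_mode_correlogram(
    c: float,
    tau1_us: float,
    alpha1: float,
    tau2_us: float,
    alpha2: float,
    q_nm: float = 0.22,
    n_points: int = 240,
    t_min_us: float = 0.05,
    t_max_us: float = 1e6,
    contrast: float = 0.95,
    baseline: float = 1.0,
    noise: float = 0.002,
    seed: int = 0,
) -> Correlogram:
    """Two-mode stretched-exponential correlogram (crowded-sample model)."""
    rng = np.random.default_rng(seed)
    t = np.geomspace(t_min_us, t_max_us, n_points)
    g1 = c * np.exp(-((t / tau1_us) ** alpha1)) + (1 - c) * np.exp(
        -((t / tau2_us) ** alpha2)
    )
    g2 = baseline + contrast * g1**2
    eps, sigma = _correlogram_noise(rng, g1**2, contrast, noise)
    return Correlogram(t, g2 + eps, sigma, q=q_nm)


def synth_saxs_curve(
    truth: GroundTruth,
    phi: float,
    q_grid_nm: np.ndarray,
    concentration: float | None = None,
    scale: float = 1.0,
    background: float = 0.0,
    structure: str = "none",
    structure_curve: tuple[np.ndarray, np.ndarray] | None = None,
    noise: float | None = None,
    seed: int | None = None,
) -> ScatteringCurve:
    """SAXS curve I(q) = scale·c_p·P_poly(q)·S(q) + background (+ noise).

    ``structure`` selects the interparticle term: "none" (dilute form
    factor), "theory" (monodisperse square-well RPA S(q) at φ, using the
    z-average diameter), or "edmd" (interpolate a measured S(q) passed as
    ``structure_curve`` in reduced units of the mean diameter).
    """
    noise = truth.noise if noise is None else noise
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    q = np.asarray(q_grid_nm, dtype=float)
    if concentration is None:
        nu = truth.interaction.voluminosity or 1.7
        concentration = phi / nu * 1000.0  # φ = c[mg/mL]·ν[mL/g]/1000

    model = FormFactorModel(truth.distribution, scale=scale, background=0.0)
    p_poly = polydisperse_form_intensity(model, q)
    if structure == "none" or phi == 0:
        s_q = np.ones_like(q)
    elif structure == "theory":
        d_nm = 2.0 * truth.distribution.mean_radius
        s_q = sw_structure_factor_mono(
            q, phi, truth.interaction.well_depth, truth.interaction.well_width,
            diameter=d_nm,
        )
    elif structure == "edmd":
        if structure_curve is None:
            raise ValueError('structure="edmd" requires structure_curve')
        q_red, s_red = structure_curve
        # reduced q (units of inverse mean diameter) → nm⁻¹
        q_phys = np.asarray(q_red) / (2.0 * truth.distribution.mean_radius)
        s_q = np.interp(q, q_phys, np.asarray(s_red))
    else:
        raise ValueError(f"unknown structure option {structure!r}")

    i_clean = concentration * p_poly * s_q + background
    sigma = np.maximum(noise * i_clean, 1e-12 + 0.0 * i_clean)
    i_noisy = i_clean + rng.standard_normal(len(q)) * sigma
    return ScatteringCurve(q, i_noisy, np.maximum(sigma, 1e-12),
                           concentration=concentration, label="synthetic")


def synth_nse_set(
    truth: GroundTruth,
    q_list_nm: np.ndarray | None = None,
    d_of_q=None,
    n_times: int = 40,
    noise: float | None = None,
    seed: int | None = None,
) -> list[ISFCurve]:
    """NSE intermediate-scattering-function curves over the echo windows.

    I(q,t)/I(q,0) = exp(−D(q)·q²·t) sampled on each instrument window whose
    q-range covers the requested q; ``d_of_q`` maps q [nm⁻¹] → D [m²/s]
    (default: constant D₀ with a mild low-q upturn mimicking rotational and
    internal contributions).
    """
    noise = truth.noise if noise is None else noise
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if q_list_nm is None:
        q_list_nm = np.linspace(0.3, 2.1, 10)
    if d_of_q is None:
        def d_of_q(q):
            return truth.d0_m2s * (1.0 + 0.5 * np.exp(-((q / 0.5) ** 2)))

    curves = []
    for q in np.atleast_1d(q_list_nm):
        setting = min(
            (s for s in NSE_SETTINGS if s["q_range_nm"][0] <= q <= s["q_range_nm"][1]),
            key=lambda s: s["tau_max_ns"],
            default=NSE_SETTINGS[-1],
        )
        # quasi-logarithmic echo-time grid, dense at short times
        t = np.concatenate(
            [[0.0], np.geomspace(setting["tau_max_ns"] / 300.0,
                                 setting["tau_max_ns"], n_times - 1)]
        )
        rate_ns = d_of_q(q) * q**2 * 1e9  # m²/s·nm⁻² → ns⁻¹
        isf = np.exp(-rate_ns * t)
        sigma = np.maximum(noise * (isf + 0.05), 1e-8)
        vals = isf + rng.standard_normal(len(t)) * sigma
        vals[0] = 1.0
        curves.append(ISFCurve(t, vals, sigma, q=q))
    return curves


def synth_viscosity_series(
    truth: GroundTruth,
    concentrations: np.ndarray,
    noise: float | None = None,
    seed: int | None = None,
) -> ViscositySeries:
    """Relative viscosities on the arrest power law with multiplicative noise."""
    noise = truth.noise if noise is None else noise
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    if np.any(c >= truth.c_star):
        raise ValueError("concentrations must stay below c*")
    eta_r = (1.0 - c / truth.c_star) ** (-truth.gamma)
    sigma = np.maximum(noise * eta_r, 1e-12)
    vals = np.maximum(eta_r + rng.standard_normal(len(c)) * sigma, 1.0)
    return ViscositySeries(c, vals, sigma)


def synth_tracer_correlogram(
    truth: GroundTruth,
    eta_mpas: float,
    q_nm: float | None = None,
    tracer_radius_nm: float = TRACER_RADIUS_NM,
    n_points: int = 200,
    noise: float | None = None,
    seed: int | None = None,
) -> Correlogram:
    """Correlogram of tracer beads diffusing in a medium of viscosity η.

    Default geometry: θ = 90°, λ = 632.8 nm, n = 1.33.
    """
    from .correlations import scattering_vector

    noise = truth.noise if noise is None else noise
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if q_nm is None:
        q_nm = scattering_vector(90.0, 632.8, 1.33)
    d = stokes_einstein_diffusion(tracer_radius_nm, truth.temperature, eta_mpas)
    rate = d * q_nm**2 * 1e12  # µs⁻¹
    t = np.geomspace(0.01 / rate, 20.0 / rate, n_points)
    g1 = np.exp(-rate * t)
    contrast = 0.95
    g2 = 1.0 + contrast * g1**2
    eps, sigma = _correlogram_noise(rng, g1**2, contrast, noise)
    return Correlogram(t, g2 + eps, sigma, q=q_nm, temperature=truth.temperature,
                       solvent_viscosity=eta_mpas)
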