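# crowdscatter

Colloidal multiscale analysis of crowded protein solutions — from dilute
characterization to dynamical arrest.

Concentrated solutions of polydisperse protein oligomers (the motivating
system is the βH fraction of eye-lens crystallins, reaching several hundred
mg/mL in vivo) can be described remarkably well as a colloidal fluid of
polydisperse hard spheres with a weak short-range attraction. This package
implements the full analysis chain that builds and tests that description:

* **Schulz polydispersity & scattering theory** — the gamma-type radius
  distribution P(R) with normalized width σ*, its moments
  ⟨Rⁿ⟩ = ⟨R⟩ⁿσ*²ⁿΓ(n+1/σ*²)/Γ(1/σ*²), the intensity-averaged radii
  R_h = ⟨R⁶⟩/⟨R⁵⟩ and R_g = √(3⟨R⁸⟩/5⟨R⁶⟩), Perrin ellipsoid friction
  factors, the R_h/R_g shape–polydispersity map, and the polydisperse
  sphere form factor used to fit dilute SAXS curves.
* **Interaction theory** — Baxter sticky-hard-sphere relations for gradient
  diffusion K_d = (1.454 − 1.125/τ)ν_eff, the normalized second virial
  coefficient B₂/B₂(HS) = 1 − 1/4τ, the short-time self-diffusion slope
  1.8315 + 0.295/τ, square-well virial equivalents, Carnahan–Starling and
  polydisperse (BMCSL) compressibility S(0), and Percus–Yevick structure
  factors (analytic hard-sphere and numeric square-well).
* **Event-driven molecular dynamics** — exact piecewise-ballistic dynamics
  of N polydisperse spheres with a square well (depth u in k_BT, range
  λ×contact), conserving energy to round-off; effective structure factors
  S_M(q) weighted by per-particle sphere amplitudes, S(0) from the low-q
  plateau, pressure from the collision virial.
* **Correlation fitting** — DLS cumulant analysis with truncation-time
  scans, single-exponential and two-mode stretched-exponential (KWW) fits
  through the Siegert relation, K_d virial regression, NSE initial-slope
  diffusion D(q) = 1/(τ_s q²) and band averages.
* **Microrheology & arrest** — tracer-bead viscometry via Stokes–Einstein,
  the arrest power law η_r = (1 − c/c*)^(−γ), and two independent
  voluminosity estimates converting mg/mL to volume fraction.
* **Synthetic data** — exact forward models for every input (correlograms,
  SAXS curves, NSE curves, viscosity series) with known ground truth and
  seeded, bit-reproducible noise.

## Worked example

```python
import numpy as np
import crowdscatter as cs

# dilute-solution DLS: cumulant fit of a synthetic correlogram
truth = cs.GroundTruth()            # R̄ = 2.51 nm, σ* = 0.475, D₂O at 25 °C
corr = cs.synth_dls_correlogram(truth, seed=5)
fit = cs.cumulant_fit(corr, truncation_time=100.0)
d0 = cs.rate_to_diffusion(fit.mean_rate, corr.q)
print(f"rate = {fit.mean_rate:.5f}/us, D0 = {d0:.3e} m2/s,",
      f"Rh = {cs.stokes_einstein_radius(d0, 298.15, 1.095):.2f} nm")
# rate = 0.01947/us, D0 = 3.713e-11 m2/s, Rh = 5.37 nm

# interaction chain: measured Kd ≈ 0 → stickiness → virial ratio
tau = cs.solve_tau_kd_zero()
print(f"tau = {tau:.3f}, B2/B2(HS) = {cs.b2_ratio_shs(tau):.3f}")
# tau = 0.774, B2/B2(HS) = 0.677

# arrest: fit the viscosity divergence
series = cs.synth_viscosity_series(
    truth, np.array([30., 60., 120., 180., 240., 280., 320., 340.]), seed=3)
arrest = cs.arrest_powerlaw_fit(series)
print(f"c* = {arrest.c_star:.1f} mg/mL, gamma = {arrest.gamma:.2f}")
# c* = 360.0 mg/mL, gamma = 2.80
```

The first block prints the mean relaxation rate of the Schulz ensemble;
the Stokes–Einstein radius built from it (5.37 nm) recovers the
generator's z-average hydrodynamic radius ⟨R⁶⟩/⟨R⁵⟩ = 5.35 nm to within
the finite fit window. The second block solves the sticky-sphere relation at
the measured K_d ≈ 0 and converts the stickiness into the reduced second
virial coefficient, showing that weak attraction compensates about a third
of the hard-core repulsion. The third block recovers the arrest point and
exponent of the viscosity divergence; γ < 3 classifies the system as
nearly hard-sphere-like.

A command-line interface wraps the same functions:

```bash
crowdscatter synthesize --seed 1 --out data/
crowdscatter fit-dls data/dls_dilute.dat
crowdscatter simulate --phi 0.3 --n 500 --seed 1 --out sq.dat
crowdscatter report --seed 1 --out report.json
```

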