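# Methods

## The colloidal model

The system is a solution of polydisperse, roughly globular protein
oligomers treated as spheres whose radii follow a Schulz (gamma)
distribution

P(R) = (R/b)^(c−1) e^(−R/b) / (b Γ(c)),  c = 1/σ*²,  b = ⟨R⟩/c,

parameterized by the number-average radius ⟨R⟩ and the normalized standard
deviation σ*. Scattering weights particles by their volume squared, so the
observables are intensity averages: DLS measures the z-average
hydrodynamic radius R_h = ⟨R⁶⟩/⟨R⁵⟩ = ⟨R⟩(1+5σ*²), SAXS the z-average
radius of gyration R_g = √(3⟨R⁸⟩/5⟨R⁶⟩). Moments come from the closed
form ⟨Rⁿ⟩ = ⟨R⟩ⁿσ*²ⁿ Γ(n+c)/Γ(c), evaluated through log-gamma; orders
above n = 12 are refused because the Γ ratio loses precision for large σ*.

Interactions are summarized at two levels. The Baxter sticky-hard-sphere
(SHS) parameterization carries the analytic relations used on the measured
side: K_d = (1.454 − 1.125/τ)ν_eff for gradient diffusion with
hydrodynamic interactions, B₂/B₂(HS) = 1 − 1/4τ, and
D_s/D₀ = 1 − (1.8315 + 0.295/τ)φ for short-time self-diffusion (linear in
φ, flagged — not rejected — beyond φ = 0.3). The simulation side uses a
square well of depth u (k_BT) and range λ = 1.25 times hard-core contact,
whose reduced second virial coefficient 1 − (λ³−1)(e^u−1) matches the
SHS value near u ≈ 0.289. The analytic chain 1 − 1.454/4.5 = 0.676889 is
what the commonly quoted "≈ 0.677" rounds from; the square-well pair
(u = 0.289, λ = 1.25) gives 0.6806 — the package computes both and does
not force them equal.

## Event-driven molecular dynamics

N spheres with equal masses (equilibrium structure is mass-independent)
evolve ballistically between discrete events in a cubic periodic box, in
reduced units k_BT = 1, mean diameter = 1. Four event types: elastic core
bounce; well entry at separation λ(R_i+R_j) with a radial speed-up taking
up the potential energy −u; well-exit attempt resolved by the radial
kinetic-energy test μv_r²/2 > u (escape with slow-down, else interior
bounce); and per-particle refresh events. Each collision rule is an exact
momentum- and energy-conserving impulse, so total energy is conserved to
round-off — the 1e-6 acceptance threshold is a regression guard against
bookkeeping errors (a missed event or a stale bond), not a discretization
tolerance.

Scheduling keeps a single next event per particle in a binary heap with
lazy invalidation by per-particle event counters. Predictions scan all
partners (O(N) per update) under the minimum-image convention; a
per-particle travel-horizon refresh guarantees no prediction outlives the
validity of its periodic image. At the package's desk scale (N ≤ 2000) the
compiled O(N) scan is faster in practice than a cell-list scheme and much
easier to verify; cell lists would pay off only at substantially larger N.

Initial configurations are drawn at random and inflated to full size by
iterative pair push-apart relaxation, with the box length fixed so that
Σ(4π/3)R_i³/L³ equals the requested φ exactly. The radius distribution is
discretized into 10 species at the conditional means of equal-probability
quantile bins, which preserves ⟨R⟩ exactly and narrows the sample σ* by a
few percent (0.29 realized for a target of 0.30 — the known cost of
quantile-bin discretization). Equilibration is declared when the potential
energy per particle is stationary within 1% across consecutive windows of
200 events/particle; snapshots are then taken every 30 events/particle by
default, which brings the snapshot-to-snapshot displacement correlation
below ≈ 0.2 at φ = 0.3.

The effective structure factor is the scattering-weighted
S_M(q) = ⟨|Σ f_i e^{iq·r_i}|²⟩ / Σ f_i² with sphere amplitudes
f_i = V_i·3(sin qR_i − qR_i cos qR_i)/(qR_i)³, computed on the lattice
q = 2π n/L and averaged over up to 48 directions per |q| shell. S(0) is
the mean of the five lowest-q values (the same convention is applied to
experimental curves). Pressure comes from the collision virial
Z = 1 + Σ Δp·r_ij /(3NkTt).

## Structure-factor theory

The monodisperse hard-sphere S(q) is Wertheim's analytic Percus–Yevick
solution; its kernels cancel catastrophically below qd ≈ 0.5 and are
replaced there by series expansions (coefficients verified against
high-precision evaluation). The square-well S(q) solves the
Ornstein–Zernike equation with the PY closure numerically (discrete sine
transforms, Picard iteration with density-dependent mixing 0.4/0.2,
8192-point grid to r = 50d); a first-order perturbation around the PY
reference was tried first and discarded after missing the simulation
oracle by ~24% at φ = 0.3, where the full PY solution agrees to a few
percent. Convergence failure raises an explicit error rather than
returning a partial answer.

The polydisperse hard-sphere S(0) is obtained from the BMCSL mixture free
energy: the Schulz distribution is discretized into 30 equal-probability
components, concentration fluctuations follow from the inverse Hessian
∂²(βF/V)/∂ρ_i∂ρ_j (central differences), and the zero-q scattering
weights are the particle volumes. This reduces exactly to
Carnahan–Starling in the monodisperse limit and reproduces the simulated
u = 0 value at σ* = 0.3 within a few percent.

## Correlation analysis

All DLS fits go through the Siegert relation g₂ = b + a·g₁² with the model
written for g₁ and squared inside the fit, so contrast a ∈ (0, 1.3] and
baseline b ∈ [0.98, 1.05] (slightly above 1 tolerated for correlator
artifacts) are determined together with the physical parameters, by
error-weighted least squares with multi-start initialization from
log-spaced rate guesses. Lag times are handled in µs; the conversion
D[m²/s] = rate[µs⁻¹]/q[nm⁻¹]² × 1e-12 makes a rate of 0.01592 µs⁻¹ at
q = 0.0229 nm⁻¹ correspond to D₀ = 3.04×10⁻¹¹ m²/s — the only reading
under which the standard diffusion relation closes, which is why the
package treats DLS rates as per-microsecond throughout.

The second-order cumulant fit returns σ* = √µ·τ₀. Two systematic facts
about this estimator matter for interpreting recovered values. First, it
measures the spread of decay *rates*, and with D ∝ 1/R under R⁶ weighting
the Schulz ensemble's rate spread is 1/√(1/σ*²+4) — 0.257 for a radius
polydispersity of 0.30, 0.344 for 0.475. Second, at finite truncation the
exponential tilt of the rate distribution narrows it further, so the
fitted σ* decreases smoothly as the truncation window grows; the
truncation-scan helper exposes this and a plateau detector mirrors the
usual robustness argument. Consequently a DLS-reported width near 0.30 is
what this estimator produces for a radius polydispersity near 0.475 at
customary truncations — the apparent DLS/SAXS discrepancy is a property
of the estimator, reproduced quantitatively by the synthetic chain.

The two-mode crowded-sample model
g₂ = b + a(c·e^{−(t/τ₁)^α₁} + (1−c)e^{−(t/τ₂)^α₂})² pins α₁ = 1 by
default (the fast collective mode is diffusive; freeing it returns values
within 0.1 of 1 on synthetic data) and flags mode collapse when
τ₂/τ₁ < 3. The mean slow time is the KWW average τ̄ = (τ₂/α₂)Γ(1/α₂).
NSE curves are fitted on t < 50 ns (initial slope) giving
D(q) = 1/(τ_s q²); band averages use inverse-variance weights, with the
high-q preset 1.8–2.2 nm⁻¹ (0.18–0.22 Å⁻¹).

## Microrheology, arrest, voluminosity

Tracer viscometry inverts Stokes–Einstein at the tracer radius (150 nm
polystyrene beads, θ = 90°); a reduced χ² above 25 against the
single-exponential model flags protein-scattering leakage. The arrest law
η_r = (1 − c/c*)^(−γ) is fitted in log space with both c* and γ free —
log space stabilizes the divergence and makes the errors approximately
homoscedastic for multiplicative noise. Normalized slow DLS times τ̄/τ₀
enter the same fit unchanged. The classification γ < 3 ("near hard
sphere") is reported as exactly that threshold comparison.

Voluminosity is estimated twice: ν = 0.64/c* from random close packing at
the arrest concentration (0.64 is a named, overridable constant), and
ν = V_z N_A/M_w with V_z = (4π/3)⟨R³⟩ for the Schulz distribution scaled
so that ⟨R⁶⟩/⟨R⁵⟩ equals the measured z-average R_h. With R_h = 6.5 nm,
σ* = 0.3, M_w = 180 kDa the second route gives V_z = 485.3 nm³ and
1.62 mL/g; an unrounded R_h = 6.52 nm reproduces the alternative
V_z = 489.8 nm³ (1.64 mL/g) — the difference is pure input rounding and
both are reported. The adopted intermediate default is 1.7 mL/g.

## Synthetic data: what it does and does not emulate

Every generator is the exact forward model of its analysis counterpart:
DLS correlograms are intensity-weighted exponential mixtures over an
equal-probability discretization of the Schulz ensemble (bin weights are
exact R⁶ masses and bin radii are within-bin z-averages, so the mixture's
mean rate equals the analytic z-average exactly); SAXS curves multiply the
polydisperse form factor by an optional structure factor; NSE curves decay
as exp(−D(q)q²t) on the instrument's three echo windows (τ_max = 91, 248,
598 ns, q = 0.25–2.1 nm⁻¹) with an optional low-q upturn mimicking
rotational/internal contributions; viscosities follow the arrest law.
Noise is multiplicative Gaussian with a lag-dependent floor for
correlograms, and the per-point σ is reported as the error column, in the
spirit of triplicate-measurement standard deviations. All randomness flows
from a single integer seed; regeneration is bit-identical.

Passing recovery tests on these generators demonstrates that the fitting
chain is unbiased against its own model assumptions at realistic noise. It
does not demonstrate robustness to what the generators omit: instrument
resolution functions, multiple scattering, q-dependent backgrounds,
internal protein structure at high q, or oligomerization kinetics.

## Default study conditions and problem sizes

Defaults follow the reference system: σ* = 0.3 (DLS) / 0.475 (SAXS with
R_g = 4.8 nm, giving ⟨R⟩ = 2.51 nm), D₀ = 3.04×10⁻¹¹ m²/s, D₂O buffer
viscosity 1.095 mPa·s at 298.15 K, u = 0.289 k_BT, λ = 1.25, τ = 0.774,
c* = 360 mg/mL, γ = 2.8, ν_eff = 1.7 mL/g, M_w = 180 kDa. The simulation
study scale is 2000 particles and 300 configurations; the package's test
and pipeline defaults run the same physics at N = 500 (N configurable up
to and beyond 2000), 100–300 snapshots, and three volume fractions
{0.05, 0.2, 0.5}, sizes chosen so the whole validation suite completes at
desk scale while leaving the main structural conclusions (peak suppression
by polydispersity; S(0) enhancement by attraction at low and moderate
crowding) unambiguous relative to their statistical errors.

## Known limitations

* The square-well PY closure inherits PY's known inaccuracies near
  phase boundaries and at φ ≳ 0.5; the simulation is the ground truth. In
  particular PY substantially overstates the attraction-induced S(0)
  enhancement at φ = 0.5 (simulation shows only a few percent there), and
  in the scattering-weighted S_M(0) of the polydisperse system — which is
  dominated by composition fluctuations at high density — that small
  effect falls below the resolution attainable with N = 500 and
  desk-scale run lengths, so its sign is not reliably measurable at the
  package's default sizes.
* The BMCSL S(0) weights amplitudes at q = 0 only; it is not a full
  polydisperse S_M(q).
* The EDMD scheduler is O(N) per event; it is not intended for N ≫ 10⁴.
* Cumulant widths are estimator-dependent (see above); comparisons across
  instruments should fix the truncation convention first.
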