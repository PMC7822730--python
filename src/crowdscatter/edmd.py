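"""Event-driven molecular dynamics of polydisperse square-well spheres.

The crowded protein solution is modelled as N spheres with Schulz-distributed
radii interacting through a hard core plus a square attractive well of depth
``u`` (in k_BT) reaching ``range_factor·(R_i + R_j)`` beyond contact.  The
dynamics are exact piecewise-ballistic: particles fly freely between discrete
events (elastic core bounces, well entries with radial speed-up, well-exit
attempts resolved by a radial kinetic-energy test) so energy and momentum are
conserved to round-off.  The engine produces equilibrium configurations, the
effective (scattering-amplitude-weighted) structure factor S_M(q), its
low-q plateau estimate of S(0), and the collision-virial pressure.

Reduced units: k_BT = 1, equal particle masses m = 1, mean diameter = 1.

Scheduling uses a single-next-event-per-particle binary heap with lazy
invalidation through per-particle event counters; pair predictions scan all
partners (O(N) per update, adequate at desk scale) under the minimum-image
convention, with per-particle travel-horizon refresh events guaranteeing that
no prediction outlives the validity of its periodic image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import gamma as _gamma_dist

from .schulz import SchulzDistribution

__all__ = [
    "SquareWellSpec",
    "HARD_SPHERES",
    "ParticleConfiguration",
    "EDMDDiagnostics",
    "JammingError",
    "EventOrderingError",
    "discretize_schulz",
    "initialize_box",
    "run_edmd",
    "sample_configurations",
    "effective_structure_factor",
    "low_q_plateau_s0",
    "well_contrast",
    "write_configuration",
    "read_configuration",
]

_CORE, _ENTRY, _EXIT, _REFRESH = 0, 1, 2, 3


class JammingError(RuntimeError):
    """Overlap-free initialization failed within the iteration budget."""


class EventOrderingError(RuntimeError):
    """The event queue produced a time running backwards — internal error."""


@dataclass(frozen=True)
class SquareWellSpec:
    """Square-well attraction: depth u [k_BT], width range_factor·(R_i+R_j)."""

    depth: float = 0.289
    range_factor: float = 0.25
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("well depth must be non-negative")
        if not self.range_factor > 0:
            raise ValueError("range_factor must be positive")

    @property
    def lam(self) -> float:
        """Outer range over hard-core contact, λ = 1 + range_factor."""
        return 1.0 + self.range_factor


HARD_SPHERES = SquareWellSpec(depth=0.0, range_factor=0.25)


@dataclass
class ParticleConfiguration:
    """Snapshot of the simulation state in a cubic periodic box."""

    radii: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    box_length: float
    time: float = 0.0

    @property
    def n(self) -> int:
        return len(self.radii)

    @property
    def volume_fraction(self) -> float:
        return float(np.sum(4.0 * np.pi / 3.0 * self.radii**3) / self.box_length**3)

    def max_core_overlap(self) -> float:
        """Largest pairwise core overlap (positive = overlapping); 0 if none."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        d -= self.box_length * np.round(d / self.box_length)
        r = np.sqrt((d**2).sum(-1))
        contact = self.radii[:, None] + self.radii[None, :]
        np.fill_diagonal(r, np.inf)
        return float(max(0.0, np.max(contact - r)))

    def copy(self) -> "ParticleConfiguration":
        return ParticleConfiguration(
            self.radii.copy(),
            self.positions.copy(),
            self.velocities.copy(),
            self.box_length,
            self.time,
        )


@dataclass
class EDMDDiagnostics:
    """Bookkeeping from one event-loop run."""

    n_events: int
    elapsed_time: float
    energy_drift: float
    compressibility_z: float
    potential_energy: float
    kinetic_energy: float


def discretize_schulz(
    dist: SchulzDistribution, n_species: int, n_particles: int, seed: int
) -> np.ndarray:
    """Discretize the Schulz radius distribution into species of equal count.

    Species radii are the conditional means of equal-probability quantile
    bins, which preserves the mean exactly and slightly narrows the sample
    standard deviation.  The remainder of ``n_particles // n_species`` is
    assigned round-robin; the per-particle order is shuffled deterministically
    from ``seed``.
    """
    if n_species < 2 and not dist.is_monodisperse:
        raise ValueError("need at least 2 species for a polydisperse system")
    if dist.is_monodisperse:
        return np.full(n_particles, dist.mean_radius)
    c, b = dist.shape_c, dist.scale_b
    edges = np.linspace(0.0, 1.0, n_species + 1)
    # E[R | bin] = ⟨R⟩ (F_{c+1}(hi) − F_{c+1}(lo)) / (1/n_species)
    cdf1 = _gamma_dist.ppf(edges, a=c, scale=b)
    upper = _gamma_dist.cdf(cdf1, a=c + 1.0, scale=b)
    species = dist.mean_radius * np.diff(upper) * n_species

    counts = np.full(n_species, n_particles // n_species)
    counts[: n_particles % n_species] += 1
    radii = np.repeat(species, counts)
    rng = np.random.default_rng(seed)
    return radii[rng.permutation(n_particles)]


def initialize_box(radii: np.ndarray, phi: float, seed: int) -> ParticleConfiguration:
    """Overlap-free random start at volume fraction φ with thermal velocities.

    The box length satisfies Σ(4π/3)R_i³/L³ = φ exactly.  Particles are
    inserted at random and inflated from reduced radii to full size by
    iterative pair push-apart relaxation; failure to relax within the sweep
    budget raises :class:`JammingError`.  Velocities are Maxwell–Boltzmann at
    k_BT = 1 with the net momentum removed.
    """
    radii = np.asarray(radii, dtype=float)
    if not (0.0 < phi <= 0.55):
        raise ValueError("volume fraction must be in (0, 0.55]")
    n = len(radii)
    vol = float(np.sum(4.0 * np.pi / 3.0 * radii**3))
    box = (vol / phi) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n, 3))

    # inflate from a dilute effective packing to slightly past full size so
    # the returned configuration has a strict core gap
    final_scale = 1.0 + 1e-6
    scale = min(final_scale, (0.25 / phi) ** (1.0 / 3.0))
    budget = 40000
    tol = 1e-9 * float(np.max(radii))
    while True:
        r_eff = scale * radii
        for _ in range(budget):
            d = pos[:, None, :] - pos[None, :, :]
            d -= box * np.round(d / box)
            dist2 = (d**2).sum(-1)
            contact = r_eff[:, None] + r_eff[None, :]
            np.fill_diagonal(dist2, np.inf)
            ii, jj = np.nonzero(dist2 < (contact - tol) ** 2)
            mask = ii < jj
            ii, jj = ii[mask], jj[mask]
            if ii.size == 0:
                break
            rij = np.sqrt(dist2[ii, jj])
            overlap = contact[ii, jj] - rij
            unit = d[ii, jj] / np.where(rij > 1e-12, rij, 1.0)[:, None]
            # degenerate coincident points: random direction
            bad = rij <= 1e-12
            if np.any(bad):
                u = rng.standard_normal((int(bad.sum()), 3))
                unit[bad] = u / np.linalg.norm(u, axis=1, keepdims=True)
            step = 0.55 * overlap[:, None] * unit
            np.add.at(pos, ii, step)
            np.add.at(pos, jj, -step)
            pos %= box
        else:
            raise JammingError(
                f"overlap relaxation failed at φ={phi}, scale={scale:.3f}"
            )
        if scale >= final_scale:
            break
        scale = min(final_scale, scale * 1.04)

    vel = rng.standard_normal((n, 3))
    vel -= vel.mean(axis=0)
    ke = 0.5 * np.sum(vel**2)
    vel *= math.sqrt(1.5 * n / ke)
    return ParticleConfiguration(radii.copy(), pos, vel, box, 0.0)


# ---------------------------------------------------------------------------
# numba event loop


@njit(cache=True, inline="always")
def _heap_push(h_t, h_d, size_arr, t, i, j, kind, ci, cj):
    k = size_arr[0]
    h_t[k] = t
    h_d[k, 0] = i
    h_d[k, 1] = j
    h_d[k, 2] = kind
    h_d[k, 3] = ci
    h_d[k, 4] = cj
    size_arr[0] = k + 1
    while k > 0:
        parent = (k - 1) // 2
        if h_t[parent] <= h_t[k]:
            break
        h_t[parent], h_t[k] = h_t[k], h_t[parent]
        for m in range(5):
            h_d[parent, m], h_d[k, m] = h_d[k, m], h_d[parent, m]
        k = parent


@njit(cache=True, inline="always")
def _heap_pop(h_t, h_d, size_arr, out):
    size = size_arr[0]
    t = h_t[0]
    for m in range(5):
        out[m] = h_d[0, m]
    size -= 1
    h_t[0] = h_t[size]
    for m in range(5):
        h_d[0, m] = h_d[size, m]
    size_arr[0] = size
    k = 0
    while True:
        left = 2 * k + 1
        if left >= size:
            break
        small = left
        right = left + 1
        if right < size and h_t[right] < h_t[left]:
            small = right
        if h_t[k] <= h_t[small]:
            break
        h_t[k], h_t[small] = h_t[small], h_t[k]
        for m in range(5):
            h_d[k, m], h_d[small, m] = h_d[small, m], h_d[k, m]
        k = small
    return t


@njit(cache=True)
def _heap_compact(h_t, h_d, size_arr, counters):
    """Drop entries whose owner counter is stale, then re-heapify."""
    size = size_arr[0]
    keep = 0
    for k in range(size):
        i = h_d[k, 0]
        if h_d[k, 3] == counters[i]:
            h_t[keep] = h_t[k]
            for m in range(5):
                h_d[keep, m] = h_d[k, m]
            keep += 1
    size_arr[0] = keep
    # heapify
    for start in range(keep // 2 - 1, -1, -1):
        k = start
        while True:
            left = 2 * k + 1
            if left >= keep:
                break
            small = left
            right = left + 1
            if right < keep and h_t[right] < h_t[left]:
                small = right
            if h_t[k] <= h_t[small]:
                break
            h_t[k], h_t[small] = h_t[small], h_t[k]
            for m in range(5):
                h_d[k, m], h_d[small, m] = h_d[small, m], h_d[k, m]
            k = small


@njit(cache=True)
def _schedule(i, t_now, pos, vel, t_last, rad, bonds, counters, box, u, lam,
              h_t, h_d, size_arr, d_out_max):
    """Predict particle i's earliest pair event and push it (or a refresh)."""
    n = pos.shape[0]
    has_well = u > 0.0
    xi = pos[i, 0] + vel[i, 0] * (t_now - t_last[i])
    yi = pos[i, 1] + vel[i, 1] * (t_now - t_last[i])
    zi = pos[i, 2] + vel[i, 2] * (t_now - t_last[i])
    vi2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    vmax2 = 0.0
    best_t = 1e300
    best_j = -1
    best_kind = _REFRESH
    for j in range(n):
        if j == i:
            continue
        vj2 = vel[j, 0] ** 2 + vel[j, 1] ** 2 + vel[j, 2] ** 2
        if vj2 > vmax2:
            vmax2 = vj2
        dt_j = t_now - t_last[j]
        dx = pos[j, 0] + vel[j, 0] * dt_j - xi
        dy = pos[j, 1] + vel[j, 1] * dt_j - yi
        dz = pos[j, 2] + vel[j, 2] * dt_j - zi
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        dvx = vel[j, 0] - vel[i, 0]
        dvy = vel[j, 1] - vel[i, 1]
        dvz = vel[j, 2] - vel[i, 2]
        a = dvx * dvx + dvy * dvy + dvz * dvz
        if a <= 1e-16:
            continue
        b = dx * dvx + dy * dvy + dz * dvz
        r2 = dx * dx + dy * dy + dz * dz
        d_core = rad[i] + rad[j]
        if has_well and bonds[i, j]:
            # inside the well: core bounce (if approaching) or exit attempt
            if b < 0.0:
                cc = r2 - d_core * d_core
                disc = b * b - a * cc
                if disc > 0.0:
                    tc = (-b - math.sqrt(disc)) / a
                    if tc < best_t and tc > -1e-9:
                        if tc < 0.0:
                            tc = 0.0
                        best_t = tc
                        best_j = j
                        best_kind = _CORE
            d_out = lam * d_core
            co = r2 - d_out * d_out
            if co > 0.0:
                co = 0.0  # round-off: treat as exactly at the edge
            disc = b * b - a * co
            te = (-b + math.sqrt(disc)) / a
            if te < best_t:
                best_t = te
                best_j = j
                best_kind = _EXIT
        else:
            if b >= 0.0:
                continue
            d_t = lam * d_core if has_well else d_core
            kind = _ENTRY if has_well else _CORE
            cc = r2 - d_t * d_t
            if cc < 0.0:
                cc = 0.0  # round-off at the boundary
            disc = b * b - a * cc
            if disc > 0.0:
                tc = (-b - math.sqrt(disc)) / a
                if tc < best_t and tc > -1e-9:
                    if tc < 0.0:
                        tc = 0.0
                    best_t = tc
                    best_j = j
                    best_kind = kind

    # minimum-image validity horizon (also reached when no event was found)
    vrel = math.sqrt(vi2) + math.sqrt(vmax2) + 1e-12
    t_h = 0.9 * (0.5 * box - d_out_max) / vrel
    if t_h <= 0.0:
        t_h = 1e-3
    if best_j >= 0 and best_t <= t_h:
        _heap_push(h_t, h_d, size_arr, t_now + best_t, i, best_j, best_kind,
                   counters[i], counters[best_j])
    else:
        _heap_push(h_t, h_d, size_arr, t_now + t_h, i, -1, _REFRESH,
                   counters[i], 0)


@njit(cache=True)
def _advance(i, t, pos, vel, t_last, box):
    dt = t - t_last[i]
    for k in range(3):
        x = pos[i, k] + vel[i, k] * dt
        x -= box * math.floor(x / box)
        pos[i, k] = x
    t_last[i] = t


@njit(cache=True)
def _edmd_loop(pos, vel, t_last, rad, bonds, counters, box, u, lam,
               t_start, target_events):
    """Run until ``target_events`` pair events executed.

    Returns (status, t_final, events, virial, n_bond_delta):
    status 0 = ok, 1 = heap overflow, 2 = event-time ordering violation.
    """
    n = pos.shape[0]
    cap = 16 * n + 64
    h_t = np.empty(cap, dtype=np.float64)
    h_d = np.empty((cap, 5), dtype=np.int64)
    size_arr = np.zeros(1, dtype=np.int64)
    out = np.empty(5, dtype=np.int64)

    # conservative bound: twice the largest radius times lambda
    rmax = 0.0
    for i in range(n):
        if rad[i] > rmax:
            rmax = rad[i]
    d_out_max = lam * 2.0 * rmax

    t_now = t_start
    for i in range(n):
        _schedule(i, t_now, pos, vel, t_last, rad, bonds, counters, box,
                  u, lam, h_t, h_d, size_arr, d_out_max)

    events = 0
    virial = 0.0
    bond_delta = 0
    pops = 0
    max_pops = 100 * target_events + 200000  # guard: collisionless systems
    while events < target_events:
        pops += 1
        if pops > max_pops:
            return 3, t_now, events, virial, bond_delta
        if size_arr[0] == 0:
            return 2, t_now, events, virial, bond_delta
        if size_arr[0] > cap - 4:
            _heap_compact(h_t, h_d, size_arr, counters)
            if size_arr[0] > cap - 4:
                return 1, t_now, events, virial, bond_delta
        te = _heap_pop(h_t, h_d, size_arr, out)
        i, j, kind, ci, cj = out[0], out[1], out[2], out[3], out[4]
        if ci != counters[i]:
            continue  # stale owner; a newer prediction exists
        if te < t_now - 1e-9:
            return 2, t_now, events, virial, bond_delta
        if te < t_now:
            te = t_now
        if kind == _REFRESH:
            t_now = te
            _advance(i, te, pos, vel, t_last, box)
            _schedule(i, t_now, pos, vel, t_last, rad, bonds, counters, box,
                      u, lam, h_t, h_d, size_arr, d_out_max)
            continue
        if cj != counters[j]:
            # partner state changed since prediction; re-predict owner
            _schedule(i, te if te > t_now else t_now, pos, vel, t_last, rad,
                      bonds, counters, box, u, lam, h_t, h_d, size_arr,
                      d_out_max)
            continue
        t_now = te
        _advance(i, te, pos, vel, t_last, box)
        _advance(j, te, pos, vel, t_last, box)
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        nx, ny, nz = dx / r, dy / r, dz / r
        g = ((vel[i, 0] - vel[j, 0]) * nx + (vel[i, 1] - vel[j, 1]) * ny
             + (vel[i, 2] - vel[j, 2]) * nz)
        executed = True
        if kind == _CORE:
            if g > 0.0:
                dp = g
            else:
                executed = False
                dp = 0.0
        elif kind == _ENTRY:
            if g > 0.0:
                gp = math.sqrt(g * g + 4.0 * u)
                dp = 0.5 * (g - gp)
                bonds[i, j] = 1
                bonds[j, i] = 1
                bond_delta += 1
            else:
                executed = False
                dp = 0.0
        else:  # _EXIT attempt, moving outward (g < 0)
            if g < 0.0:
                if g * g > 4.0 * u:
                    gp = -math.sqrt(g * g - 4.0 * u)
                    dp = 0.5 * (g - gp)
                    bonds[i, j] = 0
                    bonds[j, i] = 0
                    bond_delta -= 1
                else:
                    dp = g  # interior bounce: stays bound
            else:
                executed = False
                dp = 0.0
        if executed:
            vel[i, 0] -= dp * nx
            vel[i, 1] -= dp * ny
            vel[i, 2] -= dp * nz
            vel[j, 0] += dp * nx
            vel[j, 1] += dp * ny
            vel[j, 2] += dp * nz
            virial += dp * r
            events += 1
        counters[i] += 1
        counters[j] += 1
        _schedule(i, t_now, pos, vel, t_last, rad, bonds, counters, box,
                  u, lam, h_t, h_d, size_arr, d_out_max)
        _schedule(j, t_now, pos, vel, t_last, rad, bonds, counters, box,
                  u, lam, h_t, h_d, size_arr, d_out_max)
    return 0, t_now, events, virial, bond_delta


def _bonds_from_positions(config: ParticleConfiguration, lam: float) -> np.ndarray:
    d = config.positions[:, None, :] - config.positions[None, :, :]
    d -= config.box_length * np.round(d / config.box_length)
    r2 = (d**2).sum(-1)
    d_out = lam * (config.radii[:, None] + config.radii[None, :])
    bonds = (r2 < d_out**2).astype(np.uint8)
    np.fill_diagonal(bonds, 0)
    return bonds


def run_edmd(
    config: ParticleConfiguration,
    spec: SquareWellSpec,
    n_events_per_particle: float,
) -> tuple[ParticleConfiguration, EDMDDiagnostics]:
    """Advance the configuration by ``n_events_per_particle·N/2`` pair events.

    Returns the updated configuration (all particles synchronized to the
    final time) together with :class:`EDMDDiagnostics` carrying the relative
    energy drift, the collision-virial compressibility factor Z = βP/ρ, and
    the final kinetic/potential energies.
    """
    cfg = config.copy()
    n = cfg.n
    if cfg.max_core_overlap() > 1e-9:
        raise ValueError("input configuration has overlapping cores")
    u, lam = spec.depth, spec.lam
    bonds = (
        _bonds_from_positions(cfg, lam)
        if u > 0
        else np.zeros((n, n), dtype=np.uint8)
    )
    n_bonds0 = int(bonds.sum()) // 2
    ke0 = 0.5 * float(np.sum(cfg.velocities**2))
    e0 = ke0 - u * n_bonds0

    t_last = np.full(n, cfg.time)
    counters = np.zeros(n, dtype=np.int64)
    target = int(round(n_events_per_particle * n / 2))
    status, t_final, events, virial, bond_delta = _edmd_loop(
        cfg.positions, cfg.velocities, t_last, cfg.radii, bonds, counters,
        cfg.box_length, u, lam, cfg.time, target,
    )
    if status == 2:
        raise EventOrderingError("event queue time ordering violated")
    if status == 1:
        raise RuntimeError("event heap overflow; system pathological")
    # status 3: collisionless system ran out of pair events — benign
    # synchronize all particles to the final time
    for i in range(n):
        cfg.positions[i] += cfg.velocities[i] * (t_final - t_last[i])
    cfg.positions %= cfg.box_length
    cfg.time = t_final

    n_bonds = n_bonds0 + bond_delta
    ke = 0.5 * float(np.sum(cfg.velocities**2))
    e1 = ke - u * n_bonds
    scale = max(abs(e0), abs(e1), 1e-12)
    drift = abs(e1 - e0) / scale
    elapsed = t_final - config.time
    if elapsed > 0:
        rho_kt = n  # ρ V k_BT with k_BT = 1
        z = 1.0 + virial / (3.0 * rho_kt * elapsed)
    else:
        z = float("nan")
    diag = EDMDDiagnostics(
        n_events=events,
        elapsed_time=elapsed,
        energy_drift=drift,
        compressibility_z=z,
        potential_energy=-u * n_bonds,
        kinetic_energy=ke,
    )
    return cfg, diag


def sample_configurations(
    config: ParticleConfiguration,
    spec: SquareWellSpec,
    n_samples: int = 300,
    decorrelation_events: float = 30.0,
    equilibration_window: float = 200.0,
    max_equilibration_windows: int = 20,
) -> list[ParticleConfiguration]:
    """Equilibrate, then collect decorrelated snapshots.

    Equilibration runs windows of ``equilibration_window`` events/particle
    until the potential energy per particle is stationary within 1% between
    two consecutive windows (pure hard spheres mix for one window).  Snapshots
    are then separated by ``decorrelation_events`` events per particle.
    """
    cfg = config
    if spec.depth > 0:
        prev_pe = None
        for _ in range(max_equilibration_windows):
            cfg, diag = run_edmd(cfg, spec, equilibration_window)
            pe = diag.potential_energy / cfg.n
            if prev_pe is not None:
                scale = max(abs(pe), abs(prev_pe), 1e-3)
                if abs(pe - prev_pe) / scale < 0.01:
                    break
            prev_pe = pe
    else:
        cfg, _ = run_edmd(cfg, spec, equilibration_window)

    samples = []
    for k in range(n_samples):
        if k > 0:
            cfg, _ = run_edmd(cfg, spec, decorrelation_events)
        samples.append(cfg.copy())
    return samples


# ---------------------------------------------------------------------------
# structure factor from configurations


def _lattice_shells(box: float, q_max: float, max_vectors_per_shell: int = 48):
    """Group lattice wavevectors 2π·n/L by |n|² shell up to q_max."""
    n_max = int(math.ceil(q_max * box / (2.0 * math.pi)))
    rng = range(-n_max, n_max + 1)
    shells: dict[int, list[tuple[int, int, int]]] = {}
    for nx in rng:
        for ny in rng:
            for nz in rng:
                m = nx * nx + ny * ny + nz * nz
                if m == 0:
                    continue
                q = 2.0 * math.pi * math.sqrt(m) / box
                if q > q_max:
                    continue
                vecs = shells.setdefault(m, [])
                if len(vecs) < max_vectors_per_shell:
                    vecs.append((nx, ny, nz))
    out = []
    for m in sorted(shells):
        qmag = 2.0 * math.pi * math.sqrt(m) / box
        out.append((qmag, np.array(shells[m], dtype=float) * 2.0 * math.pi / box))
    return out


def effective_structure_factor(
    configs: list[ParticleConfiguration],
    q_max: float = 15.0,
    max_vectors_per_shell: int = 48,
) -> tuple[np.ndarray, np.ndarray]:
    """Measurable structure factor of a polydisperse system.

    S_M(q) = ⟨|Σ_i f_i(q) e^{iq·r_i}|²⟩ / Σ_i f_i(q)² with sphere amplitudes
    f_i(q) = V_i·3[sin(qR_i) − qR_i cos(qR_i)]/(qR_i)³, averaged over all
    lattice directions of equal |q| (q = 2π n/L) and over configurations.
    Returns (q values, S values) sorted in q.
    """
    if not configs:
        raise ValueError("no configurations")
    box = configs[0].box_length
    radii = configs[0].radii
    shells = _lattice_shells(box, q_max, max_vectors_per_shell)
    if not shells:
        raise ValueError("q_max below the smallest lattice wavevector 2π/L")
    q_out = np.array([s[0] for s in shells])
    s_out = np.zeros(len(shells))
    vols = 4.0 * np.pi / 3.0 * radii**3
    for k, (qmag, qvecs) in enumerate(shells):
        f = vols * _amp_vec(qmag, radii)
        norm = float(np.sum(f**2))
        acc = 0.0
        count = 0
        for cfg in configs:
            phase = cfg.positions @ qvecs.T  # (N, n_vec)
            amp = f @ np.exp(1j * phase)
            acc += float(np.mean(np.abs(amp) ** 2))
            count += 1
        s_out[k] = acc / (count * norm)
    return q_out, s_out


def _amp_vec(qmag: float, radii: np.ndarray) -> np.ndarray:
    x = qmag * radii
    small = np.abs(x) < 0.1
    xs = np.where(small, 1.0, x)
    exact = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return np.where(small, 1.0 - x**2 / 10.0 + x**4 / 280.0, exact)


def low_q_plateau_s0(
    q: np.ndarray, s: np.ndarray, n_points: int = 5
) -> tuple[float, float]:
    """S(0) as the mean of the ``n_points`` lowest-q values, with std. error."""
    q = np.asarray(q, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(q) < n_points:
        raise ValueError(f"need at least {n_points} low-q points, got {len(q)}")
    order = np.argsort(q)
    vals = s[order][:n_points]
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_points))


def well_contrast(
    configs: list[ParticleConfiguration],
    lam: float = 1.25,
    reference: tuple[float, float] = (2.0, 3.0),
) -> float:
    """Pair-density contrast inside the well vs. an uncorrelated reference.

    Counts pairs by the normalized separation x = r/(R_i+R_j) in the well
    shell (1, λ) and in a far reference shell where g ≈ 1, each normalized
    by its shell volume.  In the dilute limit this ratio tends to the
    Boltzmann factor e^u of the well depth.
    """
    n_in = 0
    n_out = 0
    for cfg in configs:
        d = cfg.positions[:, None, :] - cfg.positions[None, :, :]
        d -= cfg.box_length * np.round(d / cfg.box_length)
        r = np.sqrt((d**2).sum(-1))
        contact = cfg.radii[:, None] + cfg.radii[None, :]
        x = r / contact
        iu = np.triu_indices(cfg.n, k=1)
        xv = x[iu]
        n_in += int(np.sum((xv > 1.0) & (xv < lam)))
        n_out += int(np.sum((xv >= reference[0]) & (xv < reference[1])))
    if n_out == 0:
        raise ValueError("no reference-shell pairs; need more samples")
    v_in = lam**3 - 1.0
    v_out = reference[1] ** 3 - reference[0] ** 3
    return (n_in / v_in) / (n_out / v_out)


# ---------------------------------------------------------------------------
# trajectory text format


def write_configuration(path, config: ParticleConfiguration, **metadata) -> None:
    """Write a snapshot as columnar text (id, radius, x, y, z) with a header."""
    meta = {
        "box_length": config.box_length,
        "time": config.time,
        "n": config.n,
        **metadata,
    }
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# id radius x y z vx vy vz\n")
        for i in range(config.n):
            p = config.positions[i]
            v = config.velocities[i]
            fh.write(
                f"{i} {config.radii[i]:.12g} "
                f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g} "
                f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n"
            )


def read_configuration(path) -> ParticleConfiguration:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            rows.append([float(tok) for tok in line.split()])
    arr = np.array(rows)
    return ParticleConfiguration(
        radii=arr[:, 1].copy(),
        positions=arr[:, 2:5].copy(),
        velocities=arr[:, 5:8].copy(),
        box_length=float(meta["box_length"]),
        time=float(meta.get("time", 0.0)),
    )
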