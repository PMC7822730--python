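"""Event-driven MD engine: discretization, initialization, conservation laws."""

import math

import numpy as np
import pytest

from crowdscatter.edmd import (
    HARD_SPHERES,
    JammingError,
    ParticleConfiguration,
    SquareWellSpec,
    discretize_schulz,
    effective_structure_factor,
    initialize_box,
    low_q_plateau_s0,
    read_configuration,
    run_edmd,
    sample_configurations,
    well_contrast,
    write_configuration,
)
from crowdscatter.interactions import py_hs_structure_factor
from crowdscatter.schulz import SchulzDistribution

WELL = SquareWellSpec(depth=0.289)


class TestDiscretization:
    def test_monodisperse_all_equal(self):
        radii = discretize_schulz(SchulzDistribution(0.5, 0.0), 10, 100, seed=1)
        assert np.allclose(radii, 0.5)

    def test_sample_polydispersity_slightly_narrowed(self):
        radii = discretize_schulz(SchulzDistribution(0.5, 0.3), 10, 2000, seed=1)
        s = radii.std() / radii.mean()
        assert 0.285 <= s <= 0.30
        assert radii.mean() == pytest.approx(0.5, rel=1e-3)

    def test_deterministic_given_seed(self):
        a = discretize_schulz(SchulzDistribution(0.5, 0.3), 10, 500, seed=7)
        b = discretize_schulz(SchulzDistribution(0.5, 0.3), 10, 500, seed=7)
        assert np.array_equal(a, b)

    def test_remainder_assigned_round_robin(self):
        radii = discretize_schulz(SchulzDistribution(0.5, 0.3), 10, 105, seed=1)
        assert len(radii) == 105
        assert len(np.unique(radii)) == 10


class TestInitialization:
    def test_dilute_insertion(self):
        radii = np.full(100, 0.5)
        cfg = initialize_box(radii, 0.05, seed=1)
        assert cfg.max_core_overlap() == 0.0
        assert cfg.volume_fraction == pytest.approx(0.05, rel=1e-12)

    def test_dense_polydisperse_overlap_free(self):
        radii = discretize_schulz(SchulzDistribution(0.5, 0.3), 10, 300, seed=2)
        cfg = initialize_box(radii, 0.5, seed=3)
        assert cfg.max_core_overlap() == 0.0
        assert cfg.volume_fraction == pytest.approx(0.5, rel=1e-12)

    def test_thermal_velocities(self):
        cfg = initialize_box(np.full(200, 0.5), 0.2, seed=4)
        ke = 0.5 * np.sum(cfg.velocities**2)
        assert ke == pytest.approx(1.5 * 200, rel=1e-9)
        assert np.abs(cfg.velocities.sum(axis=0)).max() < 1e-10

    def test_unphysical_phi_rejected(self):
        with pytest.raises(ValueError):
            initialize_box(np.full(10, 0.5), 0.7, seed=1)


class TestEventLoop:
    def test_hard_sphere_kinetic_energy_exact(self):
        cfg = initialize_box(np.full(128, 0.5), 0.2, seed=5)
        ke0 = 0.5 * np.sum(cfg.velocities**2)
        out, diag = run_edmd(cfg, HARD_SPHERES, 50.0)
        ke1 = 0.5 * np.sum(out.velocities**2)
        assert ke1 == pytest.approx(ke0, rel=1e-12)
        assert out.max_core_overlap() < 1e-9

    def test_square_well_energy_conservation(self):
        radii = discretize_schulz(SchulzDistribution(0.5, 0.3), 10, 128, seed=6)
        cfg = initialize_box(radii, 0.3, seed=7)
        out, diag = run_edmd(cfg, WELL, 50.0)
        assert diag.energy_drift < 1e-6
        assert out.max_core_overlap() < 1e-9

    def test_momentum_conserved(self):
        cfg = initialize_box(np.full(128, 0.5), 0.3, seed=8)
        out, _ = run_edmd(cfg, WELL, 50.0)
        assert np.abs(out.velocities.sum(axis=0)).max() < 1e-9

    def test_bound_pair_with_insufficient_energy_stays_bound(self):
        # two particles inside the well, slow radial separation: must bounce
        radii = np.array([0.5, 0.5])
        box = 20.0
        pos = np.array([[5.0, 5.0, 5.0], [6.1, 5.0, 5.0]])  # inside well (r=1.1<1.25)
        vel = np.array([[-0.1, 0.0, 0.0], [0.1, 0.0, 0.0]])  # μv_r²/2 = 0.01 << u
        cfg = ParticleConfiguration(radii, pos, vel, box)
        out, diag = run_edmd(cfg, WELL, 4.0)
        d = np.linalg.norm(out.positions[1] - out.positions[0])
        assert d < 1.25 + 1e-9
        assert diag.energy_drift < 1e-9

    def test_fast_pair_escapes_well(self):
        radii = np.array([0.5, 0.5])
        box = 20.0
        pos = np.array([[5.0, 5.0, 5.0], [6.1, 5.0, 5.0]])
        vel = np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])  # μv_r²/2 = 1 > u
        cfg = ParticleConfiguration(radii, pos, vel, box)
        out, _ = run_edmd(cfg, WELL, 1.0)
        d = np.linalg.norm(out.positions[1] - out.positions[0])
        assert d >= 1.25 - 1e-12
        # exit slow-down: relative speed reduced by the well depth
        g_out = out.velocities[1, 0] - out.velocities[0, 0]
        assert g_out == pytest.approx(math.sqrt(2.0**2 - 4.0 * 0.289), rel=1e-9)

    def test_overlapping_input_rejected(self):
        radii = np.array([0.5, 0.5])
        pos = np.array([[5.0, 5.0, 5.0], [5.5, 5.0, 5.0]])
        vel = np.zeros((2, 3))
        cfg = ParticleConfiguration(radii, pos, vel, 20.0)
        with pytest.raises(ValueError):
            run_edmd(cfg, WELL, 1.0)

    def test_dilute_pressure_gives_square_well_b2(self):
        # Z − 1 ≈ B₂ρ at φ = 0.02; B₂/B₂(HS) = 1 − (λ³−1)(e^u − 1)
        phi = 0.02
        cfg = initialize_box(np.full(256, 0.5), phi, seed=14)
        cfg, _ = run_edmd(cfg, WELL, 100.0)
        _, diag = run_edmd(cfg, WELL, 3000.0)
        rho = 6.0 * phi / math.pi
        b2_measured = (diag.compressibility_z - 1.0) / rho
        b2_expected = (2.0 * math.pi / 3.0) * (
            1.0 - (1.25**3 - 1.0) * (math.exp(0.289) - 1.0)
        )
        assert b2_measured == pytest.approx(b2_expected, rel=0.10)

    def test_pressure_matches_carnahan_starling(self):
        phi = 0.3
        cfg = initialize_box(np.full(256, 0.5), phi, seed=9)
        cfg, _ = run_edmd(cfg, HARD_SPHERES, 100.0)
        _, diag = run_edmd(cfg, HARD_SPHERES, 600.0)
        z_cs = (1 + phi + phi**2 - phi**3) / (1 - phi) ** 3
        assert diag.compressibility_z == pytest.approx(z_cs, rel=0.03)


class TestSampling:
    def test_single_snapshot_equals_state(self):
        cfg = initialize_box(np.full(64, 0.5), 0.1, seed=10)
        samples = sample_configurations(cfg, HARD_SPHERES, n_samples=1,
                                        equilibration_window=5.0)
        assert len(samples) == 1
        assert samples[0].max_core_overlap() == 0.0

    def test_snapshots_decorrelated(self):
        radii = discretize_schulz(SchulzDistribution(0.5, 0.3), 10, 200, seed=11)
        cfg = initialize_box(radii, 0.3, seed=12)
        samples = sample_configurations(
            cfg, WELL, n_samples=6, decorrelation_events=30.0,
            equilibration_window=100.0,
        )
        disp = []
        box = samples[0].box_length
        for a, b in zip(samples[:-1], samples[1:]):
            d = b.positions - a.positions
            d -= box * np.round(d / box)
            disp.append(d.ravel())
        corr = np.mean(
            [np.corrcoef(disp[k], disp[k + 1])[0, 1] for k in range(len(disp) - 1)]
        )
        assert corr < 0.3


class TestStructureFactor:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(0)
        box = 10.0
        configs = [
            ParticleConfiguration(
                np.full(512, 0.5), rng.uniform(0, box, (512, 3)),
                np.zeros((512, 3)), box,
            )
            for _ in range(40)
        ]
        q, s = effective_structure_factor(configs, q_max=10.0)
        assert np.abs(s - 1.0).mean() < 0.1

    def test_single_particle_unity(self):
        cfg = ParticleConfiguration(
            np.array([0.5]), np.array([[1.0, 2.0, 3.0]]), np.zeros((1, 3)), 8.0
        )
        q, s = effective_structure_factor([cfg], q_max=8.0)
        assert np.allclose(s, 1.0)

    def test_low_q_plateau_constant_curve(self):
        q = np.linspace(0.5, 5.0, 20)
        s = np.full(20, 0.2)
        s0, err = low_q_plateau_s0(q, s)
        assert s0 == pytest.approx(0.2)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_low_q_plateau_needs_five_points(self):
        with pytest.raises(ValueError):
            low_q_plateau_s0(np.array([1.0, 2.0]), np.array([0.2, 0.2]))


class TestTrajectoryIO:
    def test_round_trip(self, tmp_path):
        cfg = initialize_box(np.full(32, 0.5), 0.1, seed=13)
        path = tmp_path / "snap.dat"
        write_configuration(path, cfg, phi=0.1, seed=13)
        back = read_configuration(path)
        assert np.allclose(back.positions, cfg.positions)
        assert np.allclose(back.velocities, cfg.velocities)
        assert back.box_length == pytest.approx(cfg.box_length)
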