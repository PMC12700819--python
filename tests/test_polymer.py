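"""Pair potential closed forms, force consistency, integrator statistics,
confinement geometry and determinism of the 3D engine."""

import numpy as np
import pytest
from scipy.integrate import quad

from chromodyn.polymer import (
    A0,
    E0,
    ConfinementSpec,
    MonomerTyping,
    PolymerSystem,
    PotentialParams,
    Trajectory3D,
    compute_forces,
    init_conformation,
    pair_force,
    pair_potential,
    run_polymer,
    summarize_conformation,
    total_energy,
)


class TestPairPotential:
    def test_closed_form_values(self):
        """U(0) = E_repel = 3 kT; U(a) = U(a*) = 0; well depth -eps at the
        midpoint of the attractive well."""
        assert pair_potential(0.0, 0.9) == pytest.approx(3.0, abs=1e-12)
        assert pair_potential(1.0, 0.9) == pytest.approx(0.0, abs=1e-12)
        assert pair_potential(1.25, 0.9) == pytest.approx(-0.9, abs=1e-12)
        assert pair_potential(1.5, 0.9) == pytest.approx(0.0, abs=1e-12)
        assert pair_potential(2.0, 0.9) == 0.0

    def test_constants_are_exact(self):
        assert A0**2 == pytest.approx(6.0 / 7.0, abs=1e-15)
        assert E0 == 46_656.0 / 823_543.0

    def test_continuity_at_branch_points(self):
        for r0 in (1.0, 1.5):
            below = pair_potential(r0 - 1e-9, 0.9)
            above = pair_potential(r0 + 1e-9, 0.9)
            assert abs(below - above) < 1e-6

    def test_bounds(self):
        """U >= -max(eps) everywhere and U <= E_repel on the core."""
        r = np.linspace(0.0, 3.0, 2001)
        u = pair_potential(r, 0.9)
        assert np.all(u >= -0.9 - 1e-12)
        assert np.all(u[r <= 1.0] <= 3.0 + 1e-12)

    def test_monotone_into_the_well(self):
        r = np.linspace(0.0, 1.25, 500)
        u = pair_potential(r, 0.9)
        assert np.all(np.diff(u) <= 1e-12)

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            pair_potential(-0.1, 0.0)

    def test_radial_force_is_minus_dU_dr(self):
        h = 1e-7
        for r in (0.3, 0.8, 1.1, 1.3, 1.45):
            fd = -(pair_potential(r + h, 0.9) - pair_potential(r - h, 0.9)) / (2 * h)
            assert pair_force(r, 0.9) == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_forces_match_finite_differences_of_total_energy(small_system):
    """Kernel forces = -grad(total energy) to 1e-6 relative (bonds + pairs +
    walls included)."""
    system = small_system
    forces = compute_forces(system)
    h = 1e-6
    num = np.zeros_like(forces)
    for i in range(system.n_monomers):
        for d in range(3):
            orig = system.coords[i, d]
            system.coords[i, d] = orig + h
            ep = total_energy(system)
            system.coords[i, d] = orig - h
            em = total_energy(system)
            system.coords[i, d] = orig
            num[i, d] = -(ep - em) / (2 * h)
    scale = max(np.abs(forces).max(), 1.0)
    assert np.allclose(forces, num, atol=2e-5 * scale)


def test_energy_decreases_under_gradient_descent(small_system):
    system = small_system
    e_prev = total_energy(system)
    for _ in range(20):
        f = compute_forces(system)
        system.coords += 1e-3 * f
        e = total_energy(system)
        assert e <= e_prev + 1e-9
        e_prev = e


class TestInitConformation:
    def test_sphere_radius_from_density_definition(self):
        """R = (a/2) (N / rho)^(1/3) from rho = N * (4/3)pi(a/2)^3 / V."""
        conf = ConfinementSpec("sphere", 0.25)
        R = conf.sphere_radius(100)
        assert R == pytest.approx(0.5 * (100 / 0.25) ** (1 / 3))
        mono_vol = 4 / 3 * np.pi * 0.5**3
        assert 100 * mono_vol / (4 / 3 * np.pi * R**3) == pytest.approx(0.25)

    def test_all_monomers_inside_container(self):
        conf = ConfinementSpec("sphere", 0.25)
        coords = init_conformation(100, conf, seed=11)
        assert np.all(np.linalg.norm(coords, axis=1) <= conf.sphere_radius(100) + 1e-9)

    def test_cylinder_volume_matches_density(self):
        conf = ConfinementSpec("cylinder", 0.65, aspect=4.0)
        r, h = conf.cylinder_radius_height(500)
        assert h == pytest.approx(8 * r)
        mono_vol = 4 / 3 * np.pi * 0.5**3
        assert 500 * mono_vol / (np.pi * r**2 * h) == pytest.approx(0.65)

    def test_two_monomer_bond_length(self):
        coords = init_conformation(2, ConfinementSpec("none"), seed=0)
        assert np.linalg.norm(coords[1] - coords[0]) == pytest.approx(1.0, rel=1e-9)

    def test_fixed_seed_bit_identical(self):
        conf = ConfinementSpec("sphere", 0.25)
        a = init_conformation(50, conf, seed=5)
        b = init_conformation(50, conf, seed=5)
        assert np.array_equal(a, b)

    def test_overfull_container_raises(self):
        with pytest.raises(ValueError):
            init_conformation(10, ConfinementSpec("sphere", 1.5), seed=0)


def test_trajectories_are_deterministic_given_seed():
    typing = MonomerTyping(np.zeros(30, dtype=np.int8))
    conf = ConfinementSpec("sphere", 0.25)

    def one():
        system = PolymerSystem(init_conformation(30, conf, seed=2), typing, confinement=conf)
        return run_polymer(system, None, n_blocks=20, steps_per_block=20, seed=9).frames

    assert np.array_equal(one(), one())


def test_bond_length_statistics_match_boltzmann_oracle():
    """Mean squared bond stretch of the harmonic bond matches the radial
    Boltzmann average (1D Gaussian-measure quadrature oracle) within 2%."""
    k, r0 = 30.0, 1.0
    num = quad(lambda r: (r - r0) ** 2 * r**2 * np.exp(-k / 2 * (r - r0) ** 2), 0, 5)[0]
    den = quad(lambda r: r**2 * np.exp(-k / 2 * (r - r0) ** 2), 0, 5)[0]
    oracle = num / den
    typing = MonomerTyping(np.zeros(2, dtype=np.int8))
    ests = []
    for seed in (1, 2, 3):
        system = PolymerSystem(
            np.array([[0.0, 0, 0], [1.0, 0, 0]]), typing,
            confinement=ConfinementSpec("none"), dt=0.01, gamma=1.0,
        )
        traj = run_polymer(system, None, n_blocks=6000, steps_per_block=100, seed=seed)
        bl = np.linalg.norm(traj.frames[500:, 1] - traj.frames[500:, 0], axis=1)
        ests.append(np.mean((bl - r0) ** 2))
    assert np.mean(ests) == pytest.approx(oracle, rel=0.02)


def test_bridged_pair_is_closer_than_unbridged_control():
    """A static extruder bridge pulls its monomers together relative to an
    unbridged pair at the same genomic separation."""
    n = 120
    typing = MonomerTyping(np.zeros(n, dtype=np.int8))
    conf = ConfinementSpec("sphere", 0.25)
    system = PolymerSystem(init_conformation(n, conf, seed=4), typing, confinement=conf)
    traj = run_polymer(system, [(10, 60)], n_blocks=300, steps_per_block=30, seed=4)
    frames = traj.frames[100:]
    d_bridge = np.linalg.norm(frames[:, 10] - frames[:, 60], axis=1).mean()
    d_ctrl = np.linalg.norm(frames[:, 65] - frames[:, 115], axis=1).mean()
    assert d_bridge < d_ctrl


def test_rg_scaling_exponent_in_excluded_volume_regime():
    """Internal-distance scaling exponent of the free, affinity-less chain
    lies in the self-avoiding-walk band [0.5, 0.65]."""
    n = 200
    typing = MonomerTyping(np.zeros(n, dtype=np.int8))
    system = PolymerSystem(
        init_conformation(n, ConfinementSpec("none"), seed=8), typing,
        confinement=ConfinementSpec("none"),
    )
    traj = run_polymer(system, None, n_blocks=1500, steps_per_block=40, seed=8)
    frames = traj.frames[500:]
    seps = np.array([10, 20, 40, 80])
    r2 = []
    for s in seps:
        d = frames[:, s:] - frames[:, :-s]
        r2.append(np.mean(np.sum(d**2, axis=2)))
    slope = np.polyfit(np.log(seps), 0.5 * np.log(r2), 1)[0]
    assert 0.5 <= slope <= 0.65


class TestSummarize:
    def test_rg_closed_forms(self):
        typing = MonomerTyping(np.zeros(3, dtype=np.int8))
        frames = np.zeros((1, 3, 3))
        traj = Trajectory3D(frames, np.array([1]), typing)
        assert summarize_conformation(traj)["rg"][0] == 0.0
        typing2 = MonomerTyping(np.zeros(2, dtype=np.int8))
        frames2 = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        traj2 = Trajectory3D(frames2, np.array([1]), typing2)
        assert summarize_conformation(traj2)["rg"][0] == pytest.approx(1.0)

    def test_empty_region_raises(self):
        typing = MonomerTyping(np.zeros(3, dtype=np.int8))
        traj = Trajectory3D(np.zeros((1, 3, 3)), np.array([1]), typing)
        with pytest.raises(ValueError):
            summarize_conformation(traj, region=np.array([], dtype=int))

    def test_confined_chain_density_and_walls(self):
        n = 150
        typing = MonomerTyping(np.zeros(n, dtype=np.int8))
        conf = ConfinementSpec("sphere", 0.25, wall_k=20.0)
        system = PolymerSystem(init_conformation(n, conf, seed=3), typing, confinement=conf)
        traj = run_polymer(system, None, n_blocks=200, steps_per_block=25, seed=3)
        out = summarize_conformation(traj, confinement=conf, tol=1.0)
        assert out["density"] == pytest.approx(0.25, rel=1e-6)
        n_points = traj.n_frames * n
        assert out["wall_violations"] <= 0.001 * n_points


def test_nan_coordinates_abort_with_diagnostic():
    typing = MonomerTyping(np.zeros(5, dtype=np.int8))
    system = PolymerSystem(
        init_conformation(5, ConfinementSpec("none"), seed=0), typing,
        confinement=ConfinementSpec("none"), dt=10.0,  # wildly unstable
    )
    with pytest.raises(RuntimeError, match="non-finite"):
        run_polymer(system, None, n_blocks=50, steps_per_block=50, seed=0)


def test_mismatched_lattice_and_polymer_lengths_raise():
    from chromodyn.extrusion import ExtruderSpecies, LatticeConfig, run_extrusion

    config = LatticeConfig(L=50, seed=0)
    species = [ExtruderSpecies("x", 100.0, 12.5)]
    traj1d = run_extrusion(config, species, None, 10, stride=1)
    typing = MonomerTyping(np.zeros(40, dtype=np.int8))
    system = PolymerSystem(
        init_conformation(40, ConfinementSpec("none"), seed=0), typing,
        confinement=ConfinementSpec("none"),
    )
    with pytest.raises(ValueError, match="lattice length"):
        run_polymer(system, traj1d, n_blocks=5, steps_per_block=10, seed=0)
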