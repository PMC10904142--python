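"""Generators: chirality labeling and many-body physics."""

import numpy as np
import pytest

from gcpnet.geometry import random_rotation
from gcpnet.synthetic_data import (
    NBodyConstants,
    chirality_label,
    generate_chiral_dataset,
    make_forecast_dataset,
    simulate_many,
    simulate_nbody,
    total_energy,
    trajectory_from_csv,
    trajectory_to_csv,
)


class TestChiralDataset:
    def test_mirror_pairs_carry_opposite_labels(self):
        mols = generate_chiral_dataset(40, seed=0)
        for base, mirror in zip(mols[::2], mols[1::2]):
            assert base.label != mirror.label
            np.testing.assert_allclose(mirror.positions[:, 0],
                                       -base.positions[:, 0])
        labels = [m.label for m in mols]
        assert labels.count("R") == labels.count("S")

    def test_label_invariant_under_rotation(self):
        mols = generate_chiral_dataset(20, seed=1)
        for i, mol in enumerate(mols):
            q = random_rotation(np.random.default_rng(i))
            rotated, _ = chirality_label(mol.positions @ q.T,
                                         mol.substituent_priorities)
            assert rotated == mol.label

    def test_label_flips_under_any_reflection_plane(self):
        mols = generate_chiral_dataset(20, seed=2)
        for axis in range(3):
            mirror = np.eye(3)
            mirror[axis, axis] = -1.0
            for mol in mols[:6]:
                flipped, _ = chirality_label(mol.positions @ mirror,
                                             mol.substituent_priorities)
                assert flipped != mol.label

    def test_label_agrees_with_independent_signed_volume_oracle(self):
        # oracle: scalar triple product computed from scratch, no np.linalg.det
        mols = generate_chiral_dataset(100, seed=3)
        for mol in mols:
            subs = mol.positions[1:] - mol.positions[0]
            order = np.argsort(mol.substituent_priorities)
            v1, v2, v3, v4 = subs[order]
            triple = np.dot(v1 - v4, np.cross(v2 - v4, v3 - v4))
            assert ("R" if triple > 0 else "S") == mol.label

    def test_seeded_regeneration_is_bitwise_identical(self):
        a = generate_chiral_dataset(30, seed=7)
        b = generate_chiral_dataset(30, seed=7)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.positions, mb.positions)
            assert ma.label == mb.label

    def test_substituents_are_in_general_position(self):
        for mol in generate_chiral_dataset(50, seed=4):
            _, det = chirality_label(mol.positions, mol.substituent_priorities)
            assert abs(det) > 1e-6

    def test_rejects_odd_counts(self):
        with pytest.raises(ValueError, match="mirror pairs"):
            generate_chiral_dataset(7, seed=0)


class TestNBodySimulator:
    def test_opposite_charges_at_rest_attract_and_momentum_is_conserved(self):
        c = NBodyConstants(vel_std=0.0)      # start from rest
        traj = simulate_nbody(2, "ES", n_steps=50, dt=1e-2, seed=0, constants=c)
        assert set(traj.charges) == {-1.0, 1.0}
        rel = traj.positions[:, 0] - traj.positions[:, 1]
        dist = np.linalg.norm(rel, axis=1)
        # attraction from rest: the pair closes in (the softened core lets
        # them pass through later, so only the initial approach is monotone)
        assert dist[10] < dist[0]
        assert dist.min() < 0.5 * dist[0]
        momentum = traj.velocities.sum(axis=1)
        assert np.abs(momentum - momentum[0]).max() < 1e-10
        np.testing.assert_allclose(momentum[0], 0.0, atol=1e-15)

    def test_es_momentum_conservation_many_bodies(self):
        traj = simulate_nbody(5, "ES", n_steps=1200, dt=1e-2, seed=1)
        momentum = traj.velocities.sum(axis=1)
        assert np.abs(momentum - momentum[0]).max() < 1e-10
        assert np.all(np.isfinite(traj.positions))

    def test_rotated_initial_state_yields_rotated_trajectory(self):
        # ES dynamics commute with rotations; emulate by rotating after the
        # fact and comparing against a run that is identical by construction
        traj = simulate_nbody(5, "ES", n_steps=300, dt=1e-2, seed=2)
        q = random_rotation(np.random.default_rng(0))
        from gcpnet.synthetic_data import _accelerations

        c = NBodyConstants()
        x = traj.positions[0] @ q.T
        v = traj.velocities[0] @ q.T
        charges = traj.charges
        a = _accelerations(x[None], v[None], charges[None], "ES", c)[0]
        for step in range(300):
            v_half = v + 0.5 * 1e-2 * a
            x = x + 1e-2 * v_half
            a = _accelerations(x[None], v_half[None], charges[None], "ES", c)[0]
            v = v_half + 0.5 * 1e-2 * a
        np.testing.assert_allclose(x, traj.positions[300] @ q.T, atol=1e-8)

    def test_energy_drift_shrinks_with_time_step(self):
        drifts = []
        for dt, steps in ((1e-2, 400), (5e-3, 800), (2.5e-3, 1600)):
            traj = simulate_nbody(5, "ES", n_steps=steps, dt=dt, seed=3)
            e0 = total_energy(traj, 0)
            energies = [total_energy(traj, f) for f in range(0, steps + 1,
                                                             steps // 20)]
            drifts.append(max(abs(e - e0) for e in energies))
        assert drifts[0] > drifts[1] > drifts[2]

    def test_gravity_field_breaks_so3_but_keeps_z_rotations(self):
        traj = simulate_nbody(5, "G+ES", n_steps=200, dt=1e-2, seed=4)
        theta = 0.7
        qz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        from gcpnet.synthetic_data import _accelerations

        c = NBodyConstants()
        x0, v0 = traj.positions[0], traj.velocities[0]
        qq = traj.charges[None]
        a_rot = _accelerations((x0 @ qz.T)[None], (v0 @ qz.T)[None], qq,
                               "G+ES", c)[0]
        a_ref = _accelerations(x0[None], v0[None], qq, "G+ES", c)[0]
        np.testing.assert_allclose(a_rot, a_ref @ qz.T, atol=1e-12)
        # a generic rotation does NOT commute (gravity picks out z)
        qgen = random_rotation(np.random.default_rng(1))
        a_gen = _accelerations((x0 @ qgen.T)[None], (v0 @ qgen.T)[None], qq,
                               "G+ES", c)[0]
        assert np.abs(a_gen - a_ref @ qgen.T).max() > 1e-3

    def test_single_charge_lorentz_orbit_matches_cyclotron_radius(self):
        # one particle, no partner forces: analytic circular orbit of radius
        # |v_perp| / (|q| B0); use two particles far apart to satisfy N >= 2
        c = NBodyConstants(softening=0.1, b_field=1.0, pos_std=1.0, vel_std=0.5)
        dt = 1e-3
        n_steps = int(2 * np.pi / (c.b_field * dt))    # one gyration period
        from gcpnet.synthetic_data import _accelerations

        x = np.array([[0.0, 0, 0], [1e6, 1e6, 0]])
        v = np.array([[0.4, 0.0, 0.0], [0.0, 0.0, 0.0]])
        q = np.array([1.0, -1.0])
        pos = [x[0].copy()]
        a = _accelerations(x[None], v[None], q[None], "L+ES", c)[0]
        for _ in range(n_steps):
            v_half = v + 0.5 * dt * a
            x = x + dt * v_half
            a = _accelerations(x[None], v_half[None], q[None], "L+ES", c)[0]
            v = v_half + 0.5 * dt * a
            a = _accelerations(x[None], v[None], q[None], "L+ES", c)[0]
            v = v_half + 0.5 * dt * a
            pos.append(x[0].copy())
        pos = np.asarray(pos)
        center = pos.mean(axis=0)
        radii = np.linalg.norm(pos - center, axis=1)
        expected = 0.4 / (1.0 * c.b_field)
        assert abs(radii.mean() - expected) / expected < 0.01

    def test_batched_and_single_simulations_agree(self):
        single = simulate_nbody(4, "ES", n_steps=50, dt=1e-2, seed=5)
        batch = simulate_many(1, 4, "ES", 50, 1e-2, seed=5)[0]
        np.testing.assert_array_equal(single.positions, batch.positions)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_nbody(1, "ES", 10, 1e-2, 0)
        with pytest.raises(ValueError):
            simulate_nbody(3, "ES", 10, -1e-2, 0)
        with pytest.raises(ValueError):
            simulate_nbody(3, "XX", 10, 1e-2, 0)


class TestForecastDataset:
    def test_zero_horizon_target_equals_input(self):
        traj = simulate_nbody(4, "ES", 50, 1e-2, seed=6)
        cloud, target = make_forecast_dataset(traj, 10, 0)
        np.testing.assert_array_equal(cloud.positions, target)

    def test_free_flight_closed_form_without_interactions(self):
        # zero-charge product: use a single pair held apart so forces vanish
        c = NBodyConstants(pos_std=0.0, vel_std=0.0)
        traj = simulate_nbody(2, "ES", 100, 1e-2, seed=7, constants=c)
        # both particles start at the origin with zero velocity: forces are
        # finite (softened) and symmetric; instead test genuine free flight
        # with well-separated particles
        x0 = np.array([[0.0, 0, 0], [1e5, 0, 0]])
        v0 = np.array([[1.0, 2.0, 3.0], [0.0, 0, 0]])
        from gcpnet.synthetic_data import Trajectory, _accelerations

        x, v = x0.copy(), v0.copy()
        qs = np.array([1.0, -1.0])
        frames = [x.copy()]
        vels = [v.copy()]
        a = _accelerations(x[None], v[None], qs[None], "ES", NBodyConstants())[0]
        for _ in range(100):
            v_half = v + 0.5e-2 * a
            x = x + 1e-2 * v_half
            a = _accelerations(x[None], v_half[None], qs[None], "ES",
                               NBodyConstants())[0]
            v = v_half + 0.5e-2 * a
            frames.append(x.copy())
            vels.append(v.copy())
        traj = Trajectory(np.asarray(frames), np.asarray(vels), qs, "ES", 1e-2,
                          meta={"constants": {"softening": 0.1}})
        cloud, target = make_forecast_dataset(traj, 0, 100)
        np.testing.assert_allclose(target[0],
                                   x0[0] + v0[0] * 100 * 1e-2, atol=1e-6)

    def test_out_of_range_rejected(self):
        traj = simulate_nbody(3, "ES", 50, 1e-2, seed=8)
        with pytest.raises(IndexError):
            make_forecast_dataset(traj, 40, 20)


class TestTrajectoryIO:
    def test_csv_roundtrip(self, tmp_path):
        traj = simulate_nbody(3, "ES", 20, 1e-2, seed=9)
        path = tmp_path / "traj.csv"
        trajectory_to_csv(path, traj)
        back = trajectory_from_csv(path)
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-12)
        np.testing.assert_allclose(back.velocities, traj.velocities, atol=1e-12)
        np.testing.assert_array_equal(back.charges, traj.charges)
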