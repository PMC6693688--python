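"""School-simulator unit and property tests."""

import numpy as np
import pytest

import flashschool as fs
from flashschool.errors import (
    DegenerateGeometryError,
    InvalidConfigError,
)
from conftest import make_agent


class TestInit:
    def test_agents_start_at_rest_inside_cube(self):
        sim = fs.init_school(fs.SimConfig(n_fish=100, seed=42))
        assert sim.positions.shape == (100, 3)
        assert np.all(np.abs(sim.positions) <= 10.0)
        assert np.all(sim.velocities == 0)
        assert np.all(sim.accelerations == 0)

    @pytest.mark.parametrize("D,expect_dark", [(1.0, True), (0.0, False)])
    def test_dark_assignment_edge_cases(self, D, expect_dark):
        sim = fs.init_school(fs.SimConfig(n_fish=50, D=D, seed=1))
        assert np.all(sim.dark == expect_dark)

    def test_init_reproducible_under_seed(self):
        a = fs.init_school(fs.SimConfig(n_fish=20, seed=9))
        b = fs.init_school(fs.SimConfig(n_fish=20, seed=9))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.dark, b.dark)

    def test_invalid_fish_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            fs.SimConfig(n_fish=0)

    @pytest.mark.parametrize("bad", [{"P": 1.5}, {"D": -0.1}, {"dt": 0.0}, {"v_max": 0.0}])
    def test_invalid_config_values_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            fs.SimConfig(**bad)


class TestVisibleNeighbors:
    region = fs.VisionRegion(radius=10.0, blind_behind_deg=90.0)

    def test_neighbor_in_rear_blind_cone_excluded(self):
        focal = make_agent((0, 0, 0), velocity=(1, 0, 0))
        behind = make_agent((-1, 0, 0))
        assert fs.visible_neighbors(focal, [focal, behind], self.region) == []

    def test_neighbor_beyond_radius_excluded(self):
        focal = make_agent((0, 0, 0), velocity=(1, 0, 0))
        far = make_agent((10.0 + 1e-6, 0, 0))
        assert fs.visible_neighbors(focal, [focal, far], self.region) == []

    def test_non_flashing_neighbor_invisible_when_gated(self):
        focal = make_agent((0, 0, 0), velocity=(1, 0, 0))
        other = make_agent((2, 0, 0), flashing=False)
        assert fs.visible_neighbors(focal, [focal, other], self.region, flash_gated=True) == []
        assert fs.visible_neighbors(focal, [focal, other], self.region, flash_gated=False) == [other]

    def test_focal_at_rest_has_no_blind_cone(self):
        focal = make_agent((0, 0, 0))
        behind = make_agent((-1, 0, 0))
        assert fs.visible_neighbors(focal, [focal, behind], self.region) == [behind]

    def test_frontal_blind_cone(self):
        region = fs.VisionRegion(radius=10.0, blind_front_deg=60.0)
        focal = make_agent((0, 0, 0), velocity=(1, 0, 0))
        ahead = make_agent((1, 0, 0))
        side = make_agent((0, 1, 0))
        vis = fs.visible_neighbors(focal, [focal, ahead, side], region)
        assert vis == [side]


class TestForces:
    def test_cohesion_pulls_toward_centroid_at_vmax(self):
        focal = make_agent((0, 0, 0))
        vis = [make_agent((2, 0, 0))]
        np.testing.assert_allclose(fs.cohesion_force(focal, vis, v_max=1.0), [1, 0, 0])

    def test_cohesion_vanishes_at_matched_velocity(self):
        focal = make_agent((0, 0, 0), velocity=(1, 0, 0))
        vis = [make_agent((2, 0, 0))]
        np.testing.assert_allclose(fs.cohesion_force(focal, vis, v_max=1.0), [0, 0, 0])

    def test_cohesion_empty_neighborhood_is_zero(self):
        focal = make_agent((0, 0, 0), velocity=(1, 0, 0))
        np.testing.assert_allclose(fs.cohesion_force(focal, [], v_max=1.0), [0, 0, 0])

    def test_alignment_matches_neighbor_heading(self):
        focal = make_agent((0, 0, 0))
        vis = [make_agent((1, 0, 0), velocity=(0, 1, 0)), make_agent((0, 1, 0), velocity=(0, 1, 0))]
        np.testing.assert_allclose(fs.alignment_force(focal, vis, v_max=1.0), [0, 1, 0])

    def test_alignment_vanishes_when_already_aligned(self):
        focal = make_agent((0, 0, 0), velocity=(0, 1, 0))
        vis = [make_agent((1, 0, 0), velocity=(0, 1, 0))]
        np.testing.assert_allclose(fs.alignment_force(focal, vis, v_max=1.0), [0, 0, 0])

    def test_alignment_opposed_neighbors_cancel_to_zero(self):
        focal = make_agent((0, 0, 0))
        vis = [make_agent((1, 0, 0), velocity=(0, 1, 0)), make_agent((0, 1, 0), velocity=(0, -1, 0))]
        np.testing.assert_allclose(fs.alignment_force(focal, vis, v_max=1.0), [0, 0, 0])

    def test_separation_pushes_away_inverse_distance(self):
        focal = make_agent((0, 0, 0))
        vis = [make_agent((1, 0, 0))]
        np.testing.assert_allclose(fs.separation_force(focal, vis, v_max=1.0), [-1, 0, 0])

    def test_separation_two_neighbor_hand_value(self):
        focal = make_agent((0, 0, 0))
        vis = [make_agent((1, 0, 0)), make_agent((0, 2, 0))]
        # mean of {(-1,0,0), (0,-0.5,0)} normalised
        expected = np.array([-0.5, -0.25, 0.0])
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(fs.separation_force(focal, vis, v_max=1.0), expected, atol=1e-12)

    def test_separation_coincident_neighbor_is_degenerate(self):
        focal = make_agent((0, 0, 0))
        with pytest.raises(DegenerateGeometryError):
            fs.separation_force(focal, [make_agent((0, 0, 0))], v_max=1.0)

    def test_internal_forces_at_rest_and_at_cruise(self):
        cfg = fs.SimConfig(n_fish=1, v_max=2.0, v_cruise=1.0)
        fric, spd = fs.internal_forces(make_agent((0, 0, 0)), cfg)
        np.testing.assert_allclose(fric, [0, 0, 0])
        np.testing.assert_allclose(spd, [0, 0, 0])
        fric, spd = fs.internal_forces(make_agent((0, 0, 0), velocity=(2, 0, 0)), cfg)
        np.testing.assert_allclose(fric, [-2, 0, 0])
        fric, spd = fs.internal_forces(make_agent((0, 0, 0), velocity=(1, 0, 0)), cfg)
        np.testing.assert_allclose(spd, [0, 0, 0])

    def test_vectorised_forces_match_single_agent_functions(self):
        """The batched engine must agree with the per-agent force formulas."""
        cfg = fs.SimConfig(n_fish=12, seed=3, P=1.0)
        sim = fs.init_school(cfg)
        sim.velocities = np.random.default_rng(0).normal(size=(12, 3))
        forces = sim.compute_forces()
        agents = sim.agent_states()
        for i, focal in enumerate(agents):
            for name, fn, region in [
                ("cohesion", fs.cohesion_force, cfg.cohesion_region),
                ("alignment", fs.alignment_force, cfg.alignment_region),
                ("separation", fs.separation_force, cfg.separation_region),
            ]:
                vis = fs.visible_neighbors(focal, agents, region, flash_gated=True)
                np.testing.assert_allclose(
                    forces[name][i], fn(focal, vis, cfg.v_max), atol=1e-10,
                    err_msg=f"{name} mismatch for agent {i}",
                )
            fric, spd = fs.internal_forces(focal, cfg)
            np.testing.assert_allclose(forces["friction"][i], fric, atol=1e-12)
            np.testing.assert_allclose(forces["speed_control"][i], spd, atol=1e-12)


class TestStep:
    def test_isolated_fish_at_rest_stays_at_rest(self):
        sim = fs.init_school(fs.SimConfig(n_fish=1, seed=0))
        p0 = sim.positions.copy()
        for _ in range(10):
            sim.step()
        np.testing.assert_array_equal(sim.positions, p0)
        np.testing.assert_array_equal(sim.velocities, 0)

    def test_mirror_symmetric_pair_stays_symmetric(self):
        sim = fs.init_school(fs.SimConfig(n_fish=2, P=1.0, seed=0))
        sim.positions = np.array([[2.0, 0.5, -1.0], [-2.0, -0.5, 1.0]])
        sim.velocities = np.zeros((2, 3))
        for _ in range(50):
            sim.step()
            np.testing.assert_allclose(sim.positions[0], -sim.positions[1], atol=1e-9)
            np.testing.assert_allclose(sim.velocities[0], -sim.velocities[1], atol=1e-9)

    @pytest.mark.parametrize("P,expect", [(1.0, True), (0.0, False)])
    def test_bernoulli_flash_edge_cases(self, P, expect):
        sim = fs.init_school(fs.SimConfig(n_fish=30, P=P, D=0.0, seed=2))
        for _ in range(5):
            sim.step()
            assert np.all(sim.flashing == expect)

    def test_dark_fish_never_flash(self):
        sim = fs.init_school(fs.SimConfig(n_fish=30, P=1.0, D=1.0, seed=2))
        for _ in range(5):
            sim.step()
            assert not np.any(sim.flashing)

    def test_square_wave_alternates_with_on_off_durations(self):
        cfg = fs.SimConfig(
            n_fish=3, flash_mode="square_wave", flash_on_s=5 / 30, flash_off_s=5 / 30, seed=4
        )
        sim = fs.init_school(cfg)
        states = []
        for _ in range(40):
            states.append(sim.flashing.copy())
            sim.step()
        states = np.array(states)
        # each agent alternates in runs of 5 frames (period 10)
        for i in range(3):
            col = states[:, i].astype(int)
            changes = np.flatnonzero(np.diff(col) != 0)
            runs = np.diff(changes)
            assert np.all(runs == 5)


class TestMotivated:
    def test_motivated_speed_capped_at_vmax(self):
        sim = fs.init_school(fs.SimConfig(n_fish=5, seed=1))
        sim.set_motivated([0], (1, 0, 0), speed_factor=1e6)
        sim.step()
        assert np.linalg.norm(sim.velocities[0]) == pytest.approx(sim.config.v_max)

    def test_all_motivated_school_is_perfectly_polarised(self):
        sim = fs.init_school(fs.SimConfig(n_fish=10, seed=1))
        sim.set_motivated(list(range(10)), (0, 0, 1), speed_factor=1.0)
        sim.step()
        assert fs.msync(sim.velocities) == pytest.approx(1.0)

    def test_unknown_agent_id_rejected(self):
        sim = fs.init_school(fs.SimConfig(n_fish=5, seed=1))
        with pytest.raises(InvalidConfigError):
            sim.set_motivated([99], (1, 0, 0))

    def test_dark_leader_rejected(self):
        sim = fs.init_school(fs.SimConfig(n_fish=5, D=1.0, seed=1))
        with pytest.raises(InvalidConfigError):
            sim.set_motivated([0], (1, 0, 0))


class TestRun:
    def test_single_step_run_keeps_initial_frame(self):
        cfg = fs.SimConfig(n_fish=8, seed=6)
        init = fs.init_school(cfg)
        p0, v0 = init.positions.copy(), init.velocities.copy()
        traj = fs.run_simulation(cfg, 1)
        assert traj.n_frames == 2
        np.testing.assert_array_equal(traj.positions[0], p0)
        np.testing.assert_array_equal(traj.velocities[0], v0)

    def test_identical_seed_gives_identical_trajectory(self):
        cfg = fs.SimConfig(n_fish=15, seed=8)
        a = fs.run_simulation(cfg, 30)
        b = fs.run_simulation(fs.SimConfig(n_fish=15, seed=8), 30)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.flashing, b.flashing)

    def test_speed_never_exceeds_vmax(self, default_run):
        cfg, traj = default_run
        speeds = np.linalg.norm(traj.velocities, axis=2)
        assert speeds.max() <= cfg.v_max + 1e-9

    def test_schooling_emerges_from_rest(self, default_run):
        """Polarisation builds from a random resting start to a schooling
        steady state."""
        _, traj = default_run
        early = [fs.msync(traj.velocities[t]) for t in range(1, 30)]
        late = [fs.msync(traj.velocities[t]) for t in range(traj.n_frames - 100, traj.n_frames)]
        assert np.mean(late) > 0.7
        assert np.mean(late) > np.mean(early) + 0.3

    def test_rotational_equivariance_with_deterministic_flashing(self):
        """With P=1 the dynamics are deterministic, so rotating the initial
        state rotates the whole trajectory."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
        cfg = fs.SimConfig(n_fish=20, P=1.0, seed=13)
        simA = fs.init_school(cfg)
        simB = fs.init_school(cfg)
        simB.positions = simA.positions @ rot.T
        simB.velocities = simA.velocities @ rot.T
        for _ in range(40):
            simA.step()
            simB.step()
        np.testing.assert_allclose(simB.positions, simA.positions @ rot.T, atol=1e-8)
        np.testing.assert_allclose(simB.velocities, simA.velocities @ rot.T, atol=1e-8)

    def test_trajectory_csv_round_trip(self, tmp_path):
        cfg = fs.SimConfig(n_fish=6, seed=2)
        traj = fs.run_simulation(cfg, 5)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = fs.SchoolTrajectory.from_csv(path, dt=cfg.dt)
        np.testing.assert_allclose(back.positions, traj.positions)
        np.testing.assert_array_equal(back.flashing, traj.flashing)

    def test_interventions_fire_at_scheduled_frame(self):
        cfg = fs.SimConfig(n_fish=10, seed=3)
        sim = fs.init_school(cfg)
        traj = sim.run(20, interventions=[(10, lambda s: s.set_motivated([0], (1, 0, 0)))])
        assert not traj.motivated[10, 0]
        assert traj.motivated[11, 0]

    def test_dark_fraction_intervention_relights_fish(self):
        sim = fs.init_school(fs.SimConfig(n_fish=40, D=1.0, P=1.0, seed=3))
        assert np.all(sim.dark)
        sim.set_dark_fraction(0.0)
        sim.step()
        assert not np.any(sim.dark)
        assert np.all(sim.flashing)
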