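import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydrasite.constants import BULK_WATER_DENSITY, R_KCAL
from hydrasite.trajectory_thermo import (WaterTrajectory, accumulate_density,
                                         extract_sites, free_energy,
                                         occupancy, site_enthalpy,
                                         site_entropy, site_observations)


class TestDensityGrid:
    def test_static_water_fills_single_voxel(self):
        traj = WaterTrajectory(frames=[np.array([[1.0, 2.0, 3.0]])] * 100)
        grid = accumulate_density(traj)
        assert grid.counts.max() == 100
        assert grid.counts.sum() == 100

    def test_conservation_matches_binning_oracle(self):
        rng = np.random.default_rng(0)
        frames = [rng.uniform(0, 5, size=(rng.integers(0, 8), 3))
                  for _ in range(50)]
        traj = WaterTrajectory(frames=frames)
        lo, hi = np.zeros(3), np.full(3, 5.0)
        grid = accumulate_density(traj, bounds=(lo, hi))
        all_xyz = np.vstack([f for f in frames if len(f)])
        assert grid.counts.sum() == len(all_xyz)
        # independent binning oracle
        expected = np.zeros_like(grid.counts)
        for p in all_xyz:
            i, j, k = np.floor((p - grid.origin) / grid.spacing).astype(int)
            expected[i, j, k] += 1
        np.testing.assert_array_equal(grid.counts, expected)

    def test_out_of_bounds_water_not_counted(self):
        traj = WaterTrajectory(frames=[np.array([[10.0, 10.0, 10.0]])])
        grid = accumulate_density(traj, bounds=(np.zeros(3), np.full(3, 2.0)))
        assert grid.counts.sum() == 0


class TestExtractSites:
    def test_single_blob_recovered(self):
        rng = np.random.default_rng(1)
        center = np.array([2.0, 3.0, 1.0])
        frames = [center + rng.normal(0, 0.3, size=(1, 3)) for _ in range(1000)]
        grid = accumulate_density(WaterTrajectory(frames=frames))
        sites = extract_sites(grid)
        assert len(sites) == 1
        assert np.linalg.norm(sites[0] - center) < 0.25

    def test_two_blobs_six_angstrom_apart(self):
        rng = np.random.default_rng(2)
        c1, c2 = np.zeros(3), np.array([6.0, 0, 0])
        frames = [np.vstack([c1 + rng.normal(0, 0.2, 3),
                             c2 + rng.normal(0, 0.2, 3)]) for _ in range(500)]
        grid = accumulate_density(WaterTrajectory(frames=frames))
        assert len(extract_sites(grid)) == 2

    def test_empty_grid_gives_no_sites(self):
        traj = WaterTrajectory(frames=[np.zeros((0, 3)) for _ in range(5)])
        grid = accumulate_density(traj, bounds=(np.zeros(3), np.full(3, 2.0)))
        assert len(extract_sites(grid)) == 0


class TestOccupancy:
    def test_always_present(self):
        traj = WaterTrajectory(frames=[np.array([[0.0, 0, 0]])] * 10)
        assert occupancy(np.zeros(3), traj) == 1.0

    def test_exact_half(self):
        frames = [np.array([[0.0, 0, 0]]) if i % 2 == 0 else np.zeros((0, 3))
                  for i in range(1000)]
        assert occupancy(np.zeros(3), WaterTrajectory(frames=frames)) == 0.5

    def test_planted_occupancy_recovered(self):
        rng = np.random.default_rng(3)
        frames = [np.array([[0.0, 0, 0]]) + rng.normal(0, 0.2, (1, 3))
                  if rng.random() < 0.73 else np.zeros((0, 3))
                  for _ in range(1000)]
        est = occupancy(np.zeros(3), WaterTrajectory(frames=frames))
        assert est == pytest.approx(0.73, abs=0.05)


class TestEnthalpy:
    def test_equal_to_bulk_gives_zero(self):
        assert site_enthalpy(np.full(10, -19.0), -19.0) == 0.0

    def test_mean_minus_bulk(self):
        assert site_enthalpy(np.array([-20.0, -22.0]), -19.0) == \
            pytest.approx(-2.0)

    def test_translation_invariance(self):
        e = np.array([-20.0, -22.0, -18.5])
        assert site_enthalpy(e, -19.0) == pytest.approx(
            site_enthalpy(e + 7.3, -19.0 + 7.3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            site_enthalpy(np.array([]), -19.0)


def _uniform_sphere(n, rng, radius=1.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return v * radius * rng.random(n)[:, None] ** (1 / 3)


class TestEntropy:
    def test_uniform_sphere_matches_analytic(self):
        """Translational part approaches R ln(V C) as the bins shrink.

        The error of the h/2 estimate is bounded by the h -> h/2 successive
        difference (first-order convergent histogram estimator).
        """
        rng = np.random.default_rng(4)
        pos = _uniform_sphere(60_000, rng)
        analytic = R_KCAL * np.log(4 / 3 * np.pi * BULK_WATER_DENSITY)
        est_h = site_entropy(pos, None, trans_bin=0.25)
        est_h2 = site_entropy(pos, None, trans_bin=0.125)
        assert abs(est_h2 - analytic) <= abs(est_h - est_h2)

    def test_convergence_toward_analytic(self):
        """Halving the bin width contracts the deviation from the truth."""
        rng = np.random.default_rng(5)
        pos = _uniform_sphere(60_000, rng)
        analytic = R_KCAL * np.log(4 / 3 * np.pi * BULK_WATER_DENSITY)
        err_h = abs(site_entropy(pos, None, trans_bin=0.25) - analytic)
        err_h2 = abs(site_entropy(pos, None, trans_bin=0.125) - analytic)
        assert err_h2 < err_h

    def test_gaussian_matches_analytic(self):
        rng = np.random.default_rng(6)
        sigma = 0.25
        pos = rng.normal(0, sigma, size=(60_000, 3))
        analytic = R_KCAL * (np.log(BULK_WATER_DENSITY)
                             + 1.5 * np.log(2 * np.pi * np.e * sigma ** 2))
        est = site_entropy(pos, None, trans_bin=0.125)
        assert est == pytest.approx(analytic, rel=0.05)

    def test_tighter_spread_more_negative(self):
        rng = np.random.default_rng(7)
        tight = site_entropy(rng.normal(0, 0.1, (5000, 3)), None)
        loose = site_entropy(rng.normal(0, 0.3, (5000, 3)), None)
        assert tight < loose

    def test_duplication_invariance(self):
        rng = np.random.default_rng(8)
        pos = rng.normal(0, 0.2, (500, 3))
        a = site_entropy(pos, None)
        b = site_entropy(np.vstack([pos, pos]), None)
        assert a == pytest.approx(b, rel=1e-12)

    def test_uniform_orientations_add_nothing(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(0, 0.2, (20_000, 3))
        quats = Rotation.random(20_000, random_state=10).as_quat()
        no_rot = site_entropy(pos, None)
        with_rot = site_entropy(pos, quats)
        # uniform rotational PDF: KL term vanishes up to sampling noise
        assert abs(with_rot - no_rot) < 0.12 * abs(no_rot)

    def test_concentrated_orientations_cost_entropy(self):
        rng = np.random.default_rng(11)
        pos = rng.normal(0, 0.2, (5000, 3))
        base = Rotation.random(random_state=12)
        wobble = Rotation.from_rotvec(rng.normal(0, 0.1, size=(5000, 3)))
        quats = (base * wobble).as_quat()
        assert site_entropy(pos, quats) < site_entropy(pos, None)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10"):
            site_entropy(np.zeros((10, 3)), None)


class TestFreeEnergy:
    def test_arithmetic(self):
        assert free_energy(-2.0, -1.0 / 300.0, 300.0) == pytest.approx(-1.0)

    def test_zero_entropy(self):
        assert free_energy(-2.0, 0.0) == -2.0

    def test_identity(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            dh, ds = rng.normal(size=2)
            assert free_energy(dh, ds) + 300.0 * ds - dh == pytest.approx(0.0)


class TestRoundTrip:
    def test_planted_sites_recovered(self, planted_trajectory):
        """Full loop: planted sites -> trajectory -> analysis recovers
        centers (<= 0.3 A), occupancies (+-0.05) and enthalpies."""
        spec, structure, sites, traj = planted_trajectory
        grid = accumulate_density(traj)
        centers = extract_sites(grid)
        for s in sites:
            if s.occupancy < 0.5:
                continue
            d = np.linalg.norm(centers - s.center, axis=1)
            assert d.min() <= 0.3
            recovered = centers[np.argmin(d)]
            occ = occupancy(recovered, traj)
            assert occ == pytest.approx(s.occupancy, abs=0.05)
            _, ene, _ = site_observations(recovered, traj)
            assert site_enthalpy(ene, spec.bulk_energy) == \
                pytest.approx(s.dH, abs=0.1)
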