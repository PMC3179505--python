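import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from pathmeta.analysis import (
    SegmentAxis,
    SwitchingParams,
    barrier_height,
    basin_delta_g,
    cluster_single_linkage,
    coordination_count,
    find_basins,
    hydration_map,
    is_catalytically_competent,
    monitor_dihedral,
    monitor_distance,
    rmsd_rmsf,
)
from pathmeta.core import Configuration, Trajectory
from pathmeta.metadynamics import FreeEnergySurface

from .oracles import clusters_by_union_find, minimax_barrier_by_percolation


def surface_from(values):
    values = np.asarray(values, dtype=float)
    values = values - values.min()
    return FreeEnergySurface(
        np.arange(values.shape[0], dtype=float),
        np.arange(values.shape[1], dtype=float),
        values,
    )


def gaussian_wells(depths, centers, shape=(60, 40), width=4.0):
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    v = np.zeros(shape)
    for d, (ci, cj) in zip(depths, centers):
        v -= d * np.exp(-(((ii - ci) ** 2) + ((jj - cj) ** 2)) / (2 * width**2))
    return surface_from(v)


class TestBasins:
    def test_two_wells_and_their_delta_g(self):
        fes = gaussian_wells([6.0, 3.0], [(15, 20), (45, 20)])
        basins = find_basins(fes, min_depth=1.0)
        assert len(basins) == 2
        assert basins[0].depth == pytest.approx(0.0)
        dg = basin_delta_g(fes, basins[0], basins[1])
        assert dg == pytest.approx(3.0, abs=0.05)
        assert basin_delta_g(fes, basins[0], basins[0]) == 0.0

    def test_single_well(self):
        fes = gaussian_wells([5.0], [(30, 20)])
        assert len(find_basins(fes, 1.0)) == 1

    def test_flat_surface_has_no_basins(self):
        assert find_basins(surface_from(np.zeros((10, 10))), 1.0) == []

    def test_three_wells_match_brute_force_minimum_scan(self):
        fes = gaussian_wells([6.0, 4.0, 2.5], [(10, 10), (30, 30), (50, 8)], width=3.0)
        basins = find_basins(fes, min_depth=0.5)
        v = fes.values
        brute = []
        for i in range(1, v.shape[0] - 1):
            for j in range(1, v.shape[1] - 1):
                patch = v[i - 1 : i + 2, j - 1 : j + 2]
                if v[i, j] == patch.min() and (patch > v[i, j]).sum() == 8:
                    brute.append((i, j))
        assert len(basins) == len(brute) == 3
        assert sorted(b.min_index for b in basins) == sorted(brute)

    def test_shallow_basins_merged(self):
        fes = gaussian_wells([6.0, 0.4], [(15, 20), (45, 20)])
        assert len(find_basins(fes, min_depth=1.0)) == 1
        assert len(find_basins(fes, min_depth=0.05)) == 2

    def test_unknown_label(self):
        from pathmeta.analysis import _resolve_basin

        fes = gaussian_wells([5.0], [(30, 20)])
        basins = find_basins(fes, 1.0)
        with pytest.raises(KeyError):
            _resolve_basin(basins, "Z")


class TestBarriers:
    def test_constructed_ridge(self):
        v = np.zeros((21, 11))
        v[:5] = -5.0  # deep left basin
        v[10] = 5.0  # ridge 5 above the shallow side, 10 above the deep side
        v[15:] = 0.0
        fes = surface_from(v)
        basins = find_basins(fes, 0.5)
        assert len(basins) == 2
        deep, shallow = basins[0], basins[1]
        assert barrier_height(fes, deep, shallow) == pytest.approx(10.0)
        assert barrier_height(fes, shallow, deep) == pytest.approx(5.0)

    def test_self_barrier_is_zero(self):
        fes = gaussian_wells([5.0], [(30, 20)])
        b = find_basins(fes, 1.0)[0]
        assert barrier_height(fes, b, b) == 0.0

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_minimax_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 10, size=(8, 8))
        fes = surface_from(v)
        a_idx = np.unravel_index(np.argmin(fes.values), v.shape)
        b_idx = (7 - a_idx[0], 7 - a_idx[1])
        from pathmeta.analysis import Basin

        a = Basin("A", (0, 0), 0.0, np.array([a_idx]), a_idx)
        b = Basin("B", (0, 0), 0.0, np.array([b_idx]), b_idx)
        got = barrier_height(fes, a, b)
        expected = minimax_barrier_by_percolation(fes.values, a_idx, b_idx)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_barrier_asymmetry_equals_depth_difference(self):
        fes = gaussian_wells([6.0, 3.0], [(15, 20), (45, 20)])
        basins = find_basins(fes, 1.0)
        a, b = basins[0], basins[1]
        forward = barrier_height(fes, a, b)
        backward = barrier_height(fes, b, a)
        depth_diff = fes.values[b.min_index] - fes.values[a.min_index]
        assert forward - backward == pytest.approx(depth_diff, abs=1e-9)


class TestCoordination:
    def test_limit_values(self):
        p = SwitchingParams()
        assert coordination_count([0, 0, 0], [[0, 0, 0]], p) == pytest.approx(1.0)
        assert coordination_count([0, 0, 0], [[3.5, 0, 0]], p) == pytest.approx(
            6.0 / 16.0, abs=1e-12
        )

    def test_matches_perturbed_direct_evaluation(self, rng):
        p = SwitchingParams()
        waters = rng.uniform(-6, 6, size=(50, 3))
        # plant some atoms exactly at the singular radius
        waters[:5] = np.array([[3.5, 0, 0], [0, 3.5, 0], [0, 0, 3.5], [-3.5, 0, 0], [0, -3.5, 0]])
        direct = 0.0
        for w in waters:
            r = np.linalg.norm(w) + 1e-9  # nudge off the removable singularity
            x = r / p.r0
            direct += (1 - x**p.n) / (1 - x**p.m)
        assert coordination_count([0, 0, 0], waters, p) == pytest.approx(direct, abs=1e-6)

    def test_strictly_decreasing_and_continuous(self):
        p = SwitchingParams()
        r = np.linspace(0.01, 7.0, 2000)
        vals = np.array([coordination_count([0, 0, 0], [[ri, 0, 0]], p) for ri in r])
        assert np.all(np.diff(vals) < 0)
        assert np.max(np.abs(np.diff(vals))) < 0.01  # no jump across r0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SwitchingParams(n=5)
        with pytest.raises(ValueError):
            SwitchingParams(n=6, m=6)


class TestSegmentAxis:
    def test_ten_slices_eleven_points(self):
        axis = SegmentAxis(np.zeros(3), np.array([0, 0, 10.0]), 10)
        assert axis.points.shape == (11, 3)
        assert np.allclose(axis.fractions, np.arange(0, 1.05, 0.1))
        assert np.allclose(np.diff(axis.points[:, 2]), 1.0)


class TestHydrationMap:
    @staticmethod
    def _traj(water_coords, n_frames=3):
        n = len(water_coords)
        coords = np.repeat(water_coords[None], n_frames, axis=0)
        return Trajectory(
            coords, ["O"] * n, groups={"water_O": np.arange(n)}
        )

    def test_requires_water_group(self):
        traj = Trajectory(np.zeros((2, 1, 3)), ["C"])
        with pytest.raises(KeyError):
            hydration_map(traj, [0, 0], SegmentAxis(np.zeros(3), np.ones(3)))

    def test_zero_waters_gives_zero_grid(self):
        traj = Trajectory(
            np.zeros((3, 2, 3)), ["C", "C"], groups={"water_O": np.array([], dtype=int)}
        )
        grid, edges = hydration_map(
            traj, [1.0, 1.2, 1.4], SegmentAxis(np.zeros(3), np.ones(3))
        )
        assert np.all(grid[np.isfinite(grid)] == 0.0)

    def test_uniform_bulk_density_matches_quadrature(self, rng):
        """Mean count in a uniform bath equals ρ·∫4πr²·s(r)dr."""
        p = SwitchingParams()
        rho = 0.022  # beads per Å³
        box = 16.0
        n = int(rho * box**3)
        frames = rng.uniform(-box / 2, box / 2, size=(12, n, 3))
        traj = Trajectory(frames, ["O"] * n, groups={"water_O": np.arange(n)})
        axis = SegmentAxis(np.array([-1.0, 0, 0]), np.array([1.0, 0, 0]), 2)
        grid, _ = hydration_map(traj, np.ones(12), axis, p, s_bin=0.5)
        x_pow = lambda r: r / p.r0
        integrand = lambda r: (
            4 * np.pi * r**2
            * sum((x_pow(r)) ** k for k in range(p.n))
            / sum((x_pow(r)) ** k for k in range(p.m))
        )
        expected = rho * quad(integrand, 0, box / 2)[0]
        assert np.all(np.abs(grid - expected) / expected < 0.10)

    def test_axis_point_order_irrelevant_to_marginal(self, rng):
        waters = rng.uniform(-5, 5, size=(40, 3))
        traj = self._traj(waters)
        s = [0.2, 0.7, 1.3]
        fwd = SegmentAxis(np.array([0, 0, -3.0]), np.array([0, 0, 3.0]), 5)
        rev = SegmentAxis(np.array([0, 0, 3.0]), np.array([0, 0, -3.0]), 5)
        g1, _ = hydration_map(traj, s, fwd)
        g2, _ = hydration_map(traj, s, rev)
        assert np.allclose(np.sort(g1, axis=0), np.sort(g2, axis=0))

    def test_pocket_bottom_hydrates_when_ligand_leaves(self):
        """With the ligand expelled, water reaches the pocket bottom."""
        from pathmeta.steering import SMDConfig, run_smd
        from pathmeta.toy_models import LangevinParams, ToyPocketSpec, build_toy_pocket

        spec = ToyPocketSpec(pocket_depth=6.0, n_solvent=40, backdoor=True)
        pot, cfg = build_toy_pocket(spec, seed=2)
        lp = LangevinParams(timestep=0.004, seed=8)
        _, pulled = run_smd(
            pot, cfg, lp, SMDConfig("ligand_heavy", "pocket_ref", 20.0, 0.08, 16.0),
            record_stride=100, save_stride=100, return_trajectory=True,
        )
        axis = SegmentAxis(np.array([0, 0, -2.0]), np.array([0, 0, 8.0]), 10)
        waters = pulled.groups["water_O"]
        bottom = axis.points[0]
        early = np.mean(
            [coordination_count(bottom, pulled.coords[k][waters]) for k in range(10)]
        )
        late = np.mean(
            [coordination_count(bottom, pulled.coords[k][waters]) for k in range(-10, 0)]
        )
        assert late > early


class TestMonitors:
    def test_three_four_five(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        traj = Trajectory(coords, ["C", "C"])
        assert monitor_distance(traj, [0], [1], "atom")[0] == pytest.approx(5.0)

    def test_coincident_selections(self):
        traj = Trajectory(np.zeros((2, 2, 3)), ["C", "C"])
        assert np.all(monitor_distance(traj, [0], [1], "centroid") == 0.0)

    def test_centroid_equals_atom_for_singletons(self, rng):
        coords = rng.normal(size=(4, 3, 3))
        traj = Trajectory(coords, ["C"] * 3)
        assert np.allclose(
            monitor_distance(traj, [0], [2], "atom"),
            monitor_distance(traj, [0], [2], "centroid"),
        )

    def test_dihedral_cis_trans(self):
        cis = np.array([[[1.0, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]]])
        trans = np.array([[[1.0, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]]])
        assert monitor_dihedral(Trajectory(cis, ["C"] * 4), [0, 1, 2, 3])[0] == pytest.approx(0.0, abs=1e-9)
        assert abs(
            monitor_dihedral(Trajectory(trans, ["C"] * 4), [0, 1, 2, 3])[0]
        ) == pytest.approx(180.0, abs=1e-9)

    def test_dihedral_against_rotation_construction(self, rng):
        """Build a tetrad with a known torsion by explicit rotation."""
        for angle in (-150.0, -60.0, 10.0, 77.5, 179.0):
            b = np.array([0.0, 0.0, 1.5])
            a0 = np.array([1.2, 0.0, -0.3])
            rot = Rotation.from_euler("z", angle, degrees=True).as_matrix()
            a3 = rot @ np.array([1.2, 0.0, 0.0]) + 2 * b
            coords = np.array([[a0, [0, 0, 0], b, a3]])
            got = monitor_dihedral(Trajectory(coords, ["C"] * 4), [0, 1, 2, 3])[0]
            assert got == pytest.approx(angle, abs=1e-9)

    def test_dihedral_errors(self):
        traj = Trajectory(np.zeros((1, 4, 3)), ["C"] * 4)
        with pytest.raises(ValueError):
            monitor_dihedral(traj, [0, 1, 2, 2])
        line = np.array([[[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1, 0]]])
        with pytest.raises(ValueError, match="collinear"):
            monitor_dihedral(Trajectory(line, ["C"] * 4), [0, 1, 2, 3])


class TestRmsdRmsf:
    def test_static_trajectory(self, rng):
        frame = rng.normal(size=(6, 3)) * 3
        traj = Trajectory(np.repeat(frame[None], 5, axis=0), ["C"] * 6)
        rmsd, rmsf = rmsd_rmsf(traj, np.arange(6), np.arange(6))
        assert np.allclose(rmsd, 0.0, atol=1e-7)
        assert np.allclose(rmsf, 0.0, atol=1e-7)

    def test_rigid_rotation_removed_by_alignment(self, rng):
        frame = rng.normal(size=(6, 3)) * 3
        frames = [frame]
        for angle in (10, 20, 30, 40):
            rot = Rotation.from_euler("y", angle, degrees=True).as_matrix()
            frames.append(frame @ rot.T + angle * 0.1)
        traj = Trajectory(np.stack(frames), ["C"] * 6)
        rmsd, rmsf = rmsd_rmsf(traj, np.arange(6), np.arange(6))
        assert np.max(rmsd) < 1e-7
        assert np.max(rmsf) < 1e-7

    def test_sinusoidal_oscillator_rmsf(self, rng):
        cage = rng.normal(size=(5, 3)) * 4
        n_frames = 10_000
        phases = 2 * np.pi * np.arange(n_frames) / 400.0
        coords = np.repeat(np.vstack([cage, [[0.0, 0, 0]]])[None], n_frames, axis=0)
        amplitude = 0.8
        coords[:, -1, 0] = amplitude * np.sin(phases)
        traj = Trajectory(coords, ["C"] * 6)
        _, rmsf = rmsd_rmsf(traj, np.arange(5), np.arange(6))
        assert rmsf[-1] == pytest.approx(amplitude / np.sqrt(2.0), rel=0.02)
        assert np.all(rmsf[:-1] < 1e-7)


class TestCompetence:
    @staticmethod
    def _frame(d_hydride, d_tyr, d_ser):
        coords = np.array(
            [
                [0.0, 0.0, 0.0],  # hydride donor
                [d_hydride, 0.0, 0.0],  # hydride acceptor
                [0.0, 5.0, 0.0],  # keto oxygen
                [0.0, 5.0 + d_tyr, 0.0],  # tyrosine OH
                [d_ser, 5.0, 0.0],  # serine OH (offset in x from keto)
            ]
        )
        return Configuration(coords, ["C", "C", "O", "O", "O"])

    ROLES = {
        "hydride_donor": 0,
        "hydride_acceptor": 1,
        "keto_oxygen": 2,
        "tyr_oxygen": 3,
        "ser_oxygen": 4,
    }

    def test_within_defaults(self):
        ok, d = is_catalytically_competent(self._frame(4.0, 3.0, 3.2), self.ROLES)
        assert ok and d["hydride"] == pytest.approx(4.0)

    def test_one_violation_fails(self):
        ok, _ = is_catalytically_competent(self._frame(4.0, 3.0, 3.8), self.ROLES)
        assert not ok

    def test_missing_role(self):
        with pytest.raises(KeyError):
            is_catalytically_competent(self._frame(4, 3, 3), {"hydride_donor": 0})

    def test_predicate_equals_distance_conjunction(self, rng):
        """Sweep of synthetic frames: predicate ≡ thresholded monitors."""
        for _ in range(30):
            dh, dt, ds = rng.uniform(2.0, 6.0, 3)
            frame = self._frame(dh, dt, ds)
            ok, d = is_catalytically_competent(frame, self.ROLES)
            traj = Trajectory(frame.coordinates[None], frame.elements)
            expected = (
                monitor_distance(traj, [0], [1], "atom")[0] <= 4.5
                and monitor_distance(traj, [2], [3], "atom")[0] <= 3.5
                and monitor_distance(traj, [2], [4], "atom")[0] <= 3.5
            )
            assert ok == expected


class TestClustering:
    def test_identical_configs_one_cluster(self, rng):
        frame = rng.normal(size=(6, 3))
        configs = [Configuration(frame.copy(), ["C"] * 6) for _ in range(4)]
        labels = cluster_single_linkage(configs, np.arange(3), np.arange(3, 6), 0.7)
        assert np.all(labels == 0)

    def test_two_separated_groups(self, rng):
        cage = rng.normal(size=(4, 3)) * 3
        probe = rng.normal(size=(2, 3))
        group_a = [
            Configuration(np.vstack([cage, probe + rng.normal(size=(2, 3)) * 0.05]), ["C"] * 6)
            for _ in range(3)
        ]
        group_b = [
            Configuration(
                np.vstack([cage, probe + [0, 0, 5.0] + rng.normal(size=(2, 3)) * 0.05]),
                ["C"] * 6,
            )
            for _ in range(2)
        ]
        labels = cluster_single_linkage(group_a + group_b, np.arange(4), np.arange(4, 6), 0.7)
        assert len(set(labels)) == 2
        assert labels[0] == 0  # larger cluster labelled first
        assert set(labels[:3]) == {0} and set(labels[3:]) == {1}

    def test_matches_union_find_oracle(self, rng):
        from pathmeta.pathcv import msd_distance

        cage = rng.normal(size=(4, 3)) * 3
        configs = [
            Configuration(np.vstack([cage, rng.normal(size=(3, 3)) * 1.0]), ["C"] * 7)
            for _ in range(12)
        ]
        ai, mi = np.arange(4), np.arange(4, 7)
        n = len(configs)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                rmsd = np.sqrt(
                    msd_distance(configs[i].coordinates, configs[j].coordinates, ai, mi)
                )
                dist[i, j] = dist[j, i] = rmsd
        cutoff = np.median(dist[np.triu_indices(n, 1)])
        got = cluster_single_linkage(configs, ai, mi, cutoff)
        expected = clusters_by_union_find(dist, cutoff)
        # same partition (labels may differ)
        for i in range(n):
            for j in range(n):
                assert (got[i] == got[j]) == (expected[i] == expected[j])
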