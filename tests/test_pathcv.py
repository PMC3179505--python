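import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from pathmeta.core import Configuration, Trajectory
from pathmeta.pathcv import (
    DegenerateFitError,
    Frameset,
    calibrate_lambda,
    evaluate_path_cv,
    evaluate_path_cv_batch,
    extract_frameset,
    msd_distance,
    superpose,
)

from .oracles import path_cv_mpmath, rmsd_by_rotation_grid


def random_frameset(rng, p=5, n=9, n_align=4):
    frames = np.cumsum(rng.normal(size=(p, n, 3)) * 0.4, axis=0)
    adj = np.array(
        [
            msd_distance(frames[k], frames[k + 1], np.arange(n_align), np.arange(n_align, n))
            for k in range(p - 1)
        ]
    )
    return Frameset(
        frames, ["C"] * n, np.arange(n_align), np.arange(n_align, n),
        calibrate_lambda(adj), adj,
    )


class TestSuperpose:
    def test_identity(self, rng):
        x = rng.normal(size=(6, 3)) * 3
        rot, t, rmsd = superpose(x, x, np.arange(6))
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(rot, np.eye(3), atol=1e-6)

    def test_rigid_transform_recovered(self, rng):
        ref = rng.normal(size=(7, 3)) * 3
        rot_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mob = ref @ rot_true.T + np.array([1.0, 2.0, 3.0])
        rot, t, rmsd = superpose(mob, ref, np.arange(7))
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(mob @ rot.T + t, ref, atol=1e-8)

    def test_matches_rotation_grid_search(self, rng):
        """Kearsley minimum agrees with a 2°-grid exhaustive search."""
        ref = rng.normal(size=(5, 3)) * 2
        mob = ref + rng.normal(size=(5, 3)) * 0.1
        _, _, rmsd = superpose(mob, ref, np.arange(5))
        brute = rmsd_by_rotation_grid(mob, ref)
        assert rmsd <= brute + 1e-12
        assert abs(rmsd - brute) < 1e-2

    def test_degenerate_fits_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateFitError):
            superpose(line, line + 0.1, np.arange(4))
        with pytest.raises(DegenerateFitError):
            superpose(line[:2], line[:2], np.arange(2))


class TestMSD:
    def test_zero_for_identical(self, rng):
        x = rng.normal(size=(8, 3))
        assert msd_distance(x, x, np.arange(4), np.arange(4, 8)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_offset_squares(self, rng):
        cage = rng.normal(size=(5, 3)) * 3
        probe = rng.normal(size=(3, 3))
        a = np.vstack([cage, probe])
        b = np.vstack([cage, probe + np.array([0.0, 0.0, 2.0])])
        d = msd_distance(a, b, np.arange(5), np.arange(5, 8))
        assert d == pytest.approx(4.0, abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.normal(size=(8, 3)) * 2
        b = a + rng.normal(size=(8, 3)) * 0.5
        ai, di = np.arange(4), np.arange(4, 8)
        assert msd_distance(a, b, ai, di) == pytest.approx(
            msd_distance(b, a, ai, di), rel=1e-9
        )

    def test_against_independent_superposition(self, rng):
        """Direct Σ‖Δr‖²/N after a scipy-based optimal alignment."""
        a = rng.normal(size=(9, 3)) * 2
        b = a @ Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix().T
        b = b + rng.normal(size=(9, 3)) * 0.3 + 1.0
        ai, di = np.arange(5), np.arange(5, 9)
        rot_sp, _ = Rotation.align_vectors(
            (b[ai] - b[ai].mean(0)), (a[ai] - a[ai].mean(0))
        )
        moved = rot_sp.apply(a - a[ai].mean(0)) + b[ai].mean(0)
        expected = np.mean(np.sum((moved[di] - b[di]) ** 2, axis=1))
        assert msd_distance(a, b, ai, di) == pytest.approx(expected, rel=1e-6)

    def test_empty_displacement_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            msd_distance(x, x, np.arange(5), np.array([], dtype=int))


class TestExtractFrameset:
    @staticmethod
    def _drift_trajectory(n_frames=101, n=6):
        # one probe atom drifting linearly across a rigid cage
        rng = np.random.default_rng(0)
        cage = rng.normal(size=(n - 1, 3)) * 4
        coords = np.repeat(np.vstack([cage, [[0.0, 0.0, 0.0]]])[None], n_frames, axis=0)
        coords[:, -1, 2] = np.linspace(0.0, 10.0, n_frames)
        return Trajectory(coords, ["C"] * n)

    def test_uniform_drift_gives_even_spacing(self):
        traj = self._drift_trajectory()
        fs = extract_frameset(traj, 5, np.arange(5), np.array([5]))
        assert fs.P == 5
        spread = fs.adjacent_msd.max() - fs.adjacent_msd.min()
        assert spread <= 0.05 * fs.adjacent_msd.mean()

    def test_full_selection_is_identity(self):
        traj = self._drift_trajectory(n_frames=7)
        fs = extract_frameset(traj, 7, np.arange(5), np.array([5]))
        assert np.array_equal(fs.coords, traj.coords)

    def test_eighteen_frames_from_pull_style_fixture(self):
        rng = np.random.default_rng(3)
        traj = self._drift_trajectory(n_frames=400)
        noisy = traj.coords.copy()
        noisy[:, -1, :2] += rng.normal(size=(400, 2)) * 0.15
        traj = Trajectory(noisy, traj.elements)
        fs = extract_frameset(traj, 18, np.arange(5), np.array([5]))
        assert fs.P == 18 and len(fs.adjacent_msd) == 17 and fs.lam > 0

    def test_no_net_displacement_rejected(self):
        coords = np.repeat(np.random.default_rng(1).normal(size=(1, 6, 3)), 20, axis=0)
        traj = Trajectory(coords, ["C"] * 6)
        with pytest.raises(ValueError, match="net displacement"):
            extract_frameset(traj, 4, np.arange(5), np.array([5]))


class TestLambda:
    def test_closed_form(self):
        assert calibrate_lambda([1.0]) == pytest.approx(math.log(10.0), rel=1e-12)

    def test_reported_pairing(self):
        # 1.1 Å spacing → 1.21 Å² MSD; the rule gives 1.903, within 2%
        # of the reference frameset's λ = 1.94
        lam = calibrate_lambda([1.21])
        assert lam == pytest.approx(1.903, abs=5e-4)
        assert abs(lam - 1.94) / 1.94 < 0.02

    @given(st.floats(0.05, 50.0))
    def test_doubling_spacing_halves_lambda(self, spacing):
        assert calibrate_lambda([2 * spacing]) == pytest.approx(
            calibrate_lambda([spacing]) / 2, rel=1e-12
        )


class TestEvaluate:
    def test_dominant_frame_limit(self, rng):
        fs = random_frameset(rng)
        sharp = Frameset(
            fs.coords, ["C"] * 9, fs.align_selection, fs.displace_selection,
            20.0 / fs.adjacent_msd.mean(), fs.adjacent_msd,
        )
        val = evaluate_path_cv(fs.coords[2], sharp)
        assert abs(val.s - 3.0) < 0.05
        assert abs(val.z) < 0.05

    def test_two_frame_midpoint_symmetry(self):
        cage = np.array([[3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0], [1.0, 1.0, 0]])
        probe_a = np.array([[0.0, 0.0, -1.0]])
        probe_b = np.array([[0.0, 0.0, 1.0]])
        frames = np.stack([np.vstack([cage, probe_a]), np.vstack([cage, probe_b])])
        fs = Frameset(frames, ["C"] * 5, np.arange(4), np.array([4]), 1.0, np.array([4.0]))
        config = np.vstack([cage, [[0.0, 0.0, 0.0]]])
        val = evaluate_path_cv(config, fs)
        assert val.s == pytest.approx(1.5, abs=1e-12)

    def test_matches_high_precision_direct_sum(self, rng):
        fs = random_frameset(rng, p=3)
        config = fs.coords[1] + rng.normal(size=fs.coords[1].shape) * 0.3
        val = evaluate_path_cv(config, fs)
        s_hp, z_hp = path_cv_mpmath(
            config, fs.coords, fs.align_selection, fs.displace_selection,
            fs.lam, msd_distance,
        )
        assert abs(val.s - s_hp) < 1e-10
        assert abs(val.z - z_hp) < 1e-10

    def test_log_sum_exp_agrees_with_naive_sum(self, rng):
        fs = random_frameset(rng)
        config = fs.coords[2] + rng.normal(size=fs.coords[2].shape) * 0.2
        d = np.array(
            [
                msd_distance(config, fs.coords[p], fs.align_selection, fs.displace_selection)
                for p in range(fs.P)
            ]
        )
        w = np.exp(-fs.lam * d)  # no underflow at these scales
        s_naive = np.sum(np.arange(1, fs.P + 1) * w) / w.sum()
        z_naive = -np.log(w.sum()) / fs.lam
        val = evaluate_path_cv(config, fs)
        assert val.s == pytest.approx(s_naive, abs=1e-12)
        assert val.z == pytest.approx(z_naive, abs=1e-12)

    def test_extreme_lambda_does_not_underflow(self, rng):
        fs = random_frameset(rng)
        huge = Frameset(
            fs.coords, ["C"] * 9, fs.align_selection, fs.displace_selection,
            5000.0, fs.adjacent_msd,
        )
        val = evaluate_path_cv(fs.coords[4] + 0.5, huge)
        assert np.isfinite(val.s) and np.isfinite(val.z)
        assert 1.0 - 1e-6 <= val.s <= huge.P + 1e-6

    def test_walking_frames_increases_s(self, rng):
        fs = random_frameset(rng, p=6)
        s_vals = [evaluate_path_cv(fs.coords[p], fs).s for p in range(fs.P)]
        assert np.all(np.diff(s_vals) > 0)

    def test_invariant_under_global_rigid_motion(self, rng):
        fs = random_frameset(rng)
        config = fs.coords[2] + rng.normal(size=fs.coords[2].shape) * 0.2
        val = evaluate_path_cv(config, fs)
        rot = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
        moved = config @ rot.T + np.array([5.0, -3.0, 2.0])
        val2 = evaluate_path_cv(moved, fs)
        assert val2.s == pytest.approx(val.s, abs=1e-8)
        assert val2.z == pytest.approx(val.z, abs=1e-8)

    def test_batch_matches_single(self, rng):
        fs = random_frameset(rng)
        configs = fs.coords[:4] + rng.normal(size=(4,) + fs.coords[0].shape) * 0.2
        s_b, z_b = evaluate_path_cv_batch(configs, fs)
        for k in range(4):
            val = evaluate_path_cv(configs[k], fs)
            assert s_b[k] == pytest.approx(val.s, abs=1e-9)
            assert z_b[k] == pytest.approx(val.z, abs=1e-9)

    def test_gradients_match_finite_differences(self, rng):
        fs = random_frameset(rng)
        config = fs.coords[2] + rng.normal(size=fs.coords[2].shape) * 0.2
        val = evaluate_path_cv(config, fs)
        eps = 1e-5
        for i in fs.displace_selection:
            for c in range(3):
                xp = config.copy()
                xm = config.copy()
                xp[i, c] += eps
                xm[i, c] -= eps
                fds = (evaluate_path_cv(xp, fs).s - evaluate_path_cv(xm, fs).s) / (2 * eps)
                fdz = (evaluate_path_cv(xp, fs).z - evaluate_path_cv(xm, fs).z) / (2 * eps)
                assert val.ds_dx[i, c] == pytest.approx(fds, rel=1e-4, abs=1e-8)
                assert val.dz_dx[i, c] == pytest.approx(fdz, rel=1e-4, abs=1e-8)


class TestFramesetIO:
    def test_save_load_round_trip(self, rng, tmp_path):
        fs = random_frameset(rng)
        fs.save(tmp_path / "fs")
        back = Frameset.load(tmp_path / "fs")
        assert back.P == fs.P
        assert back.lam == pytest.approx(fs.lam, rel=1e-9)
        assert np.allclose(back.coords, fs.coords, atol=1e-6)
        assert np.array_equal(back.align_selection, fs.align_selection)

    def test_corrupt_sidecar_reported(self, rng, tmp_path):
        fs = random_frameset(rng)
        fs.save(tmp_path / "fs")
        (tmp_path / "fs.yaml").write_text("lambda: [not, a, number]\n")
        with pytest.raises(ValueError, match="sidecar"):
            Frameset.load(tmp_path / "fs")

    def test_pipeline_frameset_spans_pull(self, pocket_study):
        fs = pocket_study.frameset
        assert fs.P == 12
        # near-even spacing achieved by the dynamic programme
        assert fs.adjacent_msd.std() / fs.adjacent_msd.mean() < 0.1
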