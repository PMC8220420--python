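"""Superposition, RMSF block statistics, cross-correlation, pocket widths."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from brr2allo.flexibility import (
    ca_selection,
    cross_correlation,
    pocket_width,
    rmsf,
    superpose,
)
from brr2allo.structure import Trajectory
from conftest import toy_topology


def _ca_trajectory(coords, times=None):
    """Trajectory of CA-only residues from an (F, A, 3) array."""
    n_atoms = coords.shape[1]
    top = toy_topology([("A", i + 1, [("CA", "C")]) for i in range(n_atoms)])
    if times is None:
        times = np.arange(len(coords), dtype=float)
    return Trajectory(top, coords, times, window=(float(times[0]), float(times[-1])))


def _base_structure(n_atoms=6, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(-5, 5, size=(n_atoms, 3))


def _rmsd(a, b):
    return np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))


class TestSuperpose:
    def test_pure_translations_removed(self):
        base = _base_structure()
        frames = np.array([base + [i * 2.0, -i, 0.5 * i] for i in range(5)])
        traj = _ca_trajectory(frames)
        out = superpose(traj, np.arange(6))
        for f in range(5):
            assert _rmsd(out.coords[f], out.coords[0]) < 1e-10

    def test_rotation_about_z_removed(self):
        base = _base_structure()
        rot = Rotation.from_euler("z", 90, degrees=True)
        frames = np.array([base, rot.apply(base)])
        out = superpose(_ca_trajectory(frames), np.arange(6))
        assert _rmsd(out.coords[1], out.coords[0]) < 1e-10

    def test_reflection_cannot_reach_zero_rmsd(self):
        base = _base_structure()
        mirrored = base * np.array([-1.0, 1.0, 1.0])
        out = superpose(_ca_trajectory(np.array([base, mirrored])), np.arange(6))
        assert _rmsd(out.coords[1], out.coords[0]) > 0.1

    def test_too_few_atoms_rejected(self):
        traj = _ca_trajectory(_base_structure(2)[None, :, :])
        with pytest.raises(ValueError):
            superpose(traj, np.arange(2))


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self):
        base = _base_structure()
        traj = _ca_trajectory(np.repeat(base[None], 20, axis=0))
        prof = rmsf(traj, np.arange(6), n_blocks=5)
        np.testing.assert_allclose(prof.rmsf_mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.rmsf_sem, 0.0, atol=1e-12)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        rng = np.random.default_rng(1)
        base = _base_structure(4)
        sigma = 0.3
        frames = base[None] + rng.normal(0, sigma, size=(10_000, 4, 3))
        prof = rmsf(_ca_trajectory(frames), np.arange(4), n_blocks=1)
        np.testing.assert_allclose(prof.rmsf_mean, sigma * np.sqrt(3), rtol=0.02)

    def test_two_block_sem_is_half_absolute_difference(self):
        rng = np.random.default_rng(2)
        base = _base_structure(3)
        f1 = base[None] + rng.normal(0, 0.2, size=(500, 3, 3))
        f2 = base[None] + rng.normal(0, 0.4, size=(500, 3, 3))
        traj = _ca_trajectory(np.concatenate([f1, f2]))
        prof = rmsf(traj, np.arange(3), n_blocks=2)
        b1 = rmsf(_ca_trajectory(f1), np.arange(3), n_blocks=1).rmsf_mean
        b2 = rmsf(_ca_trajectory(f2), np.arange(3), n_blocks=1).rmsf_mean
        np.testing.assert_allclose(prof.rmsf_sem, np.abs(b2 - b1) / 2, rtol=1e-9)

    def test_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(3)
        base = _base_structure()
        frames = base[None] + rng.normal(0, 0.1, size=(50, 6, 3))
        moved = np.array(
            [
                Rotation.random(random_state=np.random.RandomState(i)).apply(f)
                + rng.uniform(-20, 20, 3)
                for i, f in enumerate(frames)
            ]
        )
        sel = np.arange(6)
        p0 = rmsf(superpose(_ca_trajectory(frames), sel), sel, n_blocks=5)
        p1 = rmsf(superpose(_ca_trajectory(moved), sel), sel, n_blocks=5)
        np.testing.assert_allclose(p1.rmsf_mean, p0.rmsf_mean, atol=1e-9)

    def test_block_count_exceeding_frames_rejected(self):
        traj = _ca_trajectory(np.repeat(_base_structure()[None], 3, axis=0))
        with pytest.raises(ValueError):
            rmsf(traj, np.arange(6), n_blocks=10)

    def test_single_block_matches_global_reference(self):
        rng = np.random.default_rng(4)
        frames = _base_structure()[None] + rng.normal(0, 0.2, size=(200, 6, 3))
        traj = _ca_trajectory(frames)
        a = rmsf(traj, np.arange(6), n_blocks=1, reference="block-mean")
        b = rmsf(traj, np.arange(6), n_blocks=1, reference="global-mean")
        np.testing.assert_allclose(a.rmsf_mean, b.rmsf_mean, atol=1e-12)


class TestCrossCorrelation:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(5)
        frames = _base_structure()[None] + rng.normal(0, 0.2, size=(100, 6, 3))
        corr = cross_correlation(_ca_trajectory(frames), np.arange(6))
        np.testing.assert_allclose(np.diag(corr.matrix), 1.0, atol=1e-12)
        np.testing.assert_allclose(corr.matrix, corr.matrix.T, atol=1e-12)

    def test_in_phase_and_anti_phase_sinusoids(self):
        t = np.linspace(0, 4 * np.pi, 200)
        wave = np.sin(t)
        frames = np.zeros((200, 3, 3))
        frames[:, 0, 0] = wave
        frames[:, 1, 0] = wave  # identical phase
        frames[:, 2, 0] = -wave  # anti-phase
        frames += np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        corr = cross_correlation(_ca_trajectory(frames), np.arange(3))
        assert corr.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert corr.matrix[0, 2] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_jitter_nearly_uncorrelated(self):
        rng = np.random.default_rng(6)
        n_frames = 2000
        frames = _base_structure()[None] + rng.normal(0, 0.3, size=(n_frames, 6, 3))
        corr = cross_correlation(_ca_trajectory(frames), np.arange(6))
        off = corr.matrix[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n_frames))

    def test_zero_variance_atom_flagged(self):
        frames = np.zeros((50, 2, 3))
        frames[:, 0, 0] = np.sin(np.linspace(0, 6, 50))
        frames[:, 1] = [5.0, 0.0, 0.0]  # immobile
        corr = cross_correlation(_ca_trajectory(frames), np.arange(2))
        assert corr.undefined[1]
        assert np.isnan(corr.matrix[0, 1])


class TestPocketWidth:
    def test_identical_frames_mean_and_zero_sem(self):
        base = _base_structure(2)
        base[1] = base[0] + [4.0, 0, 0]
        traj = _ca_trajectory(np.repeat(base[None], 10, axis=0))
        pw = pocket_width(traj, (("A", 1), ("A", 2)), n_blocks=5)
        assert pw.mean == pytest.approx(4.0)
        assert pw.sem == pytest.approx(0.0, abs=1e-12)

    def test_two_frame_mean(self):
        frames = np.zeros((2, 2, 3))
        frames[0, 1, 0] = 10.0
        frames[1, 1, 0] = 12.0
        traj = _ca_trajectory(frames)
        pw = pocket_width(traj, (("A", 1), ("A", 2)), n_blocks=1)
        assert pw.mean == pytest.approx(11.0)

    def test_brr2_numbered_pocket_pairs_resolve(self):
        """The canonical NC (G506-G854) and CC (G1353-G1689) pairs resolve
        on a Brr2-numbered topology."""
        top = toy_topology(
            [("A", r, [("CA", "C")]) for r in (506, 854, 1353, 1689)]
        )
        coords = np.array(
            [[0, 0, 0], [18, 0, 0], [100, 0, 0], [117, 0, 0]], dtype=float
        )[None]
        traj = Trajectory(top, coords, np.array([0.0]), window=(0.0, 0.0))
        nc = pocket_width(traj, (("A", 506), ("A", 854)), n_blocks=1)
        cc = pocket_width(traj, (("A", 1353), ("A", 1689)), n_blocks=1)
        assert nc.mean == pytest.approx(18.0)
        assert cc.mean == pytest.approx(17.0)

    def test_missing_reference_atom_names_residue(self):
        traj = _ca_trajectory(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="A:99"):
            pocket_width(traj, (("A", 1), ("A", 99)))


def test_ca_selection_restricts_to_residues():
    from brr2allo.synthetic import NetworkDesign, generate_synthetic_trajectory

    traj, _ = generate_synthetic_trajectory(NetworkDesign(seed=1, n_frames=2))
    all_ca = ca_selection(traj)
    some = ca_selection(traj, [("A", 401), ("A", 402)])
    assert some.size == 2
    assert set(some) <= set(all_ca)
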