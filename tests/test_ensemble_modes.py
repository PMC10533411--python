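"""Ensemble PCA, mode scaling, morphs and cosine overlaps."""

import numpy as np
import pytest

from ampaflex import ensemble_modes as em
from ampaflex import structure_io as sio

N_ATOMS = 40


def labels(n=N_ATOMS):
    return [("A", i + 1, "CA") for i in range(n)]


def ensemble_from_vectors(mean, frames_3n):
    frames = np.asarray(frames_3n, float).reshape(len(frames_3n), -1, 3)
    return sio.AtomMatchedEnsemble(atom_labels=labels(frames.shape[1]), frames=frames)


def planted_ensemble(n_frames, variances, seed=0, n_atoms=N_ATOMS, basis_seed=None):
    """Frames = mean + sum_k c_k v_k with c_k ~ N(0, variances[k])."""
    basis_rng = np.random.default_rng(seed if basis_seed is None else basis_seed)
    rng = np.random.default_rng(seed)
    dim = 3 * n_atoms
    mean = basis_rng.uniform(-5, 5, dim)
    basis, _ = np.linalg.qr(basis_rng.normal(size=(dim, len(variances))))
    coeffs = rng.normal(0.0, np.sqrt(variances), size=(n_frames, len(variances)))
    X = mean + coeffs @ basis.T
    return ensemble_from_vectors(mean, X), basis.T, np.asarray(variances, float)


class TestEnsemblePCA:
    def test_identical_frames_zero_eigenvalues(self):
        X = np.tile(np.arange(3.0 * N_ATOMS), (5, 1))
        ms = em.ensemble_pca(ensemble_from_vectors(X[0], X))
        assert np.all(ms.eigenvalues < 1e-18)

    def test_two_frame_eigenvalue_identity(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(size=3 * N_ATOMS)
        d = rng.normal(size=3 * N_ATOMS)
        ms = em.ensemble_pca(ensemble_from_vectors(base, [base, base + d]))
        # M-normalized covariance of ±d/2: single mode d/|d|, eigenvalue |d|²/4
        assert ms.eigenvalues[0] == pytest.approx(np.dot(d, d) / 4.0, rel=1e-12)
        assert abs(ms.eigenvectors[0] @ (d / np.linalg.norm(d))) == pytest.approx(
            1.0, abs=1e-9
        )
        assert np.all(ms.eigenvalues[1:] < 1e-12 * ms.eigenvalues[0])

    def test_planted_modes_recovered(self):
        ens, modes, variances = planted_ensemble(50, [4.0, 1.0], seed=3)
        ms = em.ensemble_pca(ens)
        for k in range(2):
            assert abs(ms.eigenvectors[k] @ modes[k]) > 0.99
            assert ms.eigenvalues[k] == pytest.approx(variances[k], rel=0.25)

    def test_single_frame_rejected(self):
        X = np.arange(3.0 * N_ATOMS)
        with pytest.raises(ValueError):
            em.ensemble_pca(ensemble_from_vectors(X, [X]))

    def test_variance_conservation(self):
        ens, _, _ = planted_ensemble(30, [4.0, 2.0, 1.0], seed=9)
        ms = em.ensemble_pca(ens)
        X = ens.frames.reshape(30, -1)
        total = np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1))
        assert ms.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_projection_variance_equals_eigenvalue(self):
        ens, _, _ = planted_ensemble(40, [4.0, 1.0], seed=5)
        ms = em.ensemble_pca(ens)
        X = ens.frames.reshape(40, -1) - ms.mean_coords
        for k in range(2):
            proj = X @ ms.eigenvectors[k]
            assert proj.var() == pytest.approx(ms.eigenvalues[k], rel=1e-9)

    def test_translation_covariance_without_alignment(self):
        ens, _, _ = planted_ensemble(20, [4.0], seed=7)
        ms = em.ensemble_pca(ens)
        t = np.array([3.0, -1.0, 2.0])
        shifted = sio.AtomMatchedEnsemble(
            atom_labels=ens.atom_labels, frames=ens.frames + t
        )
        ms2 = em.ensemble_pca(shifted)
        np.testing.assert_allclose(ms2.eigenvalues, ms.eigenvalues, atol=1e-9)
        # only the planted (non-degenerate) mode has a well-defined direction
        assert abs(ms2.eigenvectors[0] @ ms.eigenvectors[0]) == pytest.approx(
            1.0, abs=1e-6
        )
        np.testing.assert_allclose(
            ms2.mean_coords.reshape(-1, 3),
            ms.mean_coords.reshape(-1, 3) + t,
            atol=1e-9,
        )

    def test_eigenvector_orthonormality(self):
        ens, _, _ = planted_ensemble(25, [4.0, 2.0, 1.0], seed=2)
        ms = em.ensemble_pca(ens)
        k = min(ms.n_modes, 10)
        gram = ms.eigenvectors[:k] @ ms.eigenvectors[:k].T
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-9)

    def test_alignment_removes_rigid_rotation_mode(self):
        # frames differing only by small rigid rotations: aligned PCA ~ zero variance
        rng = np.random.default_rng(4)
        base = rng.uniform(-10, 10, (N_ATOMS, 3))
        frames = []
        for ang in np.linspace(-0.2, 0.2, 10):
            R = np.array(
                [
                    [np.cos(ang), -np.sin(ang), 0],
                    [np.sin(ang), np.cos(ang), 0],
                    [0, 0, 1],
                ]
            )
            frames.append(base @ R.T)
        ens = sio.AtomMatchedEnsemble(atom_labels=labels(), frames=np.array(frames))
        free = em.ensemble_pca(ens, superpose_first=False)
        aligned = em.ensemble_pca(ens, superpose_first=True)
        assert aligned.eigenvalues[0] < 1e-6 * free.eigenvalues[0]


class TestScaling:
    def test_rmsd_closed_form(self):
        v = np.zeros(300)
        v[0] = 1.0
        assert em.rmsd_of_displacement(v, 20.0, 100) == pytest.approx(2.0)
        assert em.rmsd_of_displacement(v, 0.0, 100) == 0.0

    def test_rmsd_against_direct_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=3 * N_ATOMS)
        v /= np.linalg.norm(v)
        s = 7.3
        direct = np.sqrt(np.mean(np.sum((s * v).reshape(-1, 3) ** 2, axis=1)))
        assert em.rmsd_of_displacement(v, s, N_ATOMS) == pytest.approx(direct, abs=1e-9)

    def test_target_rmsd_amplitude_achieved(self):
        ens, _, _ = planted_ensemble(30, [4.0, 1.0], seed=1)
        ms = em.ensemble_pca(ens)
        disp, achieved = em.scale_mode(
            ms, em.MorphSpec(mode_index=1, target_rmsd=20.0)
        )
        assert achieved == pytest.approx(20.0, abs=1e-9)
        direct = np.sqrt(np.mean(np.sum(disp.reshape(-1, 3) ** 2, axis=1)))
        assert direct == pytest.approx(20.0, abs=1e-9)

    def test_scale_factor_is_variance_weighted(self):
        # planted λ₂ = 4 Å², N = 100, c = 0.5 → RMSD = 0.5·2/10 = 0.1 Å
        rng = np.random.default_rng(6)
        dim = 300
        basis, _ = np.linalg.qr(rng.normal(size=(dim, 2)))
        mean = np.zeros(dim)
        # frames with exact sample variances (M-normalized): ±√λ along each mode
        lam = np.array([9.0, 4.0])
        X = np.stack(
            [
                mean + np.sqrt(lam[0]) * basis[:, 0],
                mean - np.sqrt(lam[0]) * basis[:, 0],
                mean + np.sqrt(lam[1]) * basis[:, 1],
                mean - np.sqrt(lam[1]) * basis[:, 1],
            ]
        )
        ms = em.ensemble_pca(ensemble_from_vectors(mean, X))
        # 4-frame ensemble halves each planted variance: λ = (9, 4)/2·... compute directly
        disp, achieved = em.scale_mode(ms, em.MorphSpec(mode_index=2, scale_factor=0.5))
        expected = 0.5 * np.sqrt(ms.eigenvalues[1]) / np.sqrt(100)
        direct = np.sqrt(np.mean(np.sum(disp.reshape(-1, 3) ** 2, axis=1)))
        assert achieved == pytest.approx(expected, abs=1e-12)
        assert direct == pytest.approx(achieved, abs=1e-9)

    def test_zero_variance_mode_warns(self):
        X = np.tile(np.arange(3.0 * N_ATOMS), (3, 1))
        X[0, 0] += 1.0  # one nonzero mode
        ms = em.ensemble_pca(ensemble_from_vectors(X[0], X))
        with pytest.warns(UserWarning):
            em.scale_mode(ms, em.MorphSpec(mode_index=3, scale_factor=0.076))


class TestMorph:
    @pytest.fixture()
    def mode_set(self):
        ens, _, _ = planted_ensemble(30, [4.0, 1.0], seed=12)
        return em.ensemble_pca(ens)

    def test_closed_morph_starts_and_ends_at_mean(self, mode_set):
        tr = em.make_morph(mode_set, em.MorphSpec(mode_index=1, target_rmsd=20.0))
        mean = mode_set.mean_coords.reshape(-1, 3)
        assert tr.n_frames == 20
        np.testing.assert_allclose(tr.frames[0], mean, atol=1e-9)
        np.testing.assert_allclose(tr.frames[-1], mean, atol=1e-9)

    def test_max_frame_rmsd_equals_target(self, mode_set):
        tr = em.make_morph(mode_set, em.MorphSpec(mode_index=1, target_rmsd=20.0))
        mean = mode_set.mean_coords.reshape(-1, 3)
        rmsds = np.sqrt(np.mean(np.sum((tr.frames - mean) ** 2, axis=2), axis=1))
        assert rmsds.max() == pytest.approx(20.0, abs=1e-9)
        # both extremes are visited
        amp = (tr.frames - mean).reshape(20, -1) @ mode_set.eigenvectors[0]
        assert amp.min() == pytest.approx(-amp.max(), rel=1e-9)

    def test_morph_roundtrip_recovers_mode(self, mode_set):
        tr = em.make_morph(mode_set, em.MorphSpec(mode_index=2, target_rmsd=5.0))
        ms2 = em.ensemble_pca(tr)
        assert abs(ms2.eigenvectors[0] @ mode_set.eigenvectors[1]) > 0.999

    def test_zero_mode_morph_is_static(self):
        X = np.tile(np.arange(3.0 * N_ATOMS), (3, 1))
        X[0, 0] += 1.0
        ms = em.ensemble_pca(ensemble_from_vectors(X[0], X))
        with pytest.warns(UserWarning):
            tr = em.make_morph(ms, em.MorphSpec(mode_index=2, scale_factor=0.076))
        np.testing.assert_allclose(
            tr.frames, np.tile(ms.mean_coords.reshape(-1, 3), (20, 1, 1)), atol=1e-12
        )

    def test_too_few_frames_rejected(self, mode_set):
        with pytest.raises(ValueError):
            em.make_morph(mode_set, em.MorphSpec(mode_index=1, target_rmsd=1.0, n_frames=3))


class TestCosineOverlap:
    def test_self_overlap_is_identity(self):
        ens, _, _ = planted_ensemble(30, [4.0, 2.0, 1.0], seed=21)
        ms = em.ensemble_pca(ens)
        np.testing.assert_allclose(em.cosine_overlap(ms, ms, 3), np.eye(3), atol=1e-9)

    def test_orthogonal_planted_first_modes(self):
        rng = np.random.default_rng(30)
        dim = 3 * N_ATOMS
        basis, _ = np.linalg.qr(rng.normal(size=(dim, 2)))
        mean = np.zeros(dim)
        a = ensemble_from_vectors(mean, [mean + basis[:, 0], mean - basis[:, 0]])
        b = ensemble_from_vectors(mean, [mean + basis[:, 1], mean - basis[:, 1]])
        ov = em.cosine_overlap(em.ensemble_pca(a), em.ensemble_pca(b), 1)
        assert ov[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_resampled_ensembles_overlap(self):
        msa = em.ensemble_pca(planted_ensemble(200, [4.0, 1.0], seed=41, basis_seed=99)[0])
        msb = em.ensemble_pca(planted_ensemble(200, [4.0, 1.0], seed=42, basis_seed=99)[0])
        ov = em.cosine_overlap(msa, msb, 2)
        assert np.all(ov.max(axis=1)[:2] > 0.9)

    def test_label_mismatch_rejected(self):
        ens, _, _ = planted_ensemble(10, [1.0], seed=1)
        other = sio.AtomMatchedEnsemble(
            atom_labels=[("B", i + 1, "CA") for i in range(N_ATOMS)],
            frames=ens.frames,
        )
        with pytest.raises(sio.PairingError):
            em.cosine_overlap(em.ensemble_pca(ens), em.ensemble_pca(other), 1)
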