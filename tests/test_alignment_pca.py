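"""Superposition, trajectory PCA, and the essential-dynamics score."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peroxidyn import (
    SelectionSpec,
    TrajectoryEnsemble,
    TrajectoryPCA,
    align_ensemble,
    essential_dynamics_score,
    kabsch_superpose,
    pca_heavy_atoms,
    project_frames,
)
from peroxidyn.exceptions import (
    DegenerateFitError,
    InsufficientFramesError,
    UndefinedScoreError,
)
from peroxidyn.pca import B_FACTOR_SCALE


def random_coords(n, rng, scale=5.0):
    return rng.standard_normal((n, 3)) * scale


class TestKabsch:
    def test_identity_when_equal(self, rng):
        coords = random_coords(10, rng)
        transform, moved, rmsd = kabsch_superpose(coords, coords)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(moved, coords, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_rigid_motion(self, rng):
        coords = random_coords(10, rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = coords @ rot.T + np.array([5.0, 0.0, 0.0])
        _, moved, rmsd = kabsch_superpose(mobile, coords)
        assert rmsd < 1e-9
        np.testing.assert_allclose(moved, coords, atol=1e-8)

    def test_matches_independent_minimizer(self, rng):
        # oracle: scipy's align_vectors solves the same least-squares problem
        ref = random_coords(10, rng)
        mobile = ref + 0.3 * rng.standard_normal(ref.shape)
        _, _, rmsd = kabsch_superpose(mobile, ref)
        rot, rssd = Rotation.align_vectors(
            ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        oracle = rssd / np.sqrt(ref.shape[0])
        np.testing.assert_allclose(rmsd, oracle, atol=1e-6)

    def test_rmsd_invariant_under_rigid_pre_transform(self, rng):
        ref = random_coords(12, rng)
        mobile = ref + 0.2 * rng.standard_normal(ref.shape)
        _, _, base = kabsch_superpose(mobile, ref)
        for seed in range(5):
            r = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            shifted = mobile @ r.T + np.array([seed, -seed, 2.0])
            _, _, rmsd = kabsch_superpose(shifted, ref)
            np.testing.assert_allclose(rmsd, base, atol=1e-9)

    def test_reflection_excluded(self, rng):
        ref = random_coords(8, rng)
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        transform, _, _ = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(transform.rotation) > 0.99

    @pytest.mark.parametrize(
        "coords",
        [
            np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]]),
        ],
        ids=["too-few", "collinear"],
    )
    def test_degenerate_fit_raises(self, coords):
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(coords, coords + 1.0)


class TestAlignEnsemble:
    def _scattered_ensemble(self, toy, rng, n=6):
        frames = []
        for i in range(n):
            r = Rotation.random(rng=rng).as_matrix()
            frames.append(toy.coordinates @ r.T + rng.standard_normal(3) * 10)
        return TrajectoryEnsemble.from_frames(toy.topology, np.stack(frames), "x")

    def test_identical_frames_align_exactly(self, toy_small, rng):
        ens = self._scattered_ensemble(toy_small, rng)
        aligned = align_ensemble(ens)
        for f in range(aligned.n_frames):
            np.testing.assert_allclose(aligned.frames[f], aligned.frames[0], atol=1e-8)

    def test_alignment_never_increases_fit_rmsd(self, toy_small, rng):
        frames = toy_small.coordinates[None] + 0.3 * rng.standard_normal(
            (5, toy_small.topology.n_atoms, 3)
        )
        ens = TrajectoryEnsemble.from_frames(toy_small.topology, frames, "x")
        aligned = align_ensemble(ens)
        from peroxidyn import select_atoms
        from peroxidyn.structures import BACKBONE_HEAVY

        idx = select_atoms(toy_small.topology, BACKBONE_HEAVY)
        for f in range(5):
            pre = np.sqrt(np.mean(np.sum(
                (ens.frames[f][idx] - ens.frames[0][idx]) ** 2, axis=1)))
            post = np.sqrt(np.mean(np.sum(
                (aligned.frames[f][idx] - aligned.frames[0][idx]) ** 2, axis=1)))
            assert post <= pre + 1e-12

    def test_idempotent(self, toy_small, rng):
        ens = self._scattered_ensemble(toy_small, rng)
        once = align_ensemble(ens)
        twice = align_ensemble(once)
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-9)


class TestTrajectoryPCA:
    def test_matches_brute_force_eigendecomposition(self, rng):
        # 20 atoms, 50 frames; oracle: dense covariance eigh
        X = rng.standard_normal((50, 60))
        model = TrajectoryPCA(variance_target=0.75, selection=None).fit(X)
        cov = np.cov(X.T, ddof=1)
        eig = np.linalg.eigvalsh(cov)[::-1]
        np.testing.assert_allclose(model.eigenvalues_[: len(eig)], np.clip(eig, 0, None)[: model.eigenvalues_.size], atol=1e-8)
        # loading vectors span-check against eigh vectors for top components
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k in range(5):
            dot = abs(model.components_[k] @ v[:, order[k]])
            assert dot > 1 - 1e-8

    def test_total_variance_conserved(self, rng):
        X = rng.standard_normal((40, 30)) * 2.0
        model = TrajectoryPCA(selection=None).fit(X)
        total = np.sum(np.var(X, axis=0, ddof=1))
        np.testing.assert_allclose(model.eigenvalues_.sum(), total, rtol=1e-8)

    def test_planted_two_mode_retention(self, toy_small):
        from peroxidyn import synthetic as syn

        dim = toy_small.topology.n_atoms * 3
        modes = syn.ModeSpec(syn.random_orthonormal_modes(dim, 2, 5), [1.0, 0.5])
        ens, _ = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 5000, seed=6
        )
        model = TrajectoryPCA(variance_target=0.75, selection=None).fit(
            ens.frames.reshape(5000, -1)
        )
        nonzero = model.eigenvalues_[model.eigenvalues_ > 1e-10]
        assert nonzero.size == 2
        # lambda1/(lambda1+lambda2) = 1.0 / 1.25 = 0.8 >= 0.75 -> K = 1
        assert model.n_retained_ == 1
        np.testing.assert_allclose(
            nonzero[0] / nonzero.sum(), 0.8, atol=0.02
        )

    def test_planted_modes_recovered_up_to_sign(self, toy_small):
        from peroxidyn import synthetic as syn

        dim = toy_small.topology.n_atoms * 3
        vecs = syn.random_orthonormal_modes(dim, 2, 7)
        modes = syn.ModeSpec(vecs, [1.0, 0.5], noise_sd=0.05)
        ens, _ = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 1500, seed=8
        )
        model = TrajectoryPCA(selection=None).fit(ens.frames.reshape(1500, -1))
        for k in range(2):
            assert abs(model.components_[k] @ vecs[k]) >= 0.99

    def test_constant_trajectory_warns_and_retains_zero(self, toy_small):
        frames = np.repeat(toy_small.coordinates[None], 5, axis=0)
        with pytest.warns(RuntimeWarning, match="zero"):
            model = TrajectoryPCA(selection=None).fit(frames.reshape(5, -1))
        assert model.n_retained_ == 0

    def test_too_few_frames(self, toy_small):
        with pytest.raises(InsufficientFramesError):
            TrajectoryPCA(selection=None).fit(
                toy_small.coordinates.reshape(1, -1)
            )

    def test_projection_of_mean_is_zero(self, rng):
        X = rng.standard_normal((30, 12))
        model = TrajectoryPCA(selection=None).fit(X)
        scores = model.transform(X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)

    def test_projection_along_first_component(self, rng):
        X = rng.standard_normal((30, 12))
        model = TrajectoryPCA(variance_target=1.0, selection=None).fit(X)
        probe = model.mean_ + 2.5 * model.components_[0]
        scores = model.transform(probe[None])
        np.testing.assert_allclose(scores[0, 0], 2.5, atol=1e-10)
        np.testing.assert_allclose(scores[0, 1:], 0.0, atol=1e-10)

    def test_reconstruction_residual_bounded(self, toy_small):
        from peroxidyn import synthetic as syn

        dim = toy_small.topology.n_atoms * 3
        modes = syn.ModeSpec(
            syn.random_orthonormal_modes(dim, 3, 9), [1.0, 0.6, 0.3],
            noise_sd=0.05,
        )
        ens, _ = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 400, seed=10
        )
        X = ens.frames.reshape(400, -1)
        model = TrajectoryPCA(variance_target=0.75, selection=None).fit(X)
        scores = model.transform(X)
        recon = model.inverse_transform(scores)
        residual_var = np.sum(np.var(X - recon, axis=0, ddof=1))
        total_var = np.sum(np.var(X, axis=0, ddof=1))
        bound = (1.0 - model.cumulative_variance_[model.n_retained_ - 1]) * total_var
        assert residual_var <= bound * (1 + 1e-8)


class TestEssentialDynamicsScore:
    def _single_atom_oscillation(self, toy):
        # one atom's x oscillates with unbiased sample variance exactly 1 Å²
        n_frames = 10
        amp = np.sqrt((n_frames - 1) / n_frames)
        frames = np.repeat(toy.coordinates[None], n_frames, axis=0)
        signs = np.array([1.0, -1.0] * (n_frames // 2))
        frames[:, 7, 0] = toy.coordinates[7, 0] + amp * signs
        return TrajectoryEnsemble.from_frames(toy.topology, frames, "x")

    def test_unit_variance_atom_scores_eight_pi_squared_thirds(self, toy_small):
        ens = self._single_atom_oscillation(toy_small)
        model = TrajectoryPCA(variance_target=0.75, selection=None).fit(ens)
        profile = essential_dynamics_score(model, toy_small.topology)
        np.testing.assert_allclose(profile.per_atom[7], B_FACTOR_SCALE, rtol=1e-10)
        others = np.delete(profile.per_atom, 7)
        np.testing.assert_allclose(others, 0.0, atol=1e-10)
        # residue score: the oscillating atom sits in residue 2 (4 atoms)
        key = toy_small.topology.atoms[7].residue_key
        np.testing.assert_allclose(
            profile.per_residue[key], B_FACTOR_SCALE / 4.0, rtol=1e-10
        )

    def test_full_component_score_equals_total_variance_trace(self, toy_small, rng):
        frames = toy_small.coordinates[None] + 0.2 * rng.standard_normal(
            (60, toy_small.topology.n_atoms, 3)
        )
        ens = TrajectoryEnsemble.from_frames(toy_small.topology, frames, "x")
        model = TrajectoryPCA(variance_target=1.0, selection=None).fit(ens)
        profile = essential_dynamics_score(
            model, toy_small.topology, n_components=model.eigenvalues_.size
        )
        # oracle: per-atom total positional variance computed directly
        flat = frames.reshape(60, -1)
        var = np.var(flat, axis=0, ddof=1).reshape(-1, 3).sum(axis=1)
        np.testing.assert_allclose(profile.per_atom, B_FACTOR_SCALE * var, rtol=1e-8)

    def test_score_monotone_in_component_count(self, toy_small, rng):
        frames = toy_small.coordinates[None] + 0.3 * rng.standard_normal(
            (50, toy_small.topology.n_atoms, 3)
        )
        ens = TrajectoryEnsemble.from_frames(toy_small.topology, frames, "x")
        model = TrajectoryPCA(selection=None).fit(ens)
        previous = np.zeros(toy_small.topology.n_atoms)
        for k in range(1, model.eigenvalues_.size + 1, 7):
            profile = essential_dynamics_score(model, toy_small.topology, n_components=k)
            assert np.all(profile.per_atom >= previous - 1e-12)
            previous = profile.per_atom

    def test_per_residue_between_member_extremes(self, toy_small, rng):
        frames = toy_small.coordinates[None] + 0.3 * rng.standard_normal(
            (40, toy_small.topology.n_atoms, 3)
        )
        ens = TrajectoryEnsemble.from_frames(toy_small.topology, frames, "x")
        model = TrajectoryPCA(selection=None).fit(ens)
        profile = essential_dynamics_score(model, toy_small.topology)
        for key, positions in toy_small.topology.residue_index.items():
            members = profile.per_atom[positions]
            assert members.min() - 1e-12 <= profile.per_residue[key] <= members.max() + 1e-12

    def test_zero_components_raises(self, toy_small):
        frames = np.repeat(toy_small.coordinates[None], 5, axis=0)
        with pytest.warns(RuntimeWarning):
            model = TrajectoryPCA(selection=None).fit(frames.reshape(5, -1))
        with pytest.raises(UndefinedScoreError):
            essential_dynamics_score(model, toy_small.topology)


class TestFunctionalWrappers:
    def test_pca_heavy_atoms_and_project(self, toy_small, rng):
        frames = toy_small.coordinates[None] + 0.2 * rng.standard_normal(
            (30, toy_small.topology.n_atoms, 3)
        )
        ens = TrajectoryEnsemble.from_frames(toy_small.topology, frames, "x")
        model = pca_heavy_atoms(ens)
        scores = project_frames(model, ens)
        assert scores.shape == (30, model.n_retained_)
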