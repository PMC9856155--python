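"""Combined PCA against a brute-force covariance oracle and planted modes."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from codyn import synthetic as syn
from codyn.errors import AlignmentStateError, DegenerateSpanError
from codyn.pca import (
    fit_pca,
    project,
    pseudo_trajectory,
    residue_rmsf_in_mode,
    system_stats,
)
from codyn.superposition import align_to_mean
from codyn.trajectory import Trajectory, concatenate, split_chains


def _tagged_traj(coords, tag="s", aligned=True):
    n_atoms = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "chain_id": ["A"] * n_atoms,
            "resid": np.arange(1, n_atoms + 1),
            "name": ["CA"] * n_atoms,
            "element": ["C"] * n_atoms,
        }
    )
    return Trajectory(
        atoms=atoms,
        coords=coords,
        system=np.full(coords.shape[0], tag, dtype=object),
        aligned=aligned,
    )


def brute_force_pca(coords):
    """Independent oracle: explicit 3N x 3N covariance + dense eigensolve."""
    x = coords.reshape(coords.shape[0], -1)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / x.shape[0]
    evals, evecs = scipy.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestFitPCA:
    def test_identical_frames_give_zero_eigenvalues(self):
        coords = np.repeat(np.random.default_rng(0).uniform(0, 10, (1, 5, 3)), 8, axis=0)
        model = fit_pca(_tagged_traj(coords))
        assert np.allclose(model.eigenvalues, 0, atol=1e-20)

    def test_matches_brute_force_on_small_instance(self):
        coords = np.random.default_rng(1).normal(size=(10, 5, 3))
        model = fit_pca(_tagged_traj(coords))
        ref_evals, ref_evecs = brute_force_pca(coords)
        # thin SVD keeps min(F, 3N) pairs; the dense oracle keeps all 3N
        nz = np.flatnonzero(ref_evals > 1e-12 * ref_evals[0])
        nz = nz[nz < model.rank]
        assert np.allclose(
            model.eigenvalues[nz], ref_evals[nz], rtol=1e-8
        )
        # eigenvectors agree up to sign
        for j in nz:
            dot = abs(model.eigenvectors[:, j] @ ref_evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_variance_conservation(self):
        coords = np.random.default_rng(2).normal(size=(30, 7, 3))
        model = fit_pca(_tagged_traj(coords))
        x = coords.reshape(30, -1)
        total = ((x - x.mean(axis=0)) ** 2).sum() / 30
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-8)
        assert model.total_variance == pytest.approx(total, rel=1e-8)

    def test_single_planted_mode_eigenvalue_is_amplitude_squared(self, toy_monomer):
        modes = syn.make_mode_set(toy_monomer, 1, seed=1, sigma_noise=0.0)
        modes.with_system("s", mu=[0.0], a=[2.0])
        traj = syn.simulate_system_trajectory(toy_monomer, modes, "s", 4000, seed=5)
        traj.aligned = True  # noise-free, rigid-free planted motion
        model = fit_pca(traj)
        # oracle: the sample variance of the planted z draws
        proj = (traj.coords.reshape(4000, -1) - toy_monomer.flat()) @ modes.vectors[:, 0]
        assert model.eigenvalues[0] == pytest.approx(proj.var(), rel=1e-8)
        assert model.eigenvalues[0] == pytest.approx(4.0, rel=0.1)
        assert model.eigenvalues[1] < 1e-8 * model.eigenvalues[0]

    def test_unaligned_input_is_state_error(self):
        coords = np.random.default_rng(3).normal(size=(5, 4, 3))
        with pytest.raises(AlignmentStateError):
            fit_pca(_tagged_traj(coords, aligned=False))

    def test_eigenvector_sign_convention(self):
        coords = np.random.default_rng(4).normal(size=(12, 5, 3))
        model = fit_pca(_tagged_traj(coords))
        for j in range(3):
            v = model.eigenvectors[:, j]
            assert v[np.argmax(np.abs(v))] > 0


class TestProjection:
    @pytest.fixture()
    def small_model(self):
        coords = np.random.default_rng(5).normal(size=(20, 6, 3))
        traj = _tagged_traj(coords)
        return traj, fit_pca(traj)

    def test_mean_structure_projects_to_zero(self, small_model):
        traj, model = small_model
        mean_traj = _tagged_traj(model.mean.reshape(1, -1, 3))
        series = project(mean_traj, model, [0, 1, 2])
        assert np.allclose(series.values, 0, atol=1e-10)

    def test_displaced_mean_projects_to_its_own_coefficient(self, small_model):
        _, model = small_model
        frame = model.mean + 2.5 * model.eigenvectors[:, 2]
        series = project(_tagged_traj(frame.reshape(1, -1, 3)), model, [0, 1, 2, 3])
        expected = np.zeros(4)
        expected[2] = 2.5
        assert np.allclose(series.values[0], expected, atol=1e-10)

    def test_projection_variance_equals_eigenvalue(self, small_model):
        traj, model = small_model
        series = project(traj, model, list(range(5)))
        for j in range(5):
            assert series.values[:, j].var() == pytest.approx(
                model.eigenvalues[j], rel=1e-8
            )
        # combined-trajectory projections are mean-free on every PC
        assert np.abs(series.values.mean(axis=0)).max() < 1e-8

    def test_dimension_mismatch_rejected(self, small_model):
        _, model = small_model
        other = _tagged_traj(np.zeros((2, 3, 3)))
        with pytest.raises(ValueError):
            project(other, model, [0])


class TestSystemStats:
    def test_two_point_series(self):
        from codyn.pca import ProjectionSeries

        series = ProjectionSeries(
            pcs=[0],
            values=np.array([[1.0], [-1.0]]),
            system=np.array(["s", "s"], dtype=object),
        )
        stats = system_stats(series)
        assert stats.loc[0, "avg_proj_A"] == pytest.approx(0.0)
        assert stats.loc[0, "rmsf_A"] == pytest.approx(1.0)  # population sd

    def test_frame_weighted_mean_of_averages_is_zero(self):
        coords = np.random.default_rng(6).normal(size=(40, 5, 3))
        tags = np.array(["a"] * 10 + ["b"] * 30, dtype=object)
        traj = _tagged_traj(coords)
        traj.system = tags
        model = fit_pca(traj)
        stats = system_stats(project(traj, model, [0, 1]))
        for pc in [1, 2]:
            sub = stats[stats["pc"] == pc]
            weighted = (sub["avg_proj_A"] * sub["n_frames"]).sum() / sub["n_frames"].sum()
            assert abs(weighted) < 1e-8


class TestPseudoTrajectory:
    @pytest.fixture()
    def model(self):
        coords = np.random.default_rng(7).normal(size=(25, 6, 3))
        return fit_pca(_tagged_traj(coords))

    def test_two_frames_are_exactly_start_and_end(self, model):
        ps = pseudo_trajectory(model, 0, n_frames=2)
        assert ps.frames.shape[0] == 2
        assert np.array_equal(ps.start, ps.frames[0])
        assert np.array_equal(ps.end, ps.frames[-1])
        assert ps.displacements[0] < ps.displacements[-1]

    def test_frames_reproject_to_their_own_displacement(self, model):
        ps = pseudo_trajectory(model, 1, n_frames=7)
        traj = _tagged_traj(ps.frames)
        series = project(traj, model, [0, 1, 2, 3])
        assert np.allclose(series.values[:, 1], ps.displacements, atol=1e-8)
        off = np.delete(series.values, 1, axis=1)
        assert np.abs(off).max() < 1e-8

    def test_observed_span_equals_projection_range(self, model):
        ps = pseudo_trajectory(model, 0, n_frames=5, span="observed")
        assert ps.displacements[0] == pytest.approx(model.proj_min[0], abs=1e-10)
        assert ps.displacements[-1] == pytest.approx(model.proj_max[0], abs=1e-10)

    def test_zero_variance_pc_gives_degenerate_span_error(self):
        coords = np.repeat(np.random.default_rng(8).uniform(0, 5, (1, 4, 3)), 6, axis=0)
        model = fit_pca(_tagged_traj(coords))
        with pytest.raises(DegenerateSpanError):
            pseudo_trajectory(model, 0, span="observed")

    def test_std_span_is_symmetric(self, model):
        ps = pseudo_trajectory(model, 0, n_frames=3, span=("std", 2.0))
        half = 2.0 * np.sqrt(model.eigenvalues[0])
        assert ps.displacements[0] == pytest.approx(-half)
        assert ps.displacements[-1] == pytest.approx(half)


class TestResidueRMSF:
    def test_normalisation_identity(self):
        coords = np.random.default_rng(9).normal(size=(15, 8, 3))
        model = fit_pca(_tagged_traj(coords))
        vals = residue_rmsf_in_mode(model, 0)
        assert (vals**2).sum() / model.eigenvalues[0] == pytest.approx(1.0, rel=1e-10)

    def test_zero_variance_pc_gives_zero_values(self):
        coords = np.repeat(np.random.default_rng(10).uniform(0, 5, (1, 4, 3)), 6, axis=0)
        model = fit_pca(_tagged_traj(coords))
        assert np.allclose(residue_rmsf_in_mode(model, 0), 0.0)

    def test_planted_mode_hotspots_recovered(self, toy_monomer):
        # oracle: per-residue component norms of the planted vector
        modes = syn.make_mode_set(toy_monomer, 1, seed=4, sigma_noise=0.0)
        modes.with_system("s", mu=[0.0], a=[2.0])
        traj = syn.simulate_system_trajectory(toy_monomer, modes, "s", 3000, seed=6)
        traj.aligned = True
        model = fit_pca(traj)
        recovered = residue_rmsf_in_mode(model, 0)
        planted = np.linalg.norm(modes.vectors[:, 0].reshape(-1, 3), axis=1)
        rho = np.corrcoef(
            np.argsort(np.argsort(recovered)), np.argsort(np.argsort(planted))
        )[0, 1]
        assert rho > 0.95


class TestDiagnosticFidelity:
    """The interpretive rules: average projection separates average
    structures; r.m.s.f. in projection separates dynamics; and the two
    diagnostics are independent of each other."""

    def _combined(self, params, n_frames=600, seed=0):
        s = syn.make_toy_structure(30, 1, seed)
        modes = syn.make_mode_set(s, 2, seed=seed, sigma_noise=0.1)
        parts = []
        for i, (tag, mu, a) in enumerate(params):
            modes.with_system(tag, mu=mu, a=a)
            parts.append(
                syn.simulate_system_trajectory(s, modes, tag, n_frames, seed=100 + i)
            )
        combined = align_to_mean(concatenate(parts))
        model = fit_pca(combined)
        stats = system_stats(project(combined, model, [0, 1]))
        return modes, model, stats

    def test_mean_shift_changes_average_not_rmsf(self):
        modes, model, stats = self._combined(
            [("plus", [2.0, 0.0], [1.0, 1.0]), ("minus", [-2.0, 0.0], [1.0, 1.0])]
        )
        pc1 = stats[stats["pc"] == 1].set_index("system")
        sign = np.sign(model.eigenvectors[:, 0] @ modes.vectors[:, 0])
        assert pc1.loc["plus", "avg_proj_A"] * sign == pytest.approx(2.0, abs=0.2)
        assert pc1.loc["minus", "avg_proj_A"] * sign == pytest.approx(-2.0, abs=0.2)
        ratio = pc1.loc["plus", "rmsf_A"] / pc1.loc["minus", "rmsf_A"]
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_amplitude_change_changes_rmsf_not_average(self):
        _, _, stats = self._combined(
            [("live", [0.0, 0.0], [1.0, 2.0]), ("quenched", [0.0, 0.0], [1.0, 1.0])]
        )
        # mode-2 fluctuations dominate PC 1 here (4x vs 1x variance)
        pc1 = stats[stats["pc"] == 1].set_index("system")
        assert pc1.loc["live", "rmsf_A"] / pc1.loc["quenched", "rmsf_A"] > 1.5
        assert abs(pc1.loc["live", "avg_proj_A"]) < 0.2
        assert abs(pc1.loc["quenched", "avg_proj_A"]) < 0.2
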