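"""Generator contracts: determinism, planted truth, and limiting cases."""

import numpy as np
import pytest
from scipy import stats

from peroxidyn import synthetic as syn


class TestToyTopology:
    def test_two_residue_backbone(self):
        toy = syn.build_toy_topology(2)
        assert toy.topology.n_atoms == 8
        assert {a.name for a in toy.topology.atoms} == {"N", "CA", "C", "O"}

    def test_cofactors_have_single_iron(self, toy_cofactors):
        fe = [a for a in toy_cofactors.topology.atoms if a.name == "FE"]
        assert len(fe) == 1
        assert fe[0].residue_name == "HEM"
        plm_names = {
            a.name for a in toy_cofactors.topology.atoms if a.residue_name == "PLM"
        }
        assert {"CA", "CB"} <= plm_names

    def test_advertised_backbone_count_cross_module(self, toy_polar):
        from peroxidyn import SelectionSpec, select_atoms

        idx = select_atoms(
            toy_polar.topology,
            SelectionSpec(residue_range=(1, 5), backbone_only=True,
                          exclude_hydrogens=True),
        )
        assert len(idx) == toy_polar.advertised_count(
            residue_range=(1, 5), backbone_only=True, exclude_hydrogens=True
        )
        assert len(idx) == 20  # 4 backbone atoms x 5 residues

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            syn.build_toy_topology(1)


class TestModeTrajectory:
    def test_seed_determinism_bitwise(self, toy_small):
        modes = syn.ModeSpec(
            syn.random_orthonormal_modes(toy_small.topology.n_atoms * 3, 2, 0),
            [1.0, 0.5], noise_sd=0.1,
        )
        a, _ = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 10, seed=7
        )
        b, _ = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 10, seed=7
        )
        assert np.array_equal(a.frames, b.frames)

    def test_covariance_eigenvalues_recovered(self, toy_small):
        # oracle: dense covariance eigendecomposition of the generated frames
        dim = toy_small.topology.n_atoms * 3
        modes = syn.ModeSpec(syn.random_orthonormal_modes(dim, 2, 1), [1.0, 0.5])
        ens, _ = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 5000, seed=11
        )
        flat = ens.frames.reshape(5000, -1)
        eig = np.linalg.eigvalsh(np.cov(flat.T))[::-1]
        np.testing.assert_allclose(eig[0], 1.0, rtol=0.05)
        np.testing.assert_allclose(eig[1], 0.25, rtol=0.05)
        assert np.all(np.abs(eig[2:]) < 1e-10)

    def test_two_frame_forced_coefficients(self, toy_small):
        # 2-frame PCA by hand: cov = outer(v, v) * (2 a^2) / (F-1) -> top evec = v
        dim = toy_small.topology.n_atoms * 3
        mode = syn.random_orthonormal_modes(dim, 1, 2)
        modes = syn.ModeSpec(mode, [1.0])
        ens, truth = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 2, seed=0,
            coefficients=np.array([[1.0], [-1.0]]),
        )
        flat = ens.frames.reshape(2, -1)
        centered = flat - flat.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        assert abs(float(vt[0] @ mode[0])) > 1 - 1e-10

    def test_zero_amplitude_zero_noise_constant(self, toy_small):
        dim = toy_small.topology.n_atoms * 3
        modes = syn.ModeSpec(syn.random_orthonormal_modes(dim, 1, 3), [0.0])
        ens, _ = syn.generate_mode_trajectory(
            toy_small.topology, toy_small.coordinates, modes, 5, seed=0
        )
        assert np.all(ens.frames == ens.frames[0])

    def test_non_orthonormal_modes_rejected(self, toy_small):
        dim = toy_small.topology.n_atoms * 3
        bad = np.ones((2, dim)) / np.sqrt(dim)
        with pytest.raises(ValueError, match="orthonormal"):
            syn.ModeSpec(bad, [1.0, 0.5])

    def test_increasing_amplitudes_rejected(self, toy_small):
        dim = toy_small.topology.n_atoms * 3
        vecs = syn.random_orthonormal_modes(dim, 2, 4)
        with pytest.raises(ValueError, match="decreasing"):
            syn.ModeSpec(vecs, [0.5, 1.0])


class TestMetastable:
    def test_single_state_single_label(self, toy_small):
        plan = syn.make_state_plan(toy_small.coordinates, 1, 20, 3.0, 0.2, seed=0)
        _, labels = syn.generate_metastable_ensemble(toy_small.topology, plan, seed=1)
        assert set(labels) == {0}

    def test_overlap_zero_collapses_centers(self, toy_small):
        plan = syn.make_state_plan(
            toy_small.coordinates, 3, 10, 3.0, 0.2, seed=0, overlap_factor=0.0
        )
        centers = plan.effective_centers()
        assert np.allclose(centers, centers[0])

    def test_separation_is_rmsd_scale(self, toy_small):
        plan = syn.make_state_plan(toy_small.coordinates, 2, 10, 3.0, 0.2, seed=5)
        for center in plan.state_centers:
            rmsd = np.sqrt(
                np.mean(np.sum((center - toy_small.coordinates) ** 2, axis=1))
            )
            np.testing.assert_allclose(rmsd, 3.0, rtol=1e-10)

    def test_true_labels_align_with_frames(self, toy_small):
        plan = syn.make_state_plan(toy_small.coordinates, 3, 7, 5.0, 0.01, seed=2)
        ens, labels = syn.generate_metastable_ensemble(toy_small.topology, plan, seed=3)
        centers = plan.effective_centers()
        for f in range(ens.n_frames):
            dists = [np.linalg.norm(ens.frames[f] - c) for c in centers]
            assert int(np.argmin(dists)) == labels[f]


class TestHBondScenario:
    def _plan(self, toy, occ_a, occ_b):
        triads = [
            (toy.donor_pairs[0][0], toy.donor_pairs[0][1], toy.acceptor_indices[-1]),
        ]
        return syn.HBondPlan(
            triads=triads,
            occupancy_by_condition={"A": [occ_a], "B": [occ_b]},
        )

    def test_occupancy_one_always_on(self, toy_polar):
        plan = self._plan(toy_polar, 1.0, 0.0)
        _, truth = syn.generate_hbond_scenario(
            toy_polar.topology, toy_polar.coordinates, plan, 50, seed=0
        )
        assert truth.realized_on["A"].all()
        assert not truth.realized_on["B"].any()

    def test_empirical_occupancy_within_binomial_bounds(self, toy_polar):
        plan = self._plan(toy_polar, 0.7, 0.2)
        n = 200
        _, truth = syn.generate_hbond_scenario(
            toy_polar.topology, toy_polar.coordinates, plan, n, seed=42
        )
        for label, p in (("A", 0.7), ("B", 0.2)):
            count = int(truth.realized_on[label].sum())
            lo = stats.binom.ppf(0.005, n, p)
            hi = stats.binom.ppf(0.995, n, p)
            assert lo <= count <= hi

    def test_bound_geometry_must_satisfy_cutoffs(self, toy_polar):
        with pytest.raises(ValueError, match="bound geometry"):
            syn.HBondPlan(
                triads=[(0, 1, 2)],
                occupancy_by_condition={"A": [0.5]},
                bound_geometry=(3.5, 0.0),
            )

    def test_unbound_geometry_must_violate(self, toy_polar):
        with pytest.raises(ValueError, match="unbound geometry"):
            syn.HBondPlan(
                triads=[(0, 1, 2)],
                occupancy_by_condition={"A": [0.5]},
                unbound_geometry=(2.9, 10.0),
            )

    def test_seed_determinism(self, toy_polar):
        plan = self._plan(toy_polar, 0.5, 0.5)
        e1, _ = syn.generate_hbond_scenario(
            toy_polar.topology, toy_polar.coordinates, plan, 20, seed=9
        )
        e2, _ = syn.generate_hbond_scenario(
            toy_polar.topology, toy_polar.coordinates, plan, 20, seed=9
        )
        assert np.array_equal(e1["A"].frames, e2["A"].frames)


class TestCoupledTrajectory:
    def test_rho_validation(self, toy_cofactors):
        with pytest.raises(ValueError, match="rho"):
            syn.generate_coupled_substrate_trajectory(
                toy_cofactors, 3, rho=1.5, n_frames=10, seed=0
            )

    def test_truth_record_consistency(self, toy_cofactors):
        ens, truth = syn.generate_coupled_substrate_trajectory(
            toy_cofactors, 3, rho=0.8, n_frames=50, seed=1
        )
        assert truth.z_true.shape == (50,)
        assert np.all(truth.fe_cbeta_distance > 0)
        assert np.all((truth.calpha_cbeta_fe_angle >= 0)
                      & (truth.calpha_cbeta_fe_angle <= 180))
        assert truth.coupled_residue_key[1] == 3
        # z_true is the standardized equal-weight combination
        assert abs(truth.z_true.mean()) < 1e-9


class TestSpectroDatasets:
    def test_kinetics_noiseless_recovery_to_six_digits(self):
        from peroxidyn import fit_double_exponential

        t = np.linspace(0, 0.25, 400)
        table, truth = syn.generate_spectro_dataset(
            "kinetics",
            {"offset": 0.05, "a_fast": 0.4, "k_fast": 183.0,
             "a_slow": 0.2, "k_slow": 24.1},
            noise_sd=0.0, design=t, seed=0,
        )
        fit = fit_double_exponential(table["time_s"], table["absorbance"])
        np.testing.assert_allclose(fit.rates_[0], 183.0, rtol=1e-6)
        np.testing.assert_allclose(fit.rates_[1], 24.1, rtol=1e-6)

    def test_titration_weak_binding_limit_is_hyperbola(self):
        s = np.linspace(0.1, 50, 60)
        kd, damax, enzyme = 5.0, 0.1, 0.005  # E = 0.001 Kd
        table, _ = syn.generate_spectro_dataset(
            "titration", {"kd": kd, "damax": damax, "enzyme": enzyme},
            noise_sd=0.0, design=s, seed=0,
        )
        hyperbola = damax * s / (s + kd)
        np.testing.assert_allclose(
            table["delta_absorbance"], hyperbola, rtol=1e-3, atol=1e-6 * damax
        )

    def test_melting_half_transition_at_tm(self):
        t = np.linspace(20, 90, 141)
        table, truth = syn.generate_spectro_dataset(
            "melting", {"tm": 51.0, "slope": 2.5, "lower": -20.0, "upper": -2.0},
            noise_sd=0.0, design=t, seed=0,
        )
        at_tm = np.interp(51.0, table["temperature_c"], table["ellipticity"])
        np.testing.assert_allclose(at_tm, (-20.0 + -2.0) / 2, atol=1e-6)

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            syn.generate_spectro_dataset("nmr", {}, 0.0, np.arange(5.0), seed=0)

    def test_truth_record_carries_parameters(self):
        _, truth = syn.generate_spectro_dataset(
            "titration", {"kd": 2.0, "damax": 0.1, "enzyme": 5.0},
            noise_sd=0.01, design=np.linspace(0, 30, 20), seed=4,
        )
        assert truth["kd"] == 2.0 and truth["noise_sd"] == 0.01
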