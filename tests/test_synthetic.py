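import numpy as np
import pytest

from mdcompare import (
    ConformerMixtureSpec,
    GaussianEnsembleSpec,
    TwoStateContactSpec,
    analytic_dcc,
    compute_dcc,
    contact_counts_frame,
    dynamical_contact_network,
    linear_structure,
    make_conformer_mixture,
    make_gaussian_ensemble,
    make_two_state_pair,
    perturbation,
    residue_mode,
    spec_from_covariance,
    static_contact_difference,
)
from mdcompare.synthetic import SpecError


class TestGaussianEnsemble:
    def test_zero_modes_zero_noise_gives_reference(self, small_structure):
        structure, ref = small_structure
        spec = GaussianEnsembleSpec(structure=structure, reference_coords=ref)
        e = make_gaussian_ensemble(spec, 5, seed=0)
        assert np.array_equal(e.coords, np.stack([ref] * 5))

    def test_single_mode_variance_matches_closed_form(self, small_structure):
        structure, ref = small_structure
        v = residue_mode(structure, {1: [0, 1, 0], 4: [0, 1, 0]}, atoms="all")
        spec = GaussianEnsembleSpec(
            structure=structure, reference_coords=ref, modes=((v, 1.0),)
        )
        e = make_gaussian_ensemble(spec, 10_000, seed=1)
        disp = (e.coords - ref[None]).reshape(e.n_frames, -1)
        sample_var = disp.var(axis=0)
        # per-coordinate displacement variance = lambda * component^2
        expect = v ** 2
        active = expect > 0
        assert np.allclose(sample_var[active], expect[active], rtol=0.10)
        assert np.allclose(sample_var[~active], 0.0)

    def test_same_seed_bit_identical(self, noise_spec):
        a = make_gaussian_ensemble(noise_spec, 20, seed=42)
        b = make_gaussian_ensemble(noise_spec, 20, seed=42)
        assert np.array_equal(a.coords, b.coords)

    def test_different_seed_differs(self, noise_spec):
        a = make_gaussian_ensemble(noise_spec, 20, seed=1)
        b = make_gaussian_ensemble(noise_spec, 20, seed=2)
        assert not np.array_equal(a.coords, b.coords)

    def test_nonorthonormal_modes_rejected(self, small_structure):
        structure, ref = small_structure
        v = residue_mode(structure, {0: [1, 0, 0]})
        with pytest.raises(SpecError):
            GaussianEnsembleSpec(
                structure=structure,
                reference_coords=ref,
                modes=((v, 1.0), (v, 0.5)),
            )

    def test_amplitudes_must_not_increase(self, small_structure):
        structure, ref = small_structure
        v1 = residue_mode(structure, {0: [1, 0, 0]})
        v2 = residue_mode(structure, {1: [0, 1, 0]})
        with pytest.raises(SpecError):
            GaussianEnsembleSpec(
                structure=structure,
                reference_coords=ref,
                modes=((v1, 0.5), (v2, 1.0)),
            )

    def test_min_frames(self, noise_spec):
        with pytest.raises(SpecError):
            make_gaussian_ensemble(noise_spec, 1, seed=0)

    def test_sample_covariance_converges_to_model(self):
        # Frobenius relative error < 5% at n = 5e4 for a 10-residue spec
        structure, ref = linear_structure(10, 3)
        v1 = residue_mode(structure, {i: [0, 1, 0] for i in range(5)}, atoms="all")
        v2 = residue_mode(structure, {i: [0, 0, 1] for i in range(5, 10)}, atoms="all")
        spec = GaussianEnsembleSpec(
            structure=structure,
            reference_coords=ref,
            modes=((v1, 2.0), (v2, 1.0)),
            noise_sigma=0.3,
        )
        e = make_gaussian_ensemble(spec, 50_000, seed=7)
        disp = (e.coords - ref[None]).reshape(e.n_frames, -1)
        sample = disp.T @ disp / e.n_frames
        model = spec.model_covariance()
        rel = np.linalg.norm(sample - model) / np.linalg.norm(model)
        assert rel < 0.05


class TestAnalyticDcc:
    def test_shared_mode_perfect_correlation(self):
        structure, ref = linear_structure(2, 3)
        v = residue_mode(structure, {0: [0, 1, 0], 1: [0, 1, 0]})
        spec = GaussianEnsembleSpec(
            structure=structure, reference_coords=ref, modes=((v, 1.0),)
        )
        assert analytic_dcc(spec).matrix[0, 1] == pytest.approx(1.0)

    def test_opposite_sign_anticorrelation(self):
        structure, ref = linear_structure(2, 3)
        v = residue_mode(structure, {0: [0, 1, 0], 1: [0, -1, 0]})
        spec = GaussianEnsembleSpec(
            structure=structure, reference_coords=ref, modes=((v, 1.0),)
        )
        assert analytic_dcc(spec).matrix[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_residue_rejected(self, one_mode_spec):
        # residues without mode components and zero noise have no variance
        with pytest.raises(SpecError):
            analytic_dcc(one_mode_spec)

    def test_mode_plus_noise_matches_brute_force_covariance(self, small_structure):
        # independent oracle: assemble the dense model covariance and
        # evaluate the correlation with explicit per-axis loops
        structure, ref = small_structure
        v = residue_mode(structure, {1: [0, 1, 0], 4: [0, 1, 0]})
        spec = GaussianEnsembleSpec(
            structure=structure,
            reference_coords=ref,
            modes=((v, 1.0),),
            noise_sigma=1.0,
        )
        dcc = analytic_dcc(spec)
        cov = spec.model_covariance()
        reps = [structure.residue_atoms(r)[0] for r in range(structure.n_residues)]
        # CA is the first atom of each residue in the scaffold
        for i in range(structure.n_residues):
            for j in range(structure.n_residues):
                tr_ij = sum(cov[3 * reps[i] + ax, 3 * reps[j] + ax] for ax in range(3))
                tr_ii = sum(cov[3 * reps[i] + ax, 3 * reps[i] + ax] for ax in range(3))
                tr_jj = sum(cov[3 * reps[j] + ax, 3 * reps[j] + ax] for ax in range(3))
                expect = tr_ij / np.sqrt(tr_ii * tr_jj)
                assert dcc.matrix[i, j] == pytest.approx(expect, abs=1e-6)

    def test_analytic_matches_sampled_dcc(self, small_structure):
        # cross-module invariant: analytic vs trajectory DCC within 0.03
        structure, ref = small_structure
        v = residue_mode(structure, {1: [0, 1, 0], 4: [0, 1, 0]}, atoms="all")
        spec = GaussianEnsembleSpec(
            structure=structure,
            reference_coords=ref,
            modes=((v, 1.0),),
            noise_sigma=0.4,
        )
        e = make_gaussian_ensemble(spec, 20_000, seed=11)
        sampled = compute_dcc(e, fit=False)
        assert np.allclose(sampled.matrix, analytic_dcc(spec).matrix, atol=0.03)


class TestSpecFromCovariance:
    def test_round_trip(self, small_structure):
        structure, ref = small_structure
        dim = 3 * structure.n_atoms
        rng = np.random.default_rng(0)
        A = rng.standard_normal((dim, 3))
        cov = A @ A.T
        spec = spec_from_covariance(structure, ref, cov)
        assert np.allclose(spec.model_covariance(), cov, atol=1e-8)


class TestTwoStatePair:
    def _spec(self, displacement, block=(3, 4), noise=0.1):
        structure, ref = linear_structure(5, 3)
        base = GaussianEnsembleSpec(
            structure=structure, reference_coords=ref, noise_sigma=noise
        )
        return TwoStateContactSpec(
            base=base, displaced_block=block, displacement=displacement
        )

    def test_block_must_be_strict_subset(self):
        with pytest.raises(SpecError):
            self._spec([0, 0, 1], block=(0, 1, 2, 3, 4))

    def test_block_out_of_range(self):
        with pytest.raises(SpecError):
            self._spec([0, 0, 1], block=(9,))

    def test_null_displacement_gives_empty_dpn(self):
        spec = self._spec([0.0, 0.0, 0.0])
        a, b = make_two_state_pair(spec, 2000, seed=3)
        net_a = dynamical_contact_network([a], exclude_bonded=0)
        net_b = dynamical_contact_network([b], exclude_bonded=0)
        assert perturbation(net_a, net_b, threshold=5.0).deltas == {}

    def test_displacement_pulls_block_out_of_contact(self):
        # hand geometry: 6 A z-shift of residues {3,4} breaks the 9
        # atom-pair contacts of edge (2,3); spacing keeps others intact
        spec = self._spec([0.0, 0.0, 6.0])
        truth = static_contact_difference(spec, cutoff=5.0, exclude_bonded=0)
        assert truth == {(2, 3): -9.0}
        a, b = make_two_state_pair(spec, 3000, seed=5)
        net_a = dynamical_contact_network([a], exclude_bonded=0)
        net_b = dynamical_contact_network([b], exclude_bonded=0)
        dpn = perturbation(net_a, net_b, threshold=5.0)
        assert set(dpn.deltas) == {(2, 3)}
        assert dpn.deltas[(2, 3)] < -5

    def test_swap_flips_signs(self):
        spec = self._spec([0.0, 0.0, 6.0])
        a, b = make_two_state_pair(spec, 1500, seed=6)
        net_a = dynamical_contact_network([a], exclude_bonded=0)
        net_b = dynamical_contact_network([b], exclude_bonded=0)
        fwd = perturbation(net_a, net_b, threshold=5.0)
        rev = perturbation(net_b, net_a, threshold=5.0)
        assert set(fwd.deltas) == set(rev.deltas)
        for k in fwd.deltas:
            assert fwd.deltas[k] == pytest.approx(-rev.deltas[k])

    def test_deterministic(self):
        spec = self._spec([0.0, 0.0, 6.0])
        a1, b1 = make_two_state_pair(spec, 50, seed=9)
        a2, b2 = make_two_state_pair(spec, 50, seed=9)
        assert np.array_equal(a1.coords, a2.coords)
        assert np.array_equal(b1.coords, b2.coords)


class TestConformerMixture:
    def _spec(self, weights=(0.8, 0.2), jitter=0.0):
        structure, ref = linear_structure(4, 3)
        other = ref.copy()
        other[structure.residue_atoms(3)] += [0.0, 0.0, 5.0]
        return ConformerMixtureSpec(
            structure=structure,
            conformers=(ref, other),
            weights=weights,
            jitter_sigma=jitter,
        )

    def test_weights_recovered(self):
        spec = self._spec()
        _, labels = make_conformer_mixture(spec, 10_000, seed=1)
        frac = np.mean(labels == 0)
        assert abs(frac - 0.8) < 0.02

    def test_zero_jitter_frames_equal_conformers(self):
        spec = self._spec()
        ens, labels = make_conformer_mixture(spec, 50, seed=2)
        for f in range(50):
            assert np.array_equal(ens.coords[f], spec.conformers[labels[f]])

    def test_deterministic(self):
        spec = self._spec(jitter=0.1)
        e1, l1 = make_conformer_mixture(spec, 100, seed=5)
        e2, l2 = make_conformer_mixture(spec, 100, seed=5)
        assert np.array_equal(e1.coords, e2.coords)
        assert np.array_equal(l1, l2)

    def test_needs_two_conformers(self):
        structure, ref = linear_structure(4, 3)
        with pytest.raises(SpecError):
            ConformerMixtureSpec(
                structure=structure, conformers=(ref,), weights=(1.0,)
            )

    def test_weights_must_sum_to_one(self):
        structure, ref = linear_structure(4, 3)
        with pytest.raises(SpecError):
            ConformerMixtureSpec(
                structure=structure,
                conformers=(ref, ref + 1),
                weights=(0.6, 0.6),
            )

    def test_separability_rule(self):
        spec = self._spec(jitter=0.1)
        # block shift of 5 A over 3 of 12 atoms -> rmsd 2.5; 2.5 > 0.3
        assert spec.is_separable()
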