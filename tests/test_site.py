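import numpy as np
import pytest
from scipy.stats import gaussian_kde

from mdcompare import (
    ConformerMixtureSpec,
    Ensemble,
    GaussianEnsembleSpec,
    SelectionSpec,
    linear_structure,
    make_conformer_mixture,
    make_gaussian_ensemble,
    orientation_occupancy,
    overlap_fraction,
    pair_distance_stats,
    site_rmsd_distribution,
)


def _site_sel():
    return SelectionSpec(residues=(1, 2), atom_class="all")


class TestSiteRmsdDistribution:
    def test_reference_repeated_degenerate_at_zero(self, small_structure):
        structure, ref = small_structure
        e = Ensemble(structure=structure, coords=np.stack([ref] * 10))
        dist = site_rmsd_distribution(e, ref, _site_sel(), fit_selection="heavy")
        assert np.allclose(dist.values, 0.0, atol=1e-10)
        assert len(dist.peaks) == 1
        assert dist.peaks[0] == pytest.approx(0.0, abs=1e-10)

    def test_planted_bimodality_detected(self):
        structure, ref = linear_structure(6, 3)
        far = ref.copy()
        site_atoms = np.concatenate(
            [structure.residue_atoms(1), structure.residue_atoms(2)]
        )
        far[site_atoms] += [0.0, 2.5, 0.0]
        spec = ConformerMixtureSpec(
            structure=structure,
            conformers=(ref, far),
            weights=(0.5, 0.5),
            jitter_sigma=0.15,
        )
        ens, _ = make_conformer_mixture(spec, 4000, seed=1)
        dist = site_rmsd_distribution(
            ens, ref, _site_sel(), fit_selection=SelectionSpec(
                residues=(0, 3, 4, 5), atom_class="all"
            ),
        )
        assert len(dist.peaks) == 2
        # second basin sits ~2.5 A from the reference on site atoms
        assert dist.peaks[1] == pytest.approx(2.5, abs=0.3)

    def test_unimodal_peak_matches_sampling_oracle(self, small_structure):
        structure, ref = small_structure
        sigma = 0.3
        spec = GaussianEnsembleSpec(
            structure=structure, reference_coords=ref, noise_sigma=sigma
        )
        ens = make_gaussian_ensemble(spec, 8000, seed=2)
        fit_sel = SelectionSpec(residues=(0, 3, 4, 5), atom_class="all")
        dist = site_rmsd_distribution(ens, ref, _site_sel(), fit_selection=fit_sel)
        assert len(dist.peaks) == 1
        # oracle: site RMSD of k atoms with iid N(0, sigma^2) coordinates
        # is sigma * sqrt(chi2_{3k}/k); estimate its density peak by
        # direct sampling (independent of the analysis code path)
        k = 6  # 2 residues x 3 atoms
        rng = np.random.default_rng(3)
        samples = sigma * np.sqrt(rng.chisquare(3 * k, size=100_000) / k)
        grid = np.linspace(0, samples.max(), 2000)
        oracle_peak = grid[np.argmax(gaussian_kde(samples)(grid))]
        assert dist.peaks[0] == pytest.approx(oracle_peak, rel=0.05)

    def test_density_integrates_to_one(self, noise_spec):
        ens = make_gaussian_ensemble(noise_spec, 500, seed=4)
        dist = site_rmsd_distribution(
            ens, noise_spec.reference_coords, _site_sel(), fit_selection="heavy"
        )
        integral = np.trapezoid(dist.density, dist.grid)
        assert integral == pytest.approx(1.0, abs=0.02)


class TestOverlapFraction:
    def _dist(self, noise_spec, n=300):
        ens = make_gaussian_ensemble(noise_spec, n, seed=5)
        return site_rmsd_distribution(
            ens, noise_spec.reference_coords, _site_sel(), fit_selection="heavy"
        )

    def test_cutoff_above_max_gives_one(self, noise_spec):
        dist = self._dist(noise_spec)
        frac, _ = overlap_fraction(dist, cutoff=dist.values.max() + 1)
        assert frac == 1.0

    def test_cutoff_below_min_gives_zero(self, noise_spec):
        dist = self._dist(noise_spec)
        frac, _ = overlap_fraction(dist, cutoff=dist.values.min() / 2)
        assert frac == 0.0

    def test_monotone_in_cutoff(self, noise_spec):
        dist = self._dist(noise_spec)
        cuts = np.linspace(0.01, dist.values.max() + 0.5, 25)
        fracs = [overlap_fraction(dist, c)[0] for c in cuts]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_planted_40_60_mixture_valley_cutoff(self):
        structure, ref = linear_structure(6, 3)
        far = ref.copy()
        site_atoms = np.concatenate(
            [structure.residue_atoms(1), structure.residue_atoms(2)]
        )
        far[site_atoms] += [0.0, 3.0, 0.0]
        spec = ConformerMixtureSpec(
            structure=structure,
            conformers=(ref, far),
            weights=(0.4, 0.6),
            jitter_sigma=0.15,
        )
        ens, _ = make_conformer_mixture(spec, 10_000, seed=6)
        dist = site_rmsd_distribution(
            ens, ref, _site_sel(),
            fit_selection=SelectionSpec(residues=(0, 3, 4, 5), atom_class="all"),
        )
        frac, cutoff = overlap_fraction(dist)  # default valley rule
        assert frac == pytest.approx(0.40, abs=0.02)
        assert 0 < cutoff < 3.0


class TestPairDistanceStats:
    def test_static_distance(self):
        structure, ref = linear_structure(4, 3, spacing=3.0)
        e = Ensemble(structure=structure, coords=np.stack([ref] * 5))
        stats = pair_distance_stats(
            e,
            SelectionSpec(residues=(0,), atom_class="heavy"),
            SelectionSpec(residues=(1,), atom_class="heavy"),
        )
        assert stats.mean == pytest.approx(3.0)
        assert stats.sd == pytest.approx(0.0)

    def test_two_frame_arithmetic(self):
        structure, ref = linear_structure(2, 1, spacing=2.0)
        far = ref.copy()
        far[1] += [2.0, 0, 0]
        e = Ensemble(structure=structure, coords=np.stack([ref, far]))
        stats = pair_distance_stats(
            e,
            SelectionSpec(residues=(0,)),
            SelectionSpec(residues=(1,)),
        )
        assert stats.mean == pytest.approx(3.0)
        assert stats.sd == pytest.approx(1.0)

    def test_min_distance_matches_exhaustive_oracle(self, noise_spec):
        e = make_gaussian_ensemble(noise_spec, 20, seed=7)
        ga = SelectionSpec(residues=(0, 1), atom_class="heavy")
        gb = SelectionSpec(residues=(4, 5), atom_class="heavy")
        stats = pair_distance_stats(e, ga, gb)
        ia = e.structure.select(ga)
        ib = e.structure.select(gb)
        for f in range(e.n_frames):
            best = min(
                np.linalg.norm(e.coords[f, a] - e.coords[f, b])
                for a in ia
                for b in ib
            )
            assert stats.values[f] == pytest.approx(best, abs=1e-12)

    def test_overlapping_groups_rejected(self, noise_spec):
        e = make_gaussian_ensemble(noise_spec, 5, seed=8)
        with pytest.raises(ValueError):
            pair_distance_stats(
                e,
                SelectionSpec(residues=(0, 1)),
                SelectionSpec(residues=(1, 2)),
            )

    def test_mean_sd_recompute_from_series(self, noise_spec):
        e = make_gaussian_ensemble(noise_spec, 50, seed=9)
        stats = pair_distance_stats(
            e, SelectionSpec(residues=(0,)), SelectionSpec(residues=(3,))
        )
        assert stats.mean == pytest.approx(float(np.mean(stats.values)), abs=1e-12)
        assert stats.sd == pytest.approx(float(np.std(stats.values)), abs=1e-12)


class TestOrientationOccupancy:
    def _two_basin(self, weights=(0.55, 0.45), n=10_000, seed=10):
        structure, ref = linear_structure(5, 3, spacing=4.0)
        left = ref.copy()
        left[structure.residue_atoms(2)] += [-1.2, 0.0, 0.0]
        right = ref.copy()
        right[structure.residue_atoms(2)] += [1.2, 0.0, 0.0]
        spec = ConformerMixtureSpec(
            structure=structure,
            conformers=(left, right),
            weights=weights,
            jitter_sigma=0.1,
        )
        ens, labels = make_conformer_mixture(spec, n, seed=seed)
        return ens, labels

    def test_always_partner_a(self):
        structure, ref = linear_structure(5, 3, spacing=4.0)
        shifted = ref.copy()
        shifted[structure.residue_atoms(2)] += [-1.5, 0.0, 0.0]
        e = Ensemble(structure=structure, coords=np.stack([shifted] * 10))
        split = orientation_occupancy(
            e,
            SelectionSpec(residues=(2,)),
            SelectionSpec(residues=(1,)),
            SelectionSpec(residues=(3,)),
            contact_cutoff=4.0,
        )
        assert split.fractions() == (100.0, 0.0)

    def test_planted_55_45_split(self):
        ens, labels = self._two_basin()
        split = orientation_occupancy(
            ens,
            SelectionSpec(residues=(2,)),
            SelectionSpec(residues=(1,)),
            SelectionSpec(residues=(3,)),
            contact_cutoff=4.0,
        )
        fa, fb = split.fractions()
        assert fa == pytest.approx(55.0, abs=2.0)
        assert fb == pytest.approx(45.0, abs=2.0)

    def test_all_beyond_cutoff_neither(self):
        structure, ref = linear_structure(5, 3, spacing=10.0)
        e = Ensemble(structure=structure, coords=np.stack([ref] * 4))
        split = orientation_occupancy(
            e,
            SelectionSpec(residues=(2,)),
            SelectionSpec(residues=(0,)),
            SelectionSpec(residues=(4,)),
            contact_cutoff=4.0,
        )
        assert split.fractions() == (0.0, 0.0)
        assert split.neither_fraction == 100.0

    def test_rigid_motion_invariance(self):
        ens, _ = self._two_basin(n=200, seed=11)
        theta = 0.9
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = Ensemble(
            structure=ens.structure, coords=ens.coords @ R.T + np.array([5.0, 1.0, 2.0])
        )
        args = (
            SelectionSpec(residues=(2,)),
            SelectionSpec(residues=(1,)),
            SelectionSpec(residues=(3,)),
        )
        s1 = orientation_occupancy(ens, *args, contact_cutoff=4.0)
        s2 = orientation_occupancy(moved, *args, contact_cutoff=4.0)
        assert np.array_equal(s1.assignment, s2.assignment)

    def test_overlapping_partners_rejected(self):
        ens, _ = self._two_basin(n=20, seed=12)
        with pytest.raises(ValueError):
            orientation_occupancy(
                ens,
                SelectionSpec(residues=(2,)),
                SelectionSpec(residues=(1, 3)),
                SelectionSpec(residues=(3,)),
                contact_cutoff=4.0,
            )
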