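"""Generator correctness: parcellation, time-course calibration, cohort
contrasts, and the diffusion signal model."""

import numpy as np
import pytest
from scipy import ndimage

from mconn import phantoms as ph
from mconn.image import ellipsoid_mask


class TestParcellation:
    def test_two_regions_partition_foreground(self):
        labels = ph.make_parcellation((8, 8, 8), 2, seed=0)
        mask = ellipsoid_mask((8, 8, 8))
        assert set(np.unique(labels[mask])) == {1, 2}
        assert np.all(labels[~mask] == 0)

    def test_681_regions_all_present(self):
        labels = ph.make_parcellation((20, 20, 20), 681, seed=1)
        present = np.unique(labels)
        assert len(present[present > 0]) == 681

    def test_regions_are_connected(self):
        labels = ph.make_parcellation((12, 12, 12), 30, seed=2)
        struct = ndimage.generate_binary_structure(3, 1)
        for lab in range(1, 31):
            _, n = ndimage.label(labels == lab, structure=struct)
            assert n == 1

    def test_deterministic(self):
        a = ph.make_parcellation((10, 10, 10), 7, seed=9)
        b = ph.make_parcellation((10, 10, 10), 7, seed=9)
        assert np.array_equal(a, b)

    def test_too_many_regions_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            ph.make_parcellation((4, 4, 4), 10_000, seed=0)


class TestTimecourses:
    def test_full_loading_gives_perfect_within_cluster_correlation(self):
        spec = ph.default_functional_spec(w=1.0, anticorr=0.0, n_timepoints=200)
        tcs = ph.simulate_timecourses(spec, np.random.default_rng(0))
        cl = np.array([c.cluster for c in spec.components])
        same = np.flatnonzero(cl == 1)
        r = np.corrcoef(tcs[:, same].T)
        assert np.allclose(r, 1.0, atol=1e-10)

    def test_within_cluster_correlation_calibrates_to_w(self, functional_spec):
        # invariant: empirical r -> w at long T
        spec = ph.default_functional_spec(
            n_timepoints=2000, anticorr=0.0, n_noise_components=0
        )
        vals = []
        for seed in range(5):
            tcs = ph.simulate_timecourses(spec, np.random.default_rng(seed))
            cl = np.array([c.cluster for c in spec.components])
            r = np.corrcoef(tcs.T)
            iu, ju = np.triu_indices(len(cl), k=1)
            vals.append(np.mean(r[iu, ju][cl[iu] == cl[ju]]))
        assert abs(np.mean(vals) - 0.6) < 0.03

    def test_monte_carlo_within_and_between_cluster_structure(self):
        # 4 clusters x 3 comps, w=0.6, independent clusters, T=300
        spec = ph.default_functional_spec(
            n_timepoints=300, anticorr=0.0, n_noise_components=0
        )
        cl = np.array([c.cluster for c in spec.components])
        iu, ju = np.triu_indices(len(cl), k=1)
        within, between = [], []
        for seed in range(20):
            tcs = ph.simulate_timecourses(spec, np.random.default_rng(seed))
            r = np.corrcoef(tcs.T)[iu, ju]
            within.append(np.mean(r[cl[iu] == cl[ju]]))
            between.append(np.mean(np.abs(r[cl[iu] != cl[ju]])))
        assert abs(np.mean(within) - 0.6) < 0.05
        assert np.mean(between) <= 0.1

    def test_anticorrelated_cluster_pair_is_negative(self, functional_spec):
        # clusters 3 and 4 carry factor correlation -0.5
        neg = []
        for seed in range(10):
            tcs = ph.simulate_timecourses(functional_spec, np.random.default_rng(seed))
            cl = np.array([c.cluster for c in functional_spec.components])
            a, b = np.flatnonzero(cl == 3), np.flatnonzero(cl == 4)
            r = np.corrcoef(tcs.T)
            neg.append(np.mean(r[np.ix_(a, b)]))
        assert np.mean(neg) < -0.1

    def test_non_positive_definite_factor_covariance_raises(self):
        spec = ph.default_functional_spec(anticorr=0.0)
        spec.inter_cluster_corr = {(1, 2): -0.9, (1, 3): -0.9, (2, 3): -0.9}
        with pytest.raises(ValueError, match="positive definite"):
            ph.simulate_timecourses(spec, np.random.default_rng(0))


class TestSimulateRsfmri:
    def test_seeded_determinism(self, noisy_spec):
        a, _ = ph.simulate_rsfmri(noisy_spec)
        b, _ = ph.simulate_rsfmri(noisy_spec)
        assert np.array_equal(a.data, b.data)

    def test_ground_truth_bookkeeping(self, noisy_spec):
        _, truth = ph.simulate_rsfmri(noisy_spec)
        n_signal = len(noisy_spec.components)
        n_total = n_signal + noisy_spec.n_noise_components
        assert truth.true_maps.shape[0] == n_total
        assert truth.true_timecourses.shape == (noisy_spec.n_timepoints, n_total)
        assert truth.true_noise_flags.sum() == noisy_spec.n_noise_components

    def test_sphere_outside_grid_rejected(self):
        spec = ph.FunctionalPhantomSpec(
            grid_shape=(8, 8, 8),
            components=[ph.ComponentSpec(center=(7.5, 4, 4), radius=2.0)],
        )
        with pytest.raises(ValueError, match="leaves the grid"):
            spec.validate()

    def test_noise_components_sit_on_mask_edge(self, noisy_spec):
        from mconn.image import mask_edge_shell

        _, truth = ph.simulate_rsfmri(noisy_spec)
        shell = mask_edge_shell(truth.mask)
        for k in np.flatnonzero(truth.true_noise_flags):
            support = truth.true_maps[k] > 0
            assert support.any() and np.all(shell[support])


class TestCohort:
    def test_zero_subjects_gives_empty_list(self, functional_spec):
        subjects, _ = ph.simulate_cohort(functional_spec, functional_spec, 0, seed=0)
        assert subjects == []

    def test_mismatched_component_lists_rejected(self, functional_spec):
        other = ph.default_functional_spec(
            n_clusters=3, comps_per_cluster=4, n_noise_components=0
        )
        with pytest.raises(ValueError, match="share component geometry"):
            ph.simulate_cohort(functional_spec, other, 2, seed=0)

    def test_identical_specs_give_null_group_difference(self, functional_spec):
        subjects, truth = ph.simulate_cohort(functional_spec, functional_spec, 5, seed=3)
        K = len(functional_spec.components)
        rs = [np.corrcoef(tc.T) for tc in truth.subject_timecourses]
        d = np.mean(rs[:5], axis=0) - np.mean(rs[5:], axis=0)
        iu, ju = np.triu_indices(K, k=1)
        assert abs(d[iu, ju].mean()) < 0.1

    def test_lowered_loading_reduces_within_cluster_correlation(self, functional_spec):
        hypo = ph.lowered_loading_spec(functional_spec, 1, 0.3)
        cl = np.array([c.cluster for c in functional_spec.components])
        members = np.flatnonzero(cl == 1)
        wins = 0
        for rep in range(20):
            subjects, truth = ph.simulate_cohort(functional_spec, hypo, 3, seed=rep)
            mean_r = []
            for grp in (slice(0, 3), slice(3, 6)):
                rs = [
                    np.corrcoef(tc[:, members].T)[np.triu_indices(3, k=1)].mean()
                    for tc in truth.subject_timecourses[grp]
                ]
                mean_r.append(np.mean(rs))
            wins += mean_r[0] > mean_r[1]
        assert wins >= 18


class TestSimulateDwi:
    def test_isotropic_background_closed_form(self, diffusion_spec):
        dwi, tensors, truth = ph.simulate_dwi(diffusion_spec)
        bg = ~truth.bundle_masks.any(axis=0)
        vox = tuple(np.argwhere(bg)[0])
        d_bg = diffusion_spec.background_diffusivity
        for m in range(len(diffusion_spec.b_values)):
            b = diffusion_spec.b_values[m]
            expected = diffusion_spec.s0 * np.exp(-b * d_bg)
            assert dwi.data[vox + (m,)] == pytest.approx(expected, rel=1e-12)

    def test_signal_attenuation_strongest_along_bundle_axis(self):
        spec = ph.default_diffusion_spec()
        gx = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        spec = ph.DiffusionPhantomSpec(
            grid_shape=spec.grid_shape,
            bundles=spec.bundles,
            b_values=np.array([0.0, 1000.0, 1000.0]),
            b_vectors=np.vstack([[0, 0, 0], gx]),
        )
        dwi, _, truth = ph.simulate_dwi(spec)
        vox = tuple(np.argwhere(truth.bundle_masks[0])[50])
        s_x, s_y = dwi.data[vox + (1,)], dwi.data[vox + (2,)]
        assert s_x < s_y

    def test_zero_noise_is_noiseless_and_deterministic(self, diffusion_spec):
        a, _, _ = ph.simulate_dwi(diffusion_spec)
        b, _, _ = ph.simulate_dwi(diffusion_spec)
        assert np.array_equal(a.data, b.data)

    def test_rician_noise_changes_signal_but_keeps_it_positive(self):
        spec = ph.default_diffusion_spec(noise_sigma=20.0)
        noisy, _, _ = ph.simulate_dwi(spec)
        clean, _, _ = ph.simulate_dwi(ph.default_diffusion_spec())
        assert not np.array_equal(noisy.data, clean.data)
        assert np.all(noisy.data >= 0)

    def test_missing_b0_rejected(self):
        spec = ph.DiffusionPhantomSpec(b_values=np.full(7, 1000.0))
        with pytest.raises(ValueError, match="b=0"):
            spec.validate()

    def test_arc_endpoints_must_be_planar(self):
        with pytest.raises(ValueError, match="exactly two coordinates"):
            ph.BundleSpec(
                geometry="arc", start=(1, 1, 1), end=(5, 5, 5)
            ).validate()
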