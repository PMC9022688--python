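"""Tensor fitting, FA, probabilistic tracking, and connectome counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mconn import phantoms as ph
from mconn import tract


class TestFractionalAnisotropy:
    @pytest.mark.parametrize(
        "evals,expected",
        [
            ((1.0, 1.0, 1.0), 0.0),
            ((1.0, 0.0, 0.0), 1.0),
            ((2.0, 1.0, 1.0), 0.408248290463863),  # sqrt(1/6), hand evaluation
            ((0.0, 0.0, 0.0), 0.0),
        ],
    )
    def test_closed_forms(self, evals, expected):
        assert tract.fractional_anisotropy(*evals) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        l1=st.floats(0.1, 10), l2=st.floats(0.1, 10), l3=st.floats(0.1, 10),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, l1, l2, l3, c):
        fa = tract.fractional_anisotropy(l1, l2, l3)
        fa_scaled = tract.fractional_anisotropy(c * l1, c * l2, c * l3)
        assert fa_scaled == pytest.approx(fa, abs=1e-9)
        assert 0.0 <= fa <= 1.0 + 1e-12


class TestFitTensor:
    def test_noiseless_roundtrip(self, diffusion_spec):
        dwi, tensors, _ = ph.simulate_dwi(diffusion_spec)
        tf = tract.fit_tensor(dwi)
        assert np.abs(tf.tensors - tensors).max() < 1e-6
        assert np.abs(tf.s0 - diffusion_spec.s0).max() < 1e-6

    def test_isotropic_voxels_have_zero_fa(self, diffusion_spec):
        dwi, _, truth = ph.simulate_dwi(diffusion_spec)
        tf = tract.fit_tensor(dwi)
        bg = ~truth.bundle_masks.any(axis=0)
        assert np.abs(tf.fa[bg]).max() < 1e-6
        ev = tf.evals[bg]
        assert np.allclose(ev[:, 0], ev[:, 2], atol=1e-9)

    def test_b0_only_rejected(self):
        dwi = ph.DWIImage(
            data=np.ones((4, 4, 4, 3)),
            b_values=np.zeros(3),
            b_vectors=np.zeros((3, 3)),
        )
        with pytest.raises(ValueError, match="6 nonzero-b"):
            tract.fit_tensor(dwi)

    def test_nonpositive_samples_dropped(self, diffusion_spec):
        dwi, tensors, _ = ph.simulate_dwi(diffusion_spec)
        data = dwi.data.copy()
        data[5, 5, 5, 3] = -1.0                # one corrupted measurement
        dwi2 = ph.DWIImage(data=data, b_values=dwi.b_values, b_vectors=dwi.b_vectors)
        tf = tract.fit_tensor(dwi2)
        assert tf.mask[5, 5, 5]
        assert np.abs(tf.tensors[5, 5, 5] - tensors[5, 5, 5]).max() < 1e-3

    def test_voxel_with_too_few_measurements_invalid(self):
        spec = ph.DiffusionPhantomSpec(
            grid_shape=(3, 3, 3),
            b_values=np.array([0.0] + [1000.0] * 6),
        )
        dwi, _, _ = ph.simulate_dwi(spec)
        data = dwi.data.copy()
        data[1, 1, 1, :3] = 0.0                # only 4 usable left
        dwi2 = ph.DWIImage(data=data, b_values=dwi.b_values, b_vectors=dwi.b_vectors)
        tf = tract.fit_tensor(dwi2)
        assert not tf.mask[1, 1, 1]
        assert tf.fa[1, 1, 1] == 0.0


@pytest.fixture(scope="module")
def fitted(diffusion_spec):
    dwi, _, truth = ph.simulate_dwi(diffusion_spec)
    return tract.fit_tensor(dwi), truth


class TestTracking:
    def test_deterministic_given_seed(self, fitted):
        tf, truth = fitted
        seeds = truth.bundle_masks[0] & (tf.fa >= 0.15)
        p = tract.TrackingParams(n_samples_per_seed=2)
        a = tract.track_probabilistic(tf, seeds, p, seed=4)
        b = tract.track_probabilistic(tf, seeds, p, seed=4)
        assert len(a) == len(b)
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))

    def test_low_fa_seed_stops_immediately(self, fitted):
        tf, truth = fitted
        bg = ~truth.bundle_masks.any(axis=0)
        seeds = np.zeros_like(bg)
        seeds[tuple(np.argwhere(bg & tf.mask)[0])] = True
        sl = tract.track_probabilistic(
            tf, seeds, tract.TrackingParams(n_samples_per_seed=3), seed=0
        )
        assert all(len(s) == 2 for s in sl.streamlines)
        assert all(r == ("low_fa", "low_fa") for r in sl.termination_reasons)

    def test_angle_limit_respected(self, fitted):
        tf, truth = fitted
        seeds = truth.bundle_masks[0] & (tf.fa >= 0.15)
        p = tract.TrackingParams(n_samples_per_seed=2, angle_limit_deg=45.0,
                                 dispersion_kappa=20.0)
        sl = tract.track_probabilistic(tf, seeds, p, seed=1)
        cos_lim = np.cos(np.deg2rad(p.angle_limit_deg))
        for line in sl.streamlines:
            if len(line) < 3:
                continue
            seg = np.diff(line, axis=0)
            seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
            cosang = (seg[:-1] * seg[1:]).sum(axis=1)
            assert np.all(cosang >= cos_lim - 1e-9)

    def test_empty_seed_mask_rejected(self, fitted):
        tf, _ = fitted
        with pytest.raises(ValueError, match="empty"):
            tract.track_probabilistic(tf, np.zeros_like(tf.mask))

    def test_straight_bundle_connects_end_to_end(self, fitted):
        tf, truth = fitted
        labels = truth.endpoint_labels
        seeds = (labels == 1) & truth.bundle_masks[0] & (tf.fa >= 0.15)
        p = tract.TrackingParams(n_samples_per_seed=10, dispersion_kappa=400.0)
        sl = tract.track_probabilistic(tf, seeds, p, seed=2)
        conn = tract.build_connectome(sl, labels)
        rate = conn.counts[0, 1] / len(sl)
        assert rate >= 0.95


class TestConnectome:
    def test_no_streamlines_gives_zero_matrix(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, 0] = 1
        labels[3, 3, 3] = 2
        sl = tract.StreamlineSet(
            streamlines=[], seed_voxels=[], termination_reasons=[],
            affine=np.eye(4),
        )
        conn = tract.build_connectome(sl, labels)
        assert conn.counts.sum() == 0

    def test_counts_and_log_weights(self, diffusion_spec):
        dwi, _, truth = ph.simulate_dwi(diffusion_spec)
        tf = tract.fit_tensor(dwi)
        seeds = truth.bundle_masks[0] & (tf.fa >= 0.15)
        sl = tract.track_probabilistic(
            tf, seeds, tract.TrackingParams(n_samples_per_seed=3,
                                            dispersion_kappa=300.0), seed=0
        )
        conn = tract.build_connectome(sl, truth.endpoint_labels)
        assert np.array_equal(conn.counts, conn.counts.T)
        assert np.all(np.diag(conn.counts) == 0)
        assert conn.counts[0, 1] + conn.n_ignored == len(sl)
        assert np.allclose(conn.weights, np.log1p(conn.counts))

    def test_many_region_parcellation_shape(self):
        labels = ph.make_parcellation((20, 20, 20), 681, seed=0)
        line = np.array([[1.0, 10.0, 10.0], [18.0, 10.0, 10.0]])
        sl = tract.StreamlineSet(
            streamlines=[line], seed_voxels=[(1, 10, 10)],
            termination_reasons=[("max_steps", "max_steps")], affine=np.eye(4),
        )
        conn = tract.build_connectome(sl, labels)
        assert conn.counts.shape == (681, 681)
        assert conn.counts.sum() in (0, 2)     # one streamline, symmetric

    def test_arc_bundle_connects_far_more_often_than_background(self):
        # quarter-arc phantom end-to-end rate vs straight-phantom false
        # connections to an off-bundle region pair
        arc = ph.DiffusionPhantomSpec(
            grid_shape=(24, 24, 10),
            bundles=[ph.BundleSpec(geometry="arc", start=(4.0, 18.0, 4.5),
                                   end=(18.0, 4.0, 4.5), radius=2.0)],
        )
        dwi, _, truth = ph.simulate_dwi(arc)
        tf = tract.fit_tensor(dwi)
        seeds = truth.bundle_masks[0] & (tf.fa >= 0.15)
        sl = tract.track_probabilistic(
            tf, seeds, tract.TrackingParams(n_samples_per_seed=3,
                                            dispersion_kappa=300.0), seed=0
        )
        conn = tract.build_connectome(sl, truth.endpoint_labels)
        arc_rate = conn.counts[0, 1] / len(sl)

        straight = ph.default_diffusion_spec()
        dwi2, _, truth2 = ph.simulate_dwi(straight)
        tf2 = tract.fit_tensor(dwi2)
        # off-bundle label pair: spheres away from the bundle ends
        labels2 = np.zeros(tf2.fa.shape, dtype=int)
        labels2[2:5, 1:4, 1:4] = 1
        labels2[-5:-2, -4:-1, -4:-1] = 2
        seeds2 = truth2.bundle_masks[0] & (tf2.fa >= 0.15)
        sl2 = tract.track_probabilistic(
            tf2, seeds2, tract.TrackingParams(n_samples_per_seed=3,
                                              dispersion_kappa=300.0), seed=0
        )
        conn2 = tract.build_connectome(sl2, labels2)
        false_rate = conn2.counts[0, 1] / len(sl2)
        assert arc_rate >= 10 * max(false_rate, 1e-9)


class TestVoxelwiseFACompare:
    def test_identical_groups_zero_t(self, diffusion_spec):
        # the same two subjects duplicated into both groups: equal means,
        # nonzero within-group variance -> t exactly 0
        fas = []
        for i in range(2):
            dwi, _, _ = ph.simulate_dwi(
                ph.default_diffusion_spec(noise_sigma=20.0, seed=i)
            )
            fas.append(tract.fit_tensor(dwi).fa)
        mask = np.ones(fas[0].shape, dtype=bool)
        res = tract.voxelwise_fa_compare(fas, fas, mask)
        assert np.abs(res.t_map).max() < 1e-10
        assert not res.rejected.any()

    def test_single_subject_group_rejected(self, diffusion_spec):
        fa = np.zeros((4, 4, 4))
        with pytest.raises(ValueError, match="at least 2"):
            tract.voxelwise_fa_compare([fa], [fa, fa], np.ones_like(fa, dtype=bool))

    def test_planted_fa_reduction_detected(self):
        fa_a, fa_b = [], []
        for i in range(8):
            sp = ph.default_diffusion_spec(noise_sigma=20.0, seed=i)
            fa_a.append(tract.fit_tensor(ph.simulate_dwi(sp)[0]).fa)
        for i in range(8):
            sp = ph.default_diffusion_spec(noise_sigma=20.0,
                                           radial_diffusivity=0.5e-3, seed=100 + i)
            fa_b.append(tract.fit_tensor(ph.simulate_dwi(sp)[0]).fa)
        bundle = ph.simulate_dwi(ph.default_diffusion_spec())[2].bundle_masks[0]
        mask = np.ones(bundle.shape, dtype=bool)
        res = tract.voxelwise_fa_compare(fa_a, fa_b, mask, alpha=0.05)
        assert res.rejected[bundle].mean() >= 0.8
        assert res.rejected[~bundle].mean() <= 0.02
        assert res.t_map[bundle].mean() > 0    # shams higher FA
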