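import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pkquant as pq
from pkquant.svca import (BRAIN_CLASSES, SVCAOptions,
                          align_classes, estimate_classes,
                          extract_reference_svca4, smooth_voxels,
                          svca_weights)

from .oracles import simplex_grid_nnls


class TestSmoothing:
    def _grid_dataset(self, schedule, shape=(9, 9, 9)):
        n = int(np.prod(shape))
        mat = np.zeros((n, schedule.n_frames))
        return pq.VoxelDataset(mat, schedule, voxel_size_mm=(2, 2, 2),
                               grid_shape=shape)

    def test_fwhm_zero_is_identity(self, schedule):
        vox = self._grid_dataset(schedule)
        assert smooth_voxels(vox, 0.0) is vox

    def test_delta_spreads_to_discrete_gaussian(self, schedule):
        vox = self._grid_dataset(schedule)
        img = vox.voxel_tacs.reshape(9, 9, 9, -1)
        img[4, 4, 4, 0] = 1.0
        sm = smooth_voxels(vox, 4.0)
        out = sm.voxel_tacs.reshape(9, 9, 9, -1)[..., 0]
        # mass conserved (kernel support well inside the grid)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        # profile matches the analytic discrete Gaussian, sigma = FWHM/2.355/2mm
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2))) / 2.0
        x = np.arange(9) - 4.0
        from scipy.ndimage import gaussian_filter1d
        delta = np.zeros(9)
        delta[4] = 1.0
        expect1d = gaussian_filter1d(delta, sigma, mode="constant")
        np.testing.assert_allclose(out[:, 4, 4],
                                   expect1d * out[4, 4, 4] / expect1d[4],
                                   rtol=1e-6, atol=1e-12)
        assert sigma == pytest.approx(0.85, abs=0.005)

    def test_constant_image_unchanged_in_interior(self, schedule):
        vox = self._grid_dataset(schedule)
        vox.voxel_tacs[:] = 3.0
        sm = smooth_voxels(vox, 4.0)
        out = sm.voxel_tacs.reshape(9, 9, 9, -1)
        assert out[4, 4, 4, 0] == pytest.approx(3.0, rel=1e-6)

    def test_no_grid_warns_and_passes_through(self, schedule):
        vox = pq.VoxelDataset(np.ones((5, schedule.n_frames)), schedule)
        with pytest.warns(UserWarning, match="smoothing skipped"):
            out = smooth_voxels(vox, 4.0)
        np.testing.assert_array_equal(out.voxel_tacs, vox.voxel_tacs)


class TestAlignClasses:
    def test_identity_on_matching_schedule(self, classes, schedule):
        out = align_classes(classes, schedule, drop_background=False)
        np.testing.assert_allclose(out.curves, classes.curves, rtol=1e-12)

    def test_background_frame_dropped_then_identity(self, blood, schedule):
        with_bg = pq.make_population_class_set(blood, schedule,
                                               with_background_frame=True)
        assert with_bg.schedule.n_frames == schedule.n_frames + 1
        out = align_classes(with_bg, schedule, drop_background=True)
        plain = pq.make_population_class_set(blood, schedule)
        np.testing.assert_allclose(out.curves, plain.curves, rtol=1e-6)

    def test_resampled_curves_have_unit_area(self, classes):
        target = pq.FrameSchedule(np.arange(0.0, 60.0, 3.0),
                                  np.arange(3.0, 63.0, 3.0))
        out = align_classes(classes, target)
        areas = out.curves @ target.durations
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_extrapolation_rejected(self, classes):
        target = pq.FrameSchedule([0.0, 60.0], [60.0, 120.0])
        with pytest.raises(ValueError, match="beyond"):
            align_classes(classes, target)


class TestWeights:
    def test_pure_class_voxel_gets_unit_weight(self, classes, schedule):
        for k in range(classes.n_classes):
            vox = pq.VoxelDataset(7.3 * classes.curves[[k]], schedule)
            w, flagged = svca_weights(vox, classes)
            expect = np.zeros(classes.n_classes)
            expect[k] = 1.0
            np.testing.assert_allclose(w[0], expect, atol=1e-9)

    def test_mixture_recovered_and_matches_grid_oracle(self, classes,
                                                       schedule):
        mix = 0.6 * classes.curves[0] + 0.4 * classes.curves[2]
        vox = pq.VoxelDataset(mix[None, :] * 3.0, schedule)
        w, _ = svca_weights(vox, classes)
        np.testing.assert_allclose(w[0], [0.6, 0, 0.4, 0], atol=1e-6)
        sq = np.sqrt(schedule.durations)
        A = (classes.curves * sq).T
        area = mix @ schedule.durations
        oracle = simplex_grid_nnls(A, (mix / area) * sq, step=0.01)
        assert np.max(np.abs(w[0] - oracle)) <= 0.01 + 1e-9

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_weights_scale_invariant(self, classes, scale):
        mix = 0.5 * classes.curves[1] + 0.5 * classes.curves[3]
        w1, _ = svca_weights(pq.VoxelDataset(mix[None, :], classes.schedule),
                             classes)
        wc, _ = svca_weights(
            pq.VoxelDataset(scale * mix[None, :], classes.schedule), classes)
        np.testing.assert_allclose(w1, wc, atol=1e-9)

    def test_zero_activity_voxel_flagged(self, classes, schedule):
        mat = np.vstack([classes.curves[0], np.zeros(schedule.n_frames)])
        w, flagged = svca_weights(pq.VoxelDataset(mat, schedule), classes)
        assert flagged.tolist() == [False, True]
        assert np.all(w[1] == 0)


class TestReferenceExtraction:
    def test_pure_low_binding_dataset_gives_mean_tac(self, classes, schedule):
        rng = np.random.default_rng(1)
        amps = rng.uniform(1, 5, 8)
        mat = amps[:, None] * classes.curves[1]
        ref = extract_reference_svca4(pq.VoxelDataset(mat, schedule), classes,
                                      SVCAOptions(smoothing_fwhm_mm=0))
        np.testing.assert_allclose(ref.values, mat.mean(axis=0), rtol=1e-9)

    def test_noiseless_mixed_dataset_reference_matches_class(self, classes):
        ds, _ = pq.gen_voxel_dataset(classes, [0.3, 0.4, 0.25, 0.05], 300,
                                     noise=pq.NoiseModel(sc=0), seed=3,
                                     spatial_arrangement="random")
        ref = extract_reference_svca4(ds, classes,
                                      SVCAOptions(smoothing_fwhm_mm=0))
        low = classes.curves[classes.class_names.index("gm_low_binding")]
        assert np.corrcoef(ref.values, low)[0, 1] >= 0.999

    def test_no_low_binding_voxels_rejected(self, classes, schedule):
        mat = np.tile(classes.curves[0], (6, 1))
        with pytest.raises(ValueError, match="reference class"):
            extract_reference_svca4(pq.VoxelDataset(mat, schedule), classes,
                                    SVCAOptions(smoothing_fwhm_mm=0))

    def test_six_class_set_restricted_to_brain_classes(self, blood, schedule):
        six = pq.make_population_class_set(blood, schedule, six_class=True)
        assert six.n_classes == 6
        ds, _ = pq.gen_voxel_dataset(
            six.subset(BRAIN_CLASSES), [0.3, 0.4, 0.25, 0.05], 100,
            noise=pq.NoiseModel(sc=0), seed=4, spatial_arrangement="random")
        ref = extract_reference_svca4(ds, six,
                                      SVCAOptions(smoothing_fwhm_mm=0))
        low = six.curves[six.class_names.index("gm_low_binding")]
        assert np.corrcoef(ref.values, low)[0, 1] >= 0.999


class TestEstimateClasses:
    def test_recovers_generating_classes_noiselessly(self, classes):
        ds, truth = pq.gen_voxel_dataset(classes, [0.25] * 4, 100,
                                         noise=pq.NoiseModel(sc=0), seed=6,
                                         spatial_arrangement="random")
        est = estimate_classes(ds, truth["label"].to_numpy())
        for name in classes.class_names:
            i, j = est.class_names.index(name), classes.class_names.index(name)
            np.testing.assert_allclose(est.curves[i], classes.curves[j],
                                       atol=1e-9)

    def test_missing_label_rejected(self, classes, schedule):
        vox = pq.VoxelDataset(classes.curves[:2], schedule)
        with pytest.raises(ValueError):
            estimate_classes(vox, np.array(["a"]))

    def test_class_estimate_converges_with_n(self, classes):
        """RMSE of the class-mean estimate halves when n quadruples."""
        def rmse(n, seed):
            ds, truth = pq.gen_voxel_dataset(
                classes, [1.0, 0, 0, 0], n, noise=pq.NoiseModel(sc=0.3),
                seed=seed, spatial_arrangement="random")
            est = estimate_classes(ds, truth["label"].to_numpy())
            return np.sqrt(np.mean((est.curves[0] - classes.curves[0]) ** 2))

        small = np.mean([rmse(50, s) for s in range(8)])
        large = np.mean([rmse(200, s + 100) for s in range(8)])
        assert large < 0.7 * small
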