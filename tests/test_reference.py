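import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import pkquant as pq
from pkquant.reference import (SRTMParams, SRTMvParams, extract_idif,
                               fit_srtm, fit_srtmv, simulate_srtm)
from pkquant.simulate import CLASS_KINETICS

from .oracles import srtm_midpoint_values_quadrature


@pytest.fixture(scope="module")
def ref_tac(blood, schedule):
    return pq.simulate_2tcm(CLASS_KINETICS["gm_low_binding"], blood, schedule)


class TestSRTMForward:
    def test_identity_when_r1_one_bp_zero(self, ref_tac):
        out = simulate_srtm(SRTMParams(1.0, 0.3, 0.0), ref_tac)
        np.testing.assert_allclose(out.values, ref_tac.values, rtol=1e-12)

    def test_large_bp_limit_is_r1_ref_plus_k2_integral(self, ref_tac):
        p = SRTMParams(1.1, 0.3, 1e6)
        out = simulate_srtm(p, ref_tac)
        mids = ref_tac.schedule.midpoints
        t = np.concatenate(([0.0], mids))
        cr = np.concatenate(([0.0], ref_tac.values))
        integral = cumulative_trapezoid(cr, t)[-len(mids):]
        expect = 1.1 * ref_tac.values + 0.3 * integral
        np.testing.assert_allclose(out.values, expect, rtol=2e-3)

    def test_matches_quadrature_oracle(self, ref_tac):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = SRTMParams(rng.uniform(0.5, 2.0), rng.uniform(0.05, 0.6),
                           rng.uniform(-0.5, 3.0))
            mine = simulate_srtm(p, ref_tac).values
            oracle = srtm_midpoint_values_quadrature(p, ref_tac)
            scale = np.max(np.abs(oracle))
            assert np.max(np.abs(mine - oracle)) / scale < 1e-3

    def test_bp_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            SRTMParams(1.0, 0.3, -1.5)


class TestSRTMFit:
    def test_noiseless_recovery(self, ref_tac):
        p = SRTMParams(1.2, 0.3, 0.5)
        target = simulate_srtm(p, ref_tac)
        fr = fit_srtm(target, ref_tac, n_starts=50, n_refine=5, seed=1)
        np.testing.assert_allclose(
            [fr.params.R1, fr.params.k2, fr.params.bp],
            [p.R1, p.k2, p.bp], rtol=1e-3)

    def test_target_equals_reference(self, ref_tac):
        fr = fit_srtm(ref_tac, ref_tac, n_starts=50, n_refine=5, seed=1)
        assert fr.params.bp == pytest.approx(0.0, abs=1e-4)
        assert fr.params.R1 == pytest.approx(1.0, abs=1e-4)
        assert fr.has_flag("k2-weakly-identified")

    def test_noisy_low_binding_estimates_straddle_truth(self, ref_tac,
                                                        schedule):
        """On noisy low-binding data bp estimates scatter around truth."""
        p = SRTMParams(1.0, 0.35, 0.25)
        clean = simulate_srtm(p, ref_tac)
        nm = pq.NoiseModel(sc=0.02)
        rng = np.random.default_rng(0)
        est = []
        for _ in range(20):
            noisy = pq.TAC(schedule, nm.apply(clean.values, schedule, rng))
            fr = fit_srtm(noisy, ref_tac, n_starts=40, n_refine=4, seed=2)
            est.append(fr.params.bp)
        est = np.asarray(est)
        assert est.min() < p.bp < est.max()
        # tolerance frozen from the recovery harness at this noise level
        assert abs(np.median(est) - p.bp) < 0.1

    def test_zero_reference_rejected(self, schedule, ref_tac):
        zero = pq.TAC(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(Exception, match="zero"):
            fit_srtm(ref_tac, zero)


@pytest.fixture(scope="module")
def blood_tac(blood, schedule):
    from pkquant._grid import dense_grid, frame_average
    t = dense_grid(schedule)
    wb = blood.interp(t, "whole_blood", warn_extrapolate=False)
    return pq.TAC(schedule, frame_average(t, wb, schedule), region_label="blood")


class TestSRTMv:
    def test_reduces_to_srtm_when_truth_has_no_blood(self, ref_tac, blood_tac):
        target = simulate_srtm(SRTMParams(1.2, 0.3, 0.5), ref_tac)
        a = fit_srtmv(target, ref_tac, blood_tac, n_starts=60, n_refine=5,
                      seed=1)
        b = fit_srtm(target, ref_tac, n_starts=60, n_refine=5, seed=1)
        assert a.params.vB_t == pytest.approx(0.0, abs=1e-6)
        assert a.params.vB_r == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(
            [a.params.R1, a.params.k2, a.params.bp],
            [b.params.R1, b.params.k2, b.params.bp], rtol=1e-5)

    def test_recovers_blood_volume_fractions(self, ref_tac, blood_tac):
        vb_t, vb_r = 0.05, 0.03
        srtm_vals = simulate_srtm(SRTMParams(1.2, 0.3, 0.5), ref_tac).values
        target = pq.TAC(ref_tac.schedule,
                        (1 - vb_t) * srtm_vals + vb_t * blood_tac.values)
        ref_obs = pq.TAC(ref_tac.schedule,
                         (1 - vb_r) * ref_tac.values + vb_r * blood_tac.values)
        fr = fit_srtmv(target, ref_obs, blood_tac, n_starts=80, n_refine=6,
                       seed=1)
        np.testing.assert_allclose(
            [fr.params.R1, fr.params.k2, fr.params.bp,
             fr.params.vB_t, fr.params.vB_r],
            [1.2, 0.3, 0.5, vb_t, vb_r], rtol=1e-2)

    def test_zero_blood_curve_falls_back_to_srtm(self, ref_tac, schedule):
        target = simulate_srtm(SRTMParams(1.1, 0.3, 0.4), ref_tac)
        zero = pq.TAC(schedule, np.zeros(schedule.n_frames))
        with pytest.warns(UserWarning, match="reduces to SRTM"):
            a = fit_srtmv(target, ref_tac, zero, n_starts=40, n_refine=4,
                          seed=1)
        b = fit_srtm(target, ref_tac, n_starts=40, n_refine=4, seed=1)
        assert a.has_flag("zero-blood-curve")
        assert isinstance(a.params, SRTMvParams)
        assert (a.params.R1, a.params.k2, a.params.bp) == \
            (b.params.R1, b.params.k2, b.params.bp)


class TestIDIF:
    def test_spiked_voxels_selected(self, schedule):
        rng = np.random.default_rng(0)
        mat = rng.random((50, schedule.n_frames)) * 0.1
        spiked = rng.choice(50, 10, replace=False)
        mat[spiked, 0] = 100.0  # first frame lies inside [0, 1] min
        vox = pq.VoxelDataset(mat, schedule)
        tac, info = extract_idif(vox, return_info=True)
        assert sorted(info["voxel_indices"]) == sorted(spiked)

    def test_identical_voxels_tie_break_by_index(self, schedule):
        mat = np.ones((30, schedule.n_frames))
        vox = pq.VoxelDataset(mat, schedule)
        tac, info = extract_idif(vox, return_info=True)
        assert info["voxel_indices"].tolist() == list(range(10))
        assert "selection-ties" in info["flags"]

    def test_blood_subpopulation_recovered(self, classes):
        ds, truth = pq.gen_voxel_dataset(
            classes, [0.3, 0.4, 0.2, 0.1], 200, noise=pq.NoiseModel(sc=0),
            seed=5, spatial_arrangement="random")
        tac = extract_idif(ds)
        blood_curve = classes.curves[classes.class_names.index("blood")]
        assert np.corrcoef(tac.values, blood_curve)[0, 1] > 0.99

    def test_too_few_masked_voxels_rejected(self, schedule):
        vox = pq.VoxelDataset(np.ones((5, schedule.n_frames)), schedule)
        with pytest.raises(ValueError, match="mask"):
            extract_idif(vox)

    def test_schedule_must_cover_first_minute(self):
        late = pq.FrameSchedule([5.0, 6.0], [6.0, 7.0])
        vox = pq.VoxelDataset(np.ones((20, 2)), late)
        with pytest.raises(ValueError, match="first minute"):
            extract_idif(vox)
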