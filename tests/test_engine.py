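"""Postprocessing chain: subtraction, filtering, resampling, AIF, deconvolution."""

import dataclasses

import numpy as np
import pytest

from perfx.engine import (AIFCurve, ConcentrationSeries, TimeSeries4D, deconvolve,
                          detect_aif, make_tissue_mask, nonlinear_filter,
                          register_frames, resample_1s, subtract_mask)
from perfx.phantom import AIR, SKULL, AIFModel, default_aif, tissue_curve


def _series(data, times=None, durations=None, n_mask=0, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(data, dtype=float)
    t = np.arange(data.shape[0], dtype=float) if times is None else np.asarray(times)
    d = np.full(data.shape[0], 0.5) if durations is None else np.asarray(durations)
    return TimeSeries4D(data=data, frame_times=t, durations=d, n_mask=n_mask,
                       spacing=spacing)


def _conc(curves: np.ndarray) -> ConcentrationSeries:
    """Pack (T, V) curves into a (T, V, 1, 1) concentration series."""
    T = curves.shape[0]
    return ConcentrationSeries(data=curves.reshape(T, -1, 1, 1),
                               times=np.arange(T, dtype=float),
                               spacing=(1.0, 1.0, 1.0))


class TestSubtractMask:
    def test_mask_run_subtraction_is_exact(self, series_fdctp_noiseless):
        out = subtract_mask(series_fdctp_noiseless)
        base = series_fdctp_noiseless.data[:2].mean(axis=0)
        assert out.n_frames == series_fdctp_noiseless.n_frames - 2
        for k in range(out.n_frames):
            assert np.array_equal(out.data[k],
                                  series_fdctp_noiseless.data[k + 2] - base)
        assert out.n_mask == 0

    def test_constant_series_subtracts_to_zero(self):
        s = _series(np.full((6, 4, 4, 2), 50.0), n_mask=2)
        out = subtract_mask(s)
        assert np.allclose(out.data, 0.0)

    def test_all_mask_frames_rejected(self):
        s = _series(np.zeros((3, 2, 2, 2)), n_mask=3)
        with pytest.raises(ValueError):
            subtract_mask(s)

    def test_prebolus_baseline_without_mask_frames(self, scene,
                                                   series_mdctp_noiseless):
        """With no mask runs the pre-bolus frames define the background, so a
        noiseless vessel curve is recovered exactly as rendered enhancement."""
        out = subtract_mask(series_mdctp_noiseless)
        assert out.n_frames == series_mdctp_noiseless.n_frames
        vox = tuple(np.argwhere(scene.vessel_mask)[0])
        rendered = series_mdctp_noiseless.data[(slice(None),) + vox]
        baseline = scene.baseline_hu[vox]
        assert np.allclose(out.data[(slice(None),) + vox], rendered - baseline,
                           atol=1e-9)


class TestNonlinearFilter:
    def test_constant_image_unchanged(self):
        s = _series(np.full((2, 6, 6, 6), 7.0))
        assert np.array_equal(nonlinear_filter(s).data, s.data)

    def test_single_voxel_impulse_removed(self):
        data = np.zeros((1, 7, 7, 7))
        data[0, 3, 3, 3] = 100.0
        out = nonlinear_filter(_series(data))
        assert out.data[0, 3, 3, 3] == 0.0

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(1, 8, 8, 6))
        out = nonlinear_filter(_series(data))
        for (i, j, k) in [(2, 3, 2), (4, 4, 3), (6, 2, 2)]:
            hood = data[0, i - 1:i + 2, j - 1:j + 2, k - 1:k + 2]
            assert out.data[0, i, j, k] == pytest.approx(np.median(hood))


class TestResample1s:
    def test_reproduces_samples_at_integer_knots(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 5, size=(8, 2, 2, 1))
        s = _series(vals, times=np.arange(8, dtype=float),
                    durations=np.zeros(8))  # centres at integers
        conc = resample_1s(s)
        assert np.allclose(conc.data, vals)

    def test_exact_on_cubic_polynomial(self):
        t = np.arange(0.0, 30.0, 1.6) + 0.25
        poly = 0.01 * t**3 - 0.3 * t**2 + 3 * t + 5
        s = _series(np.broadcast_to(poly[:, None, None, None],
                                    (t.size, 2, 2, 1)).copy(),
                    times=t - 0.25, durations=np.full(t.size, 0.5))
        conc = resample_1s(s)
        grid = conc.times
        inside = grid >= t[0]
        expected = 0.01 * grid**3 - 0.3 * grid**2 + 3 * grid + 5
        assert np.allclose(conc.data[inside, 0, 0, 0], expected[inside], atol=1e-9)

    def test_fdctp_sampling_recovers_gamma_variate(self, aif):
        """Sparse 6 s sampling + cubic spline stays close to the analytic
        bolus on interior points."""
        centres = np.arange(10) * 6.0 + 2.5
        vals = aif(centres)
        s = _series(vals.reshape(-1, 1, 1, 1), times=centres - 2.5,
                    durations=np.full(10, 5.0))
        conc = resample_1s(s)
        grid = conc.times
        peak_zone = (grid >= 14.5) & (grid <= 26.5)  # bolus peak between sweeps
        err_peak = np.abs(conc.data[peak_zone, 0, 0, 0] - aif(grid[peak_zone]))
        assert err_peak.max() < 0.25 * aif.peak_value
        washout = (grid >= 33.0) & (grid <= 50.0)
        err_tail = np.abs(conc.data[washout, 0, 0, 0] - aif(grid[washout]))
        assert err_tail.max() < 0.02 * aif.peak_value

    def test_linear_fallback_below_four_frames(self, caplog):
        s = _series(np.ones((3, 2, 2, 1)), times=np.array([0.0, 2.0, 4.0]),
                    durations=np.zeros(3))
        with caplog.at_level("WARNING"):
            conc = resample_1s(s)
        assert "linear" in caplog.text
        assert np.allclose(conc.data, 1.0)

    def test_grid_is_one_second_and_causal(self, series_fdctp_noiseless):
        conc = resample_1s(subtract_mask(series_fdctp_noiseless))
        assert np.allclose(np.diff(conc.times), 1.0)
        first_centre = subtract_mask(series_fdctp_noiseless).frame_centers[0]
        assert np.allclose(conc.data[conc.times < first_centre], 0.0)
        assert conc.data.min() >= 0.0


class TestTissueMask:
    def test_hu_window_excludes_air_and_bone(self, scene, series_mdctp):
        mask = make_tissue_mask(series_mdctp)
        assert not mask[scene.labels == AIR].any()
        assert not mask[scene.labels == SKULL].any()
        assert mask[scene.brain_mask].mean() > 0.95

    def test_vessel_cut_excludes_arterial_voxels(self, scene, series_mdctp):
        conc = resample_1s(nonlinear_filter(subtract_mask(series_mdctp)))
        mask = make_tissue_mask(series_mdctp, conc)
        # interior of the vessel cluster carries the undiluted bolus
        vx, vy, vz = np.argwhere(scene.vessel_mask).mean(axis=0).astype(int)
        assert not mask[vx, vy, vz]

    def test_empty_mask_rejected(self):
        s = _series(np.full((4, 3, 3, 3), -1000.0))
        with pytest.raises(ValueError):
            make_tissue_mask(s)


class TestDetectAIF:
    def test_selects_voxels_inside_vessel_cluster(self, scene, series_mdctp):
        conc = resample_1s(nonlinear_filter(subtract_mask(series_mdctp)))
        aif = detect_aif(conc)
        for v in aif.voxels:
            assert scene.vessel_mask[v]

    def test_two_identical_candidates_average_to_either(self, aif):
        t = np.arange(47.0)
        curve = aif(t)
        curves = np.stack([curve, curve, 0.1 * curve], axis=1)
        det = detect_aif(_conc(curves), floor=100.0, top_k=2)
        assert len(det.voxels) == 2
        assert np.allclose(det.values, curve)

    def test_low_amplitude_curves_raise(self, aif):
        t = np.arange(47.0)
        curves = (0.05 * aif(t))[:, None]
        with pytest.raises(ValueError, match="manually"):
            detect_aif(_conc(curves))


class TestDeconvolve:
    def _aifcurve(self, values):
        return AIFCurve(values=values, times=np.arange(len(values), dtype=float),
                        voxels=[(0, 0, 0)])

    def test_exact_recovery_from_discrete_convolution(self):
        """Forward-convolution oracle: with an untruncated inverse, CBF and
        Tmax come back exactly for delays across the clinical range."""
        aif_m = AIFModel.with_peak(200.0, t0=3.0)
        t = np.arange(64.0)
        a = aif_m(t)
        for d in (0, 2, 5, 9, 12):
            f, m = 0.01, 4.0
            k_true = np.zeros(t.size)
            k_true[d:] = f * np.exp(-(t[d:] - d) / m)
            c = np.convolve(a, k_true)[: t.size]
            maps = deconvolve(_conc(c[:, None]), self._aifcurve(a), psi=1e-8)
            assert maps.cbf[0, 0, 0] == pytest.approx(f, rel=1e-6)
            assert abs(maps.tmax[0, 0, 0] - d) <= 0.5

    def test_identity_curve_has_zero_tmax(self, aif):
        t = np.arange(47.0)
        a = aif(t)
        maps = deconvolve(_conc(a[:, None]), self._aifcurve(a))
        assert maps.tmax[0, 0, 0] <= 0.5

    def test_delay_pair_differs_by_eight_seconds(self, aif):
        t = np.arange(64.0)
        a = aif(t)
        c0 = tissue_curve(0.01, 4.0, 0.0, aif, t)
        c8 = tissue_curve(0.01, 4.0, 8.0, aif, t)
        maps = deconvolve(_conc(np.stack([c0, c8], axis=1)), self._aifcurve(a))
        diff = maps.tmax[1, 0, 0] - maps.tmax[0, 0, 0]
        assert diff == pytest.approx(8.0, abs=1.0)

    def test_uniform_delay_shifts_tmax_not_cbf(self, aif):
        """Delay insensitivity of the block-circulant formulation."""
        t = np.arange(64.0)
        a = aif(t)
        for d in (0.0, 4.0, 10.0):
            c = tissue_curve(0.01, 4.0, d, aif, t)
            maps = deconvolve(_conc(c[:, None]), self._aifcurve(a))
            base = deconvolve(_conc(tissue_curve(0.01, 4.0, 0.0, aif, t)[:, None]),
                              self._aifcurve(a))
            assert abs((maps.tmax[0, 0, 0] - base.tmax[0, 0, 0]) - d) <= 1.0
            assert abs(maps.cbf[0, 0, 0] / base.cbf[0, 0, 0] - 1.0) < 0.05

    def test_ttp_shifts_exactly_with_curve_shift(self, aif):
        t = np.arange(64.0)
        a = aif(t)
        c = tissue_curve(0.01, 4.0, 2.0, aif, t)
        shifted = np.roll(c, 5)
        shifted[:5] = 0.0
        maps = deconvolve(_conc(np.stack([c, shifted], axis=1)), self._aifcurve(a))
        assert maps.ttp[1, 0, 0] - maps.ttp[0, 0, 0] == pytest.approx(5.0)

    def test_mtt_is_cbv_over_cbf(self, maps_mdctp):
        m = maps_mdctp.mask & (maps_mdctp.cbf > 0)
        assert np.allclose(maps_mdctp.mtt[m],
                           maps_mdctp.cbv[m] / maps_mdctp.cbf[m])

    def test_zero_aif_rejected_and_dead_voxel_unmasked(self, aif):
        t = np.arange(47.0)
        a = aif(t)
        with pytest.raises(ValueError):
            deconvolve(_conc(a[:, None]), self._aifcurve(np.zeros_like(a)))
        maps = deconvolve(_conc(np.zeros((t.size, 1))), self._aifcurve(a))
        assert not maps.mask[0, 0, 0]
        assert maps.cbf[0, 0, 0] == 0.0

    def test_bit_identical_determinism(self, aif):
        t = np.arange(47.0)
        a = aif(t)
        c = tissue_curve(0.01, 4.0, 3.0, aif, t)
        m1 = deconvolve(_conc(c[:, None]), self._aifcurve(a))
        m2 = deconvolve(_conc(c[:, None]), self._aifcurve(a))
        assert np.array_equal(m1.tmax, m2.tmax)
        assert np.array_equal(m1.cbf, m2.cbf)


class TestRegistration:
    def test_motion_free_input_passes_through(self, series_mdctp_noiseless):
        sub = _series(series_mdctp_noiseless.data[:3].copy(),
                      times=series_mdctp_noiseless.frame_times[:3],
                      durations=series_mdctp_noiseless.durations[:3],
                      spacing=series_mdctp_noiseless.spacing)
        out = register_frames(sub)
        brain = np.abs(sub.data[0]) < 500  # skip air/skull extremes
        err = np.abs(out.data[1] - sub.data[1])[brain]
        assert np.median(err) < 1.0

    def test_recovers_injected_translation(self, series_mdctp_noiseless):
        """A 2-voxel shift on one frame is undone to within half a voxel."""
        sub = _series(series_mdctp_noiseless.data[:2].copy(),
                      times=series_mdctp_noiseless.frame_times[:2],
                      durations=series_mdctp_noiseless.durations[:2],
                      spacing=series_mdctp_noiseless.spacing)
        moved = np.roll(sub.data[1], 2, axis=0)
        shifted = dataclasses.replace(sub, data=np.stack([sub.data[0], moved]))
        out = register_frames(shifted)
        ref = sub.data[1]
        interior = (slice(4, -4),) * 3
        err_before = np.abs(moved[interior] - ref[interior]).mean()
        err_after = np.abs(out.data[1][interior] - ref[interior]).mean()
        assert err_after < 0.25 * err_before

    def test_single_frame_rejected(self, series_mdctp_noiseless):
        one = _series(series_mdctp_noiseless.data[:1],
                      times=series_mdctp_noiseless.frame_times[:1],
                      durations=series_mdctp_noiseless.durations[:1])
        with pytest.raises(ValueError):
            register_frames(one)


class TestEndToEndRecovery:
    def test_mdctp_noiseless_parameter_recovery(self, scene, truth,
                                                maps_mdctp_noiseless):
        maps = maps_mdctp_noiseless
        ext = truth.extent & maps.mask
        healthy = truth.brain & maps.mask & ~truth.extent
        err = np.median(maps.tmax[ext]) - np.median(truth.tmax[ext])
        assert abs(err) <= 1.5
        assert abs(np.median(maps.tmax[healthy])
                   - np.median(truth.tmax[healthy])) <= 1.5
        true_ratio = np.median(truth.cbf[ext]) / np.median(truth.cbf[healthy])
        rec_ratio = np.median(maps.cbf[ext]) / np.median(maps.cbf[healthy])
        assert abs(rec_ratio - true_ratio) <= 0.1

    def test_fdctp_noiseless_recovery_within_coarser_tolerance(self, truth,
                                                               maps_fdctp_noiseless):
        """Sparse sweeps widen the error band; the deficit stays visible."""
        maps = maps_fdctp_noiseless
        ext = truth.extent & maps.mask
        healthy = truth.brain & maps.mask & ~truth.extent
        assert abs(np.median(maps.tmax[ext])
                   - np.median(truth.tmax[ext])) <= 2.0
        assert abs(np.median(maps.tmax[healthy])
                   - np.median(truth.tmax[healthy])) <= 2.0
        true_ratio = np.median(truth.cbf[ext]) / np.median(truth.cbf[healthy])
        rec_ratio = np.median(maps.cbf[ext]) / np.median(maps.cbf[healthy])
        assert abs(rec_ratio - true_ratio) <= 0.15
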