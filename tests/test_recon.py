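"""PRF reconstruction chain: filtering, SVD combination, Eq.-style
phase-to-temperature conversion, drift handling, diagnostics."""

import numpy as np
import pytest

import prftherm as pt
from prftherm.constants import phase_per_degC
from prftherm.recon import _centered_window


class TestReconstructImages:
    def test_zero_pad_doubles_matrix(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64, 30)) + 1j * rng.normal(size=(64, 64, 30))
        out = pt.reconstruct_images(img, target_shape=(128, 128, 60))
        assert out.shape == (128, 128, 60)

    def test_linearity_zero_input(self):
        out = pt.reconstruct_images(np.zeros((8, 8, 8), complex),
                                    target_shape=(16, 16, 16))
        assert np.abs(out).max() == 0.0

    def test_parseval_energy(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(6, 8, 10)) + 1j * rng.normal(size=(6, 8, 10))
        out = pt.reconstruct_images(img, target_shape=(12, 16, 20),
                                    apodise=True)
        k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(img), norm="ortho"))
        w = (_centered_window(6)[:, None, None]
             * _centered_window(8)[None, :, None]
             * _centered_window(10)[None, None, :])
        e_img = np.sum(np.abs(out) ** 2)
        e_k = np.sum(np.abs(k * w) ** 2)
        assert abs(e_img - e_k) / e_k < 1e-9

    def test_target_smaller_than_input_rejected(self):
        with pytest.raises(ValueError):
            pt.reconstruct_images(np.zeros((8, 8, 8), complex),
                                  target_shape=(4, 8, 8))


class TestSvdCombination:
    def test_rank_one_phase_preserved(self):
        rng = np.random.default_rng(2)
        nc, ne, nr, nv = 16, 5, 6, 12
        coil = rng.normal(size=(nc,)) + 1j * rng.normal(size=(nc,))
        signal = np.exp(1j * rng.uniform(-0.3, 0.3, size=(ne, nr, nv))) \
            * rng.uniform(0.5, 2.0, size=(ne, nr, nv))
        data = coil[:, None, None, None] * signal[None]
        combined = pt.combine_coils_svd(data.reshape(nc, ne, nr, nv, 1, 1))
        combined = combined.reshape(ne, nr, nv)
        dphi_true = np.angle(signal[:, 1:] * np.conj(signal[:, :1]))
        dphi_comb = np.angle(combined[:, 1:] * np.conj(combined[:, :1]))
        np.testing.assert_allclose(dphi_comb, dphi_true, atol=1e-9)

    def test_single_channel_identity_up_to_constant(self):
        rng = np.random.default_rng(3)
        data = (rng.normal(size=(1, 2, 3, 4, 1, 1))
                + 1j * rng.normal(size=(1, 2, 3, 4, 1, 1)))
        combined = pt.combine_coils_svd(data)
        ratio = combined / data[0]
        np.testing.assert_allclose(np.abs(ratio), np.abs(ratio).flat[0],
                                   rtol=1e-9)

    def test_projection_magnitude_bound(self):
        rng = np.random.default_rng(4)
        nc = 16
        coil = rng.normal(size=(nc,)) + 1j * rng.normal(size=(nc,))
        signal = rng.uniform(0.5, 1.5, size=(3, 4, 5)) * np.exp(
            1j * rng.uniform(0, 1, size=(3, 4, 5)))
        data = coil[:, None, None, None] * signal[None]
        combined = pt.combine_coils_svd(data.reshape(nc, 3, 4, 5, 1, 1))
        best_single = np.max(np.abs(data), axis=0)
        assert np.all(np.abs(combined.reshape(3, 4, 5))
                      >= best_single / np.sqrt(nc) - 1e-12)

    def test_all_zero_voxel_combines_to_zero(self):
        data = np.zeros((4, 2, 3, 2, 1, 1), complex)
        combined = pt.combine_coils_svd(data)
        assert np.abs(combined).max() == 0.0


class TestFirstEchoPhasing:
    def test_common_mode_offset_removed(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(3, 4, 10)) + 1j * rng.normal(size=(3, 4, 10))
        offset = np.exp(1j * 0.7)
        phased_plain, _ = pt.phase_with_first_echo(base)
        phased_off, _ = pt.phase_with_first_echo(base * offset)
        np.testing.assert_allclose(phased_off, phased_plain, rtol=1e-12)

    def test_thermal_phase_becomes_te_difference(self):
        te = np.array([1.44, 3.62, 5.5, 7.38, 9.26]) * 1e-3
        k = phase_per_degC(1.0)  # rad per degC per second of TE
        dT = 2.0
        series = np.exp(1j * k * dT * te)[:, None, None]
        phased, valid = pt.phase_with_first_echo(series)
        assert valid.all()
        np.testing.assert_allclose(np.angle(phased[:, 0, 0]),
                                   k * dT * (te[1:] - te[0]), atol=1e-12)

    def test_zero_signal_flagged(self):
        series = np.zeros((3, 2, 4), complex)
        phased, valid = pt.phase_with_first_echo(series)
        assert not valid.any()
        assert np.max(np.abs(np.angle(phased))) == 0.0


class TestPhaseToTemperature:
    def test_forward_formula_round_trip(self):
        # -0.10176 rad at effective TE 5.5 ms is +1 degC at 7 T
        dT = pt.phase_to_temperature(-0.10175655600372428, 5.5e-3)
        assert dT == pytest.approx(1.0, rel=1e-9)

    def test_null_and_linearity(self):
        assert pt.phase_to_temperature(0.0, 5.5e-3) == 0.0
        one = pt.phase_to_temperature(-0.05, 5.5e-3)
        two = pt.phase_to_temperature(-0.10, 5.5e-3)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_drift_phase_subtracted(self):
        raw = pt.phase_to_temperature(-0.10, 5.5e-3, dphi_drift=-0.04)
        ref = pt.phase_to_temperature(-0.06, 5.5e-3)
        assert raw == pytest.approx(ref, rel=1e-12)

    def test_nonpositive_te_rejected(self):
        with pytest.raises(ValueError):
            pt.phase_to_temperature(0.1, 0.0)


class TestEchoCombination:
    def test_identical_maps_unchanged(self):
        maps = np.ones((4, 5, 5)) * 2.5
        mags = np.random.default_rng(6).uniform(0.1, 1, size=(4, 5, 5))
        combined, ok = pt.combine_echo_maps(maps, mags, [3.62, 5.5, 7.38, 9.26])
        assert ok.all()
        np.testing.assert_allclose(combined, 2.5, rtol=1e-12)

    def test_two_echo_weighted_mean(self):
        maps = np.array([[[1.0]], [[3.0]]])
        mags = np.array([[[2.0]], [[1.0]]])      # TE * |I| = {2, 2}
        combined, _ = pt.combine_echo_maps(maps, mags, [1.0, 2.0])
        assert combined[0, 0] == pytest.approx(2.0)

    def test_zero_intensity_echo_ignored(self):
        maps = np.array([[[1.0]], [[99.0]]])
        mags = np.array([[[1.0]], [[0.0]]])
        combined, _ = pt.combine_echo_maps(maps, mags, [5.0, 9.0])
        assert combined[0, 0] == pytest.approx(1.0)

    def test_convexity_bound(self):
        rng = np.random.default_rng(7)
        maps = rng.normal(size=(4, 6, 6))
        mags = rng.uniform(0, 1, size=(4, 6, 6))
        combined, ok = pt.combine_echo_maps(maps, mags, [3.6, 5.5, 7.4, 9.3])
        lo, hi = maps.min(axis=0), maps.max(axis=0)
        assert np.all(combined[ok] >= lo[ok] - 1e-12)
        assert np.all(combined[ok] <= hi[ok] + 1e-12)


class TestDriftModel:
    def coords(self, shape=(8, 8, 6), d=(10.0, 10.0, 10.0)):
        ax = [(np.arange(n) - (n - 1) / 2) * dd for n, dd in zip(shape, d)]
        return np.meshgrid(*ax, indexing="ij")

    def test_exact_plane_recovery(self):
        X, Y, Z = self.coords()
        plane = 0.1 + 0.001 * X - 0.002 * Y + 0.0005 * Z
        model = pt.fit_drift_model(plane[None], np.ones_like(X, bool),
                                   (X, Y, Z))
        np.testing.assert_allclose(model.coeffs[0],
                                   [0.1, 0.001, -0.002, 0.0005], atol=1e-9)

    def test_zero_map_zero_coefficients(self):
        X, Y, Z = self.coords()
        model = pt.fit_drift_model(np.zeros((2, *X.shape)),
                                   np.ones_like(X, bool), (X, Y, Z))
        np.testing.assert_allclose(model.coeffs, 0.0, atol=1e-15)

    def test_noisy_recovery_within_ols_theory(self):
        rng = np.random.default_rng(8)
        X, Y, Z = self.coords()
        sigma = 0.05
        mask = np.ones_like(X, bool)
        A = np.column_stack([np.ones(mask.sum()), X[mask], Y[mask], Z[mask]])
        cov = sigma ** 2 * np.linalg.inv(A.T @ A)
        sd = np.sqrt(np.diag(cov))
        true = np.array([0.05, 0.0008, -0.0004, 0.0002])
        plane = true[0] + true[1] * X + true[2] * Y + true[3] * Z
        misses = 0
        for _ in range(20):
            noisy = plane + rng.normal(0, sigma, X.shape)
            model = pt.fit_drift_model(noisy[None], mask, (X, Y, Z))
            misses += np.any(np.abs(model.coeffs[0] - true) > 3 * sd)
        assert misses <= 2   # 3-sigma misses are ~1% per fit

    def test_degenerate_mask_rejected(self):
        X, Y, Z = self.coords()
        mask = np.zeros_like(X, bool)
        mask[0, 0, :] = True   # collinear points: plane not identifiable
        with pytest.raises(ValueError, match="identifiable|degenerate"):
            pt.fit_drift_model(np.zeros((1, *X.shape)), mask, (X, Y, Z))


class TestProbeDriftCorrection:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(9)
        truth = rng.normal(size=(6, 6, 6))
        roi = np.zeros((6, 6, 6), bool)
        roi[2:4, 2:4, 2] = True
        shifted = truth + 0.3
        corrected = pt.probe_drift_correct(shifted, [truth[roi].mean()], [roi])
        np.testing.assert_allclose(corrected, truth, atol=1e-12)

    def test_agreeing_probe_leaves_map_unchanged(self):
        m = np.full((4, 4, 4), 1.5)
        roi = np.zeros((4, 4, 4), bool)
        roi[1, 1, 1] = True
        corrected = pt.probe_drift_correct(m, [1.5], [roi])
        np.testing.assert_allclose(corrected, m)

    def test_two_probes_mean_offset(self):
        m = np.zeros((4, 4, 4))
        roi1 = np.zeros_like(m, bool); roi1[0, 0, 0] = True
        roi2 = np.zeros_like(m, bool); roi2[2, 2, 2] = True
        corrected = pt.probe_drift_correct(m, [-0.2, -0.4], [roi1, roi2])
        np.testing.assert_allclose(corrected, -0.3)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            pt.probe_drift_correct(np.zeros((3, 3, 3)), [0.0],
                                   [np.zeros((3, 3, 3), bool)])


class TestStabilityReport:
    def test_settling_time_recovered(self, drift_acquisition):
        cfg, truth, result = drift_acquisition
        model = pt.fit_drift_model(result.delta_T, result.mask,
                                   result.coordinates_mm())
        report = pt.stability_report(model, tr_s=cfg.tr_s)
        expected_rep = cfg.drift.settling_s / cfg.tr_s   # 14 min in reps
        assert report.stabilised_rep is not None
        assert abs(report.stabilised_rep - expected_rep) <= 2

    def test_zero_drift_stabilised_immediately(self):
        model = pt.DriftModel(coeffs=np.zeros((10, 4)),
                              rep_labels=np.arange(1, 11))
        report = pt.stability_report(model, tr_s=41.0)
        assert report.stabilised_rep == 1

    def test_pure_bulk_drift_passes_gradient_criterion(self):
        coeffs = np.zeros((20, 4))
        coeffs[:, 0] = 0.05 * np.arange(20)      # growing bulk offset
        model = pt.DriftModel(coeffs=coeffs, rep_labels=np.arange(1, 21))
        report = pt.stability_report(model, tr_s=41.0)
        assert report.stabilised_rep == 1
        assert report.bulk_C[-1] > report.bulk_C[0]


class TestMapsDiagnostics:
    def test_constant_series_zero_std(self):
        series = np.ones((5, 4, 4, 4)) * 2.0
        assert np.max(pt.temporal_std_map(series)) == 0.0

    def test_iid_noise_std_recovered(self):
        rng = np.random.default_rng(10)
        s = 0.07
        series = rng.normal(0, s, size=(100, 12, 12, 6))
        std = pt.temporal_std_map(series)
        assert abs(std.mean() - s) / s < 0.05

    def test_rmse_identities(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(6, 6, 6))
        scalar, diff = pt.rmse_map(a, a)
        assert scalar == 0.0
        scalar_c, _ = pt.rmse_map(a + 0.4, a)
        assert scalar_c == pytest.approx(0.4, rel=1e-12)
        with pytest.raises(ValueError):
            pt.rmse_map(a, a[:3])


class TestEndToEnd:
    def test_noiseless_inverse_recovery(self, noiseless_recon):
        cfg, truth, series, result = noiseless_recon
        err = (result.delta_T - truth.delta_T)[:, result.mask]
        assert np.max(np.abs(err)) < 1e-6

    def test_uniform_heating_exact_under_hann_and_padding(self):
        cfg = pt.ScenarioConfig(matrix=(16, 16, 8), n_reps=3, noise_sd=0.0,
                                seed=3, hotspot=None)
        truth = pt.make_ground_truth(cfg)
        truth.delta_T[2] = 1.0
        series = pt.render_acquisition(truth, cfg)
        rc = pt.ReconConfig(apodise=True, zero_pad_shape=(32, 32, 16),
                            reference_rep=1, drift_correction="none")
        result = pt.reconstruct_temperature(series, rc)
        vals = result.delta_T[2][result.mask]
        np.testing.assert_allclose(vals, 1.0, atol=1e-9)

    def test_injected_drift_recovered_exactly(self, drift_acquisition):
        cfg, truth, result = drift_acquisition
        model = pt.fit_drift_model(result.delta_T, result.mask,
                                   result.coordinates_mm())
        injected = truth.drift_coeffs - truth.drift_coeffs[0]
        np.testing.assert_allclose(model.coeffs, injected, atol=1e-9)

    def test_first_echo_phasing_cancels_jitter(self):
        cfg = pt.ScenarioConfig(matrix=(16, 16, 8), n_reps=5, noise_sd=0.0,
                                seed=3, jitter_sd_rad=0.3,
                                hotspot=pt.HotspotSpec(ramp_C_per_rep=0.2))
        truth = pt.make_ground_truth(cfg)
        series = pt.render_acquisition(truth, cfg)
        rc = pt.ReconConfig(apodise=False, zero_pad_shape=None,
                            reference_rep=1, drift_correction="none")
        result = pt.reconstruct_temperature(series, rc)
        err_phased = np.max(np.abs(
            (result.delta_T - truth.delta_T)[:, result.mask]))
        assert err_phased < 1e-9
        # without phasing, the same jitter corrupts the maps
        from prftherm.recon import combine_coils_svd, phase_to_temperature
        data = series.data.reshape(-1, *series.data.shape[2:])
        comb = combine_coils_svd(data)
        ref = comb[:, :1] / np.abs(comb[:, :1]).clip(min=1e-300)
        dphi = np.angle(comb * np.conj(ref))
        te = np.asarray(series.te_ms) * 1e-3
        dT_raw = phase_to_temperature(dphi[-1], te[-1], rc)
        err_raw = np.max(np.abs((dT_raw - truth.delta_T)[:, result.mask]))
        assert err_raw > 100 * err_phased

    def test_echo_combination_and_tiamo_improve_noisy_maps(
            self, noisy_acquisition):
        cfg, truth, series = noisy_acquisition
        rc = pt.ReconConfig(apodise=False, zero_pad_shape=None,
                            reference_rep=1, drift_correction="none")
        res = pt.reconstruct_temperature(series, rc)
        rms = lambda x: float(np.sqrt(np.mean(x ** 2)))
        m = res.mask
        combined = rms((res.delta_T[-1] - truth.delta_T[-1])[m])
        singles = [rms((res.per_echo_delta_T[i, -1] - truth.delta_T[-1])[m])
                   for i in range(len(res.echoes_used))]
        assert all(combined < s for s in singles)

        rc1 = pt.ReconConfig(apodise=False, zero_pad_shape=None,
                             reference_rep=1, drift_correction="none",
                             tiamo=False, mode_index=0)
        res1 = pt.reconstruct_temperature(series, rc1)
        void = (np.abs(truth.mode_maps[0])
                < 0.1 * np.median(np.abs(truth.mode_maps[0])[truth.mask]))
        void &= truth.mask
        assert void.any()
        std_two = pt.temporal_std_map(res.delta_T)
        std_one = pt.temporal_std_map(res1.delta_T)
        assert np.max(std_two[void]) < np.max(std_one[void])
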