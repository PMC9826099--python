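"""Preprocessing, LCMV beamformer, pseudo-T imaging, virtual electrodes."""

import numpy as np
import pytest
from scipy import linalg

from triaxmeg.fields import leadfield
from triaxmeg.recon import (
    CovarianceModel,
    Epochs,
    SourceImage,
    bandpass,
    cubic_grid,
    estimate_covariance,
    lcmv,
    peak_and_repeatability,
    preprocess,
    pseudo_t_image,
    virtual_electrode,
)


class TestPreprocess:
    def test_trials_per_condition(self, study_recording, small_paradigm):
        out = preprocess(study_recording)
        assert set(out) == {"left", "right"}
        for ep in out.values():
            assert ep.n_trials == small_paradigm.trials_per_block

    def test_excluding_one_sensor_leaves_87_channels(self, study_recording):
        out = preprocess(study_recording, exclude_sensors=[13])
        assert out["right"].n_channels == 87
        assert 3 * 13 not in out["right"].channel_indices

    def test_channel_means_zero(self, study_recording):
        ep = preprocess(study_recording)["right"]
        scale = np.abs(ep.data).max()
        assert np.abs(ep.data.mean(axis=2)).max() < 1e-12 * scale

    def test_missing_triggers_rejected(self, study_recording):
        import dataclasses

        bare = dataclasses.replace(study_recording, triggers=())
        with pytest.raises(ValueError):
            preprocess(bare)


class TestBandpass:
    fs = 600.0

    def _tone(self, freq, dur=10.0):
        t = np.arange(int(dur * self.fs)) / self.fs
        return np.sin(2 * np.pi * freq * t)

    def test_passband_tone_preserved(self):
        y = bandpass(self._tone(20.0), fs=self.fs)
        mid = y[int(2 * self.fs):-int(2 * self.fs)]
        amp = np.abs(mid).max()
        assert 0.95 <= amp <= 1.0

    def test_stopband_tone_suppressed(self):
        y = bandpass(self._tone(5.0), fs=self.fs)
        mid = y[int(2 * self.fs):-int(2 * self.fs)]
        assert np.abs(mid).max() < 0.01

    def test_dc_removed(self):
        y = bandpass(np.ones(6000), fs=self.fs)
        assert np.abs(y[1000:-1000]).max() < 1e-6

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 13, 350, fs=self.fs)


class TestCovariance:
    def test_regularization_shifts_spectrum(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 8, 2000))
        cov = estimate_covariance(x, mu=0.05)
        lam = np.linalg.eigvalsh(cov.matrix)
        lam_reg = np.linalg.eigvalsh(cov.regularized)
        assert lam_reg[-1] == pytest.approx((1 + 0.05) * lam[-1], rel=1e-10)
        assert lam_reg[0] >= 0.05 * lam[-1]

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 5, 500))
        c1, c2 = estimate_covariance(x), estimate_covariance(x)
        np.testing.assert_array_equal(c1.matrix, c2.matrix)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_covariance(np.zeros((1, 50, 60)))


class TestLCMV:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((4, 4))
        C = CovarianceModel(A @ A.T + 4 * np.eye(4), mu=0.05)
        L = rng.standard_normal((4, 2))
        return C, L

    def test_weights_match_constrained_qp_oracle(self):
        # oracle: bordered KKT system of min w'Cw s.t. w'(L eta) = 1
        for seed in range(5):
            C, L = self._toy(seed)
            sol = lcmv(C, L)
            Creg = C.regularized
            g = L @ sol.orientation
            kkt = np.block([[2 * Creg, g[:, None]], [g[None, :], np.zeros((1, 1))]])
            rhs = np.concatenate([np.zeros(4), [1.0]])
            w_oracle = np.linalg.solve(kkt, rhs)[:4]
            np.testing.assert_allclose(sol.weights, w_oracle, atol=1e-8)

    def test_unit_gain_constraint(self):
        for seed in range(5):
            C, L = self._toy(seed)
            sol = lcmv(C, L)
            assert abs(sol.weights @ (L @ sol.orientation) - 1.0) < 1e-8

    def test_orientation_recovery_high_snr(self, array, head):
        # single dipole with known tangential orientation, tiny noise
        from triaxmeg.fields import source_tangential_basis

        src = np.array([0.0, 0.04, 0.045])
        e_theta, e_phi = source_tangential_basis(src, head)
        angle_true = np.deg2rad(35.0)
        eta_true = np.array([np.cos(angle_true), np.sin(angle_true)])
        L = leadfield(array, src, head)
        rng = np.random.default_rng(2)
        q = rng.standard_normal(20000)
        x = np.outer(L @ eta_true, q) * 1e-9
        x += 1e-17 * rng.standard_normal(x.shape)
        cov = estimate_covariance(x[None], mu=0.05)
        sol = lcmv(cov, L)
        cosang = abs(sol.orientation @ eta_true)
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 5.0

    def test_singular_gram_rejected(self):
        C = CovarianceModel(np.eye(4), mu=0.0)
        L = np.zeros((4, 2))
        L[:, 0] = [1, 0, 0, 0]
        L[:, 1] = [1, 0, 0, 0]  # rank-1: orientation ambiguous
        with pytest.raises(ValueError):
            lcmv(C, L)


def _filtered_epochs(rec, condition="right"):
    ep = preprocess(rec)[condition]
    return Epochs(bandpass(ep.data, fs=ep.fs), ep.fs, condition,
                  ep.channel_indices, ep.labels)


class TestPseudoT:
    def test_equal_windows_give_zero_image(self, study_recording):
        fe = _filtered_epochs(study_recording)
        target = np.array([0.01, 0.04, 0.05])
        grid = cubic_grid(target, 0.004, 0.004)
        win = {"active": (1.5, 3.5), "control": (1.5, 3.5)}
        img = pseudo_t_image(fe, study_recording.array, study_recording.head,
                             grid, windows=win)
        np.testing.assert_allclose(img.values, 0.0, atol=1e-12)

    def test_ratio_form_bounded(self, study_recording):
        fe = _filtered_epochs(study_recording)
        grid = cubic_grid([0.01, 0.04, 0.05], 0.008, 0.004)
        img = pseudo_t_image(fe, study_recording.array, study_recording.head,
                             grid, normalization="ratio")
        assert np.all(img.values >= -1.0) and np.all(img.values <= 1.0)

    def test_planted_source_localized_within_voxel(self, study_recording, single_source):
        fe = _filtered_epochs(study_recording)
        target = single_source.centroids[single_source.motor_regions[0]]
        grid = cubic_grid(target + [0.002, -0.003, 0.001], 0.014, 0.004)
        grid = grid[np.linalg.norm(grid, axis=1) < 0.076]
        img = pseudo_t_image(fe, study_recording.array, study_recording.head, grid)
        peak = img.grid[np.argmax(np.abs(img.values))]
        assert np.abs(peak - target).max() <= 0.004 + 1e-12

    def test_radial_mode_uses_only_radial_channels(self, study_recording):
        fe = _filtered_epochs(study_recording)
        rad = study_recording.array.radial_channel_indices()
        # manually restricted epochs must reproduce the radial-mode image
        ep_r = Epochs(fe.data[:, rad, :], fe.fs, fe.condition, rad, ())
        grid = cubic_grid([0.01, 0.04, 0.05], 0.008, 0.004)
        img_mode = pseudo_t_image(fe, study_recording.array, study_recording.head,
                                  grid, mode="radial")
        img_manual = pseudo_t_image(ep_r, study_recording.array, study_recording.head,
                                    grid, mode="triaxial")
        np.testing.assert_allclose(img_mode.values, img_manual.values, atol=1e-12)

    def test_output_power_monotone_in_source_amplitude(self, small_paradigm,
                                                       nulled_background, single_source):
        import dataclasses
        from triaxmeg.opm import NoiseModel
        from triaxmeg.synthpara import generate_recording

        li = single_source.motor_regions[0]
        target = single_source.centroids[li]
        powers = []
        for scale in (1.0, 2.0, 4.0):
            lat = {c: scale * single_source.lateralization[c]
                   for c in single_source.lateralization}
            p = dataclasses.replace(single_source, lateralization=lat)
            rec = generate_recording(p, small_paradigm, env=nulled_background,
                                     nm=NoiseModel(10.0, seed=1), seed=33)
            fe = _filtered_epochs(rec)
            cov = estimate_covariance(fe.data)
            L = leadfield(rec.array, target, rec.head)
            sol = lcmv(cov, L)
            cat = fe.data.transpose(1, 0, 2).reshape(fe.n_channels, -1)
            powers.append(np.var(virtual_electrode(sol, cat)))
        assert powers[0] < powers[1] < powers[2]

    def test_empty_window_rejected(self, study_recording):
        fe = _filtered_epochs(study_recording)
        grid = cubic_grid([0.01, 0.04, 0.05], 0.004, 0.004)
        with pytest.raises(ValueError):
            pseudo_t_image(fe, study_recording.array, study_recording.head, grid,
                           windows={"active": (2.0, 2.0), "control": (5.0, 7.0)})


class TestPeakRepeatability:
    def _image(self, values, grid):
        return SourceImage(grid=grid, values=values, spacing=0.001)

    def test_identical_images_zero_distance(self):
        grid = cubic_grid([0, 0, 0.05], 0.005, 0.001)
        vals = np.exp(-np.linalg.norm(grid - [0, 0, 0.05], axis=1) ** 2 / 1e-5)
        imgs = [self._image(vals, grid)] * 4
        _, dists, mean_d = peak_and_repeatability(imgs)
        assert mean_d == 0.0
        np.testing.assert_array_equal(dists, 0.0)

    def test_two_runs_symmetric_peaks(self):
        grid = np.array([[0.0, 0, 0], [0.002, 0, 0]])
        img_a = self._image(np.array([1.0, 0.1]), grid)
        img_b = self._image(np.array([0.1, 1.0]), grid)
        _, dists, mean_d = peak_and_repeatability([img_a, img_b])
        np.testing.assert_allclose(dists, [1.0, 1.0])  # mm to midpoint
        assert mean_d == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        grid = np.zeros((3, 3))
        imgs = [self._image(np.arange(3.0), grid)] * 2
        with pytest.raises(ValueError):
            peak_and_repeatability(imgs, mask=np.zeros(3, bool))


class TestVirtualElectrode:
    def test_unit_gain_recovers_source(self, array, head):
        L = leadfield(array, np.array([0.0, 0.04, 0.05]), head)
        eta = np.array([0.6, 0.8])
        rng = np.random.default_rng(3)
        q = rng.standard_normal(3000)
        x = np.outer(L @ eta, q)
        cov = estimate_covariance(x[None] + 1e-18 * rng.standard_normal((1,) + x.shape))
        sol = lcmv(cov, L)
        np.testing.assert_allclose(virtual_electrode(sol, x), q, rtol=1e-6, atol=1e-9)

    def test_zero_data_zero_output(self, array, head):
        L = leadfield(array, np.array([0.0, 0.04, 0.05]), head)
        cov = CovarianceModel(np.eye(90) * 1e-26, mu=0.05)
        sol = lcmv(cov, L)
        assert np.all(virtual_electrode(sol, np.zeros((90, 10))) == 0)

    def test_distant_location_suppressed(self, study_recording, single_source):
        fe = _filtered_epochs(study_recording)
        cov = estimate_covariance(fe.data)
        cat = fe.data.transpose(1, 0, 2).reshape(fe.n_channels, -1)
        target = single_source.centroids[single_source.motor_regions[0]]
        far = np.array([-target[0], -target[1], target[2]])  # mirrored site
        v_match = np.var(virtual_electrode(lcmv(cov, leadfield(
            study_recording.array, target, study_recording.head)), cat))
        v_far = np.var(virtual_electrode(lcmv(cov, leadfield(
            study_recording.array, far, study_recording.head)), cat))
        assert v_far < 0.10 * v_match
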