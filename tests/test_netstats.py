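"""Envelopes, AEC connectomics, summary metrics, and statistics."""

import numpy as np
import pytest
from scipy import stats

from triaxmeg.netstats import (
    Connectome,
    EnvelopeTrace,
    aec_connectome,
    beta_modulation,
    channel_snr,
    fingerprint_test,
    hilbert_envelope,
    interference_bands,
    interference_ratio,
    ranksum_bonferroni,
    tfs,
)

FS = 600.0


def tone(freq, dur=10.0, amp=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestHilbertEnvelope:
    def test_constant_tone_amplitude(self):
        x, _ = tone(20.0, amp=2.5)
        env = hilbert_envelope(x, FS, trim_s=1.0)
        np.testing.assert_allclose(env.env, 2.5, rtol=0.01)

    def test_zero_signal(self):
        env = hilbert_envelope(np.zeros(1000), FS)
        assert np.all(env.env == 0)

    def test_am_demodulation(self):
        x, t = tone(20.0)
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        env = hilbert_envelope(mod * x, FS, trim_s=1.0)
        truth = mod[int(FS):-int(FS)]
        assert np.corrcoef(env.env, truth)[0, 1] > 0.99

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError):
            EnvelopeTrace(np.array([-1.0, 0.0]), FS)


class TestTFS:
    def test_tone_peaks_in_containing_band(self):
        x, _ = tone(16.6)
        mat, bands = tfs(x, FS, bands=interference_bands())
        hot = int(np.argmax(mat.mean(axis=1)))
        lo, hi = bands[hot]
        assert lo <= 16.6 <= hi

    def test_zero_input_zero_output(self):
        mat, _ = tfs(np.zeros((3, 2000)), FS, bands=[(13, 15), (15, 17)])
        assert np.all(mat == 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            tfs(np.zeros(1000), FS, bands=[(290, 310)])

    def test_erd_visible_in_beta_rows(self, study_recording, single_source):
        from triaxmeg.recon import (bandpass, estimate_covariance, lcmv,
                                    preprocess, virtual_electrode)
        from triaxmeg.fields import leadfield

        ep = preprocess(study_recording)["right"]
        filt = bandpass(ep.data, 2, 45, fs=ep.fs)
        cov = estimate_covariance(bandpass(ep.data, fs=ep.fs))
        target = single_source.centroids[single_source.motor_regions[0]]
        L = leadfield(study_recording.array, target, study_recording.head)
        sol = lcmv(cov, L)
        trials = virtual_electrode(sol, filt)
        mat, bands = tfs(trials, ep.fs, bands=[(13, 17), (17, 22), (22, 30)])
        t = np.arange(mat.shape[1]) / ep.fs
        active = mat[:, (t > 1.0) & (t < 4.0)].mean()
        control = mat[:, (t > 5.5) & (t < 7.5)].mean()
        assert active < control  # ERD below the rebound level


class TestAECConnectome:
    def test_perfect_leakage_nulled(self):
        rng = np.random.default_rng(0)
        from triaxmeg.recon import bandpass

        a = bandpass(rng.standard_normal(int(600 * FS)), fs=FS)
        tcs = np.vstack([a, 3.7 * a])  # pure zero-lag leakage
        c = aec_connectome(tcs, FS)
        assert abs(c.matrix[0, 1]) < 0.05

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        from triaxmeg.recon import bandpass

        tcs = bandpass(rng.standard_normal((5, int(120 * FS))), fs=FS)
        c = aec_connectome(tcs, FS)
        iu = np.triu_indices(5, 1)
        assert np.abs(c.matrix[iu]).mean() < 0.05

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        from triaxmeg.recon import bandpass

        tcs = bandpass(rng.standard_normal((4, int(60 * FS))), fs=FS)
        c = aec_connectome(tcs, FS)
        np.testing.assert_array_equal(c.matrix, c.matrix.T)
        np.testing.assert_array_equal(np.diag(c.matrix), 1.0)

    def test_dead_region_flagged_nan(self):
        rng = np.random.default_rng(3)
        from triaxmeg.recon import bandpass

        tcs = bandpass(rng.standard_normal((3, int(30 * FS))), fs=FS)
        tcs[1] = 0.0
        c = aec_connectome(tcs, FS)
        assert np.isnan(c.matrix[0, 1]) and np.isnan(c.matrix[1, 2])
        assert np.isfinite(c.matrix[0, 2])


class TestSummaries:
    def test_78_regions_3003_pairs_77_edges(self):
        from triaxmeg.netstats import connectivity_summaries

        m = np.ones((78, 78))
        c = Connectome(m)
        assert len(c.upper_triangle()) == 3003
        total, strength = connectivity_summaries(c, node=10)
        assert total == 3003.0  # every unique pair contributes once
        assert strength == 77.0  # row sum excludes the diagonal

    def test_zero_matrix(self):
        from triaxmeg.netstats import connectivity_summaries

        total, strength = connectivity_summaries(Connectome(np.zeros((78, 78))), node=0)
        assert (total, strength) == (0.0, 0.0)

    def test_node_out_of_range(self):
        from triaxmeg.netstats import connectivity_summaries

        with pytest.raises(ValueError):
            connectivity_summaries(Connectome(np.zeros((78, 78))), node=78)


class TestBetaModulation:
    def test_constant_envelope_zero(self):
        env = EnvelopeTrace(np.ones(1200), 100.0)
        assert beta_modulation(env, (2, 4), (5, 7)) == 0.0

    def test_step_envelope_unit(self):
        e = np.ones(1200)
        e[500:] = 2.0
        env = EnvelopeTrace(e, 100.0)
        assert beta_modulation(env, (2, 4), (5, 7)) == pytest.approx(1.0)

    def test_monotone_in_erd_depth(self, small_paradigm, nulled_background):
        from triaxmeg.opm import NoiseModel
        from triaxmeg.recon import bandpass, preprocess
        from triaxmeg.synthpara import generate_recording, single_source_participant
        from scipy.signal import hilbert

        p = single_source_participant("P", seed=5)
        mods = []
        for depth in (0.2, 0.4, 0.6):
            rec = generate_recording(p, small_paradigm, env=nulled_background,
                                     nm=NoiseModel(5.0, seed=1), seed=8,
                                     erd_depth=depth, rebound_gain=0.2)
            ep = preprocess(rec)["right"]
            filt = bandpass(ep.data, fs=ep.fs)
            c = int(np.argmax(filt.std(axis=(0, 2))))  # best channel
            env_tr = np.abs(hilbert(filt[:, c, :], axis=-1)).mean(axis=0)
            env = EnvelopeTrace(env_tr, ep.fs)
            mods.append(beta_modulation(env, (2, 4), (5, 7)))
        assert mods[0] < mods[1] < mods[2]

    def test_empty_window_rejected(self):
        env = EnvelopeTrace(np.ones(100), 100.0)
        with pytest.raises(ValueError):
            beta_modulation(env, (0.5, 0.5), (0.6, 0.9))


class TestChannelSNR:
    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        e = np.abs(rng.standard_normal((3, 1000))) + 1.0
        s1 = channel_snr(e, 100.0, (2, 4), (5, 7))
        s2 = channel_snr(10.0 * e, 100.0, (2, 4), (5, 7))
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_zero_variance_rejected(self):
        e = np.ones((2, 1000))
        with pytest.raises(ValueError):
            channel_snr(e, 100.0, (2, 4), (5, 7))


class TestInterferenceRatio:
    def test_white_noise_near_zero(self):
        # flat spectrum: the line bin carries chi-square estimation noise, so
        # the null level is checked on the average over independent records
        rng = np.random.default_rng(5)
        vals = [interference_ratio(rng.standard_normal(int(60 * FS)), FS)
                for _ in range(10)]
        assert abs(np.mean(vals)) < 0.2

    def test_line_plus_noise_matches_analytic(self):
        rng = np.random.default_rng(6)
        dur, df = 120.0, 0.1
        noise = rng.standard_normal(int(dur * FS))
        # one-sided white-noise PSD = 2 sigma^2 / fs per Hz; a unit-amplitude
        # sine concentrates power 1/2 into one df-wide Welch bin (hann ENBW 1.5)
        noise_psd = 2.0 / FS
        target = 10.0
        amp = np.sqrt(2 * target * noise_psd * df * 1.5)
        x, _ = tone(16.6, dur=dur, amp=amp)
        r = interference_ratio(x + noise, FS, df=df)
        assert abs(r - target) < 0.2 * target

    def test_monotone_in_line_amplitude(self):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal(int(30 * FS))
        rs = []
        for amp in (0.05, 0.1, 0.2):
            x, _ = tone(16.6, dur=30.0, amp=amp)
            rs.append(interference_ratio(x + noise, FS))
        assert rs[0] < rs[1] < rs[2]

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            interference_ratio(np.zeros(int(2 * FS)), FS)


class TestRankSum:
    def test_identical_groups_p_one(self):
        w, p, pc = ranksum_bonferroni([1.0] * 8, [1.0] * 8)
        assert p == 1.0 and pc == 1.0

    def test_fully_separated_exact_p(self):
        a = np.arange(8.0)
        b = np.arange(100.0, 108.0)
        _, p, _ = ranksum_bonferroni(a, b)
        assert p == pytest.approx(2.0 / 12870.0, rel=1e-10)

    def test_bonferroni_doubles_and_caps(self):
        a = np.arange(8.0)
        b = np.arange(100.0, 108.0)
        _, p, pc = ranksum_bonferroni(a, b, m_tests=2)
        assert pc == pytest.approx(2 * p)
        _, p1, pc1 = ranksum_bonferroni([1, 2, 3.0], [1.5, 2.5, 3.5], m_tests=50)
        assert pc1 == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_bonferroni([], [1.0, 2.0])


class TestFingerprint:
    def test_comparison_counts(self):
        rng = np.random.default_rng(8)
        res = fingerprint_test(rng.standard_normal((16, 30)), n_perm=100, seed=0)
        assert len(res.within) == 56
        assert len(res.between) == 64
        assert len(res.within) + len(res.between) == 120

    def test_identical_vectors_p_one(self):
        v = np.linspace(0, 1, 40)
        res = fingerprint_test(np.tile(v, (16, 1)), n_perm=500, seed=1)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_separated_participants_small_p(self):
        rng = np.random.default_rng(9)
        pa, pb = rng.uniform(0, 0.5, 300), rng.uniform(0, 0.5, 300)
        items = np.vstack(
            [pa + 0.1 * rng.standard_normal(300) for _ in range(8)]
            + [pb + 0.1 * rng.standard_normal(300) for _ in range(8)]
        )
        res = fingerprint_test(items, n_perm=10_000, seed=2)
        assert res.p_value <= 0.001
        assert res.observed < 0  # between below within

    def test_wrong_run_count_rejected(self):
        with pytest.raises(ValueError):
            fingerprint_test(np.zeros((12, 10)), n_perm=10)

    def test_null_p_values_uniform(self):
        # under exchangeability the permutation p-value is uniform
        rng = np.random.default_rng(10)
        ps = [
            fingerprint_test(rng.standard_normal((16, 40)), n_perm=500, seed=k).p_value
            for k in range(100)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01
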