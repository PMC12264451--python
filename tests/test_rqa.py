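import numpy as np
import pandas as pd
import pytest

from tpenet.rqa import (
    EmbeddingParams, RecurrencePlot, analyze_segment, embed, preprocess_eeg,
    recurrence_matrix, rqa_features, rqa_protocol, select_delay_ami,
    select_dim_fnn, _fnn_fraction,
)
from tpenet.synthetic import EEGRecording, gen_eeg_recording, _lorenz_source

from oracles import brute_fnn, brute_rqa


def henon_series(n, seed=0):
    x, y = 0.1, 0.3
    out = np.empty(n)
    for i in range(n + 100):
        x, y = 1 - 1.4 * x * x + y, 0.3 * x
        if i >= 100:
            out[i - 100] = x
    return out


class TestPreprocess:
    def test_average_reference_zero_mean(self):
        rec = gen_eeg_recording(0.3, n_channels=4, duration=5, fs=500, seed=0)
        out = preprocess_eeg(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_downsampled_to_500(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(rng.standard_normal((2, 10000)), 1000.0, ["a", "b"])
        out = preprocess_eeg(rec)
        assert out.fs == 500.0
        assert out.data.shape[1] == 5000

    @pytest.mark.parametrize("freq", [50.0, 100.0])
    def test_out_of_band_tones_attenuated(self, freq):
        """The 50 Hz notch and the 80 Hz low-pass edge both cut a pure tone
        by more than 20 dB."""
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        rng = np.random.default_rng(1)
        tone = np.sin(2 * np.pi * freq * t)
        data = np.vstack([tone, rng.standard_normal(t.size)])
        out = preprocess_eeg(EEGRecording(data, fs, ["tone", "noise"]))
        # average reference mixes channels; measure at the tone frequency via
        # the periodogram of the difference channel, which preserves the tone
        sig = out.data[0] - out.data[1]
        freqs = np.fft.rfftfreq(sig.size, 1 / fs)
        power = np.abs(np.fft.rfft(sig)) ** 2
        band = (freqs > freq - 0.5) & (freqs < freq + 0.5)
        ref_band = (freqs > 10 - 0.5) & (freqs < 10 + 0.5)
        in_power = power[band].max()
        raw = np.abs(np.fft.rfft(tone)) ** 2
        raw_power = raw[band[: raw.size]].max()
        assert 10 * np.log10(raw_power / in_power) > 20

    def test_low_rate_rejected(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((1, 1000)),
                           120.0, ["a"])
        with pytest.raises(ValueError):
            preprocess_eeg(rec)


class TestDelaySelection:
    def test_sine_quarter_period(self):
        t = np.arange(4000)
        x = np.sin(2 * np.pi * t / 100)
        x = x + 0.02 * np.random.default_rng(0).standard_normal(t.size)
        tau = select_delay_ami(x, max_lag=200)
        assert abs(tau - 25) <= 2

    def test_white_noise_triggers_fallback(self):
        x = np.random.default_rng(1).standard_normal(3000)
        with pytest.warns(UserWarning, match="1/e"):
            tau = select_delay_ami(x, max_lag=200)
        assert tau == 1

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            select_delay_ami(np.ones(3000))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            select_delay_ami(np.sin(np.arange(300) / 5.0), max_lag=200)


class TestDimensionSelection:
    def test_henon_needs_two_dimensions(self):
        x = henon_series(2000)
        assert select_dim_fnn(x, tau=1, theiler=1) == 2

    def test_lorenz_needs_three_dimensions(self):
        x = _lorenz_source(4000, 128.0, np.random.default_rng(4))[0]
        tau = select_delay_ami(x)
        assert select_dim_fnn(x, tau) == 3

    def test_fractions_match_brute_force(self):
        x = henon_series(300)
        for m in (1, 2, 3):
            mine = _fnn_fraction(x, tau=1, m=m, rtol=10.0, atol=2.0, theiler=1)
            ref = brute_fnn(x, tau=1, m=m, rtol=10.0, atol=2.0, theiler=1)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_noise_exercises_warning_path(self):
        x = np.random.default_rng(5).standard_normal(1200)
        with pytest.warns(UserWarning, match="FNN"):
            m = select_dim_fnn(x, tau=1, m_max=4, fnn_threshold=1e-6)
        assert 1 <= m <= 4


class TestRecurrenceMatrix:
    def test_achieved_rate_within_tolerance(self):
        t = np.arange(1500)
        x = np.sin(2 * np.pi * t / 90) + 0.2 * np.random.default_rng(6).standard_normal(t.size)
        rp = recurrence_matrix(x, EmbeddingParams(22, 3), rr_target=0.05)
        from tpenet.rqa import _admissible_mask

        rr = rp.R.sum() / _admissible_mask(rp.n_points, rp.theiler).sum()
        assert 0.045 <= rr <= 0.055

    def test_epsilon_zero_empty_and_diameter_full(self):
        x = np.sin(np.arange(600) / 7.0)
        p = EmbeddingParams(5, 2)
        rp0 = recurrence_matrix(x, p, rr_target=None, epsilon=0.0)
        # only exactly coincident embedded points can recur at eps=0
        assert rp0.R.sum() <= 2
        rp1 = recurrence_matrix(x, p, rr_target=None, epsilon=1e9)
        from tpenet.rqa import _admissible_mask

        assert rp1.R.sum() == _admissible_mask(rp1.n_points, rp1.theiler).sum()

    def test_symmetry_and_theiler_band_empty(self):
        x = np.random.default_rng(7).standard_normal(700)
        rp = recurrence_matrix(x, EmbeddingParams(3, 3), rr_target=0.08)
        assert np.array_equal(rp.R, rp.R.T)
        n = rp.n_points
        i = np.arange(n)
        band = np.abs(i[:, None] - i[None, :]) <= rp.theiler
        assert rp.R[band].sum() == 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            recurrence_matrix(np.zeros(500), EmbeddingParams(2, 2), 0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            recurrence_matrix(np.sin(np.arange(90) / 3), EmbeddingParams(1, 1), 0.05)


def make_plot(R, theiler=0):
    R = np.asarray(R, dtype=bool)
    return RecurrencePlot(R=R, epsilon=0.1, theiler=theiler, rr_target=None)


class TestRQAFeatures:
    def test_saturated_plot(self):
        n = 12
        R = ~np.eye(n, dtype=bool)
        # with lmin=vmin=1 the corner diagonals of length 1 count too and
        # the saturated plot reaches the exact maxima
        f = rqa_features(make_plot(R, theiler=0), lmin=1, vmin=1)
        assert f["RR"] == 1.0 and f["DET"] == 1.0 and f["LAM"] == 1.0
        assert f["Clust"] == 1.0 and f["Trans"] == 1.0
        assert f["RTmax"] == 0 and f["T2"] == 0.0
        # at the default lmin=2 only the two single-cell corner diagonals
        # fall out of the determinism numerator
        f2 = rqa_features(make_plot(R, theiler=0))
        assert f2["DET"] == pytest.approx(1 - 2 / (n * (n - 1)))

    def test_hand_written_8x8_matrix_matches_enumeration(self):
        rng = np.random.default_rng(8)
        R = rng.random((8, 8)) < 0.4
        R = np.triu(R, 1)
        R = R | R.T
        f = rqa_features(make_plot(R, theiler=0))
        ref = brute_rqa(R, theiler=0)
        for k, v in ref.items():
            assert f[k] == pytest.approx(v, abs=1e-12), k

    def test_oracle_equivalence_on_random_signals(self):
        """All 13 features match exhaustive enumeration on random signals
        with N' <= 500 (mixtures of tones and noise)."""
        rng = np.random.default_rng(9)
        for rep in range(12):
            n = int(rng.integers(150, 400))
            t = np.arange(n + 30)
            x = (rng.uniform(0.2, 1.5) * np.sin(2 * np.pi * t / rng.uniform(20, 80))
                 + rng.uniform(0.05, 1.0) * rng.standard_normal(t.size))
            tau = int(rng.integers(1, 4))
            m = int(rng.integers(1, 4))
            theiler = int(rng.integers(0, 4))
            rp = recurrence_matrix(
                x, EmbeddingParams(tau, m), rr_target=float(rng.uniform(0.03, 0.15)),
                theiler=theiler,
            )
            mine = rqa_features(rp)
            ref = brute_rqa(rp.R, theiler=theiler)
            for k, v in ref.items():
                assert mine[k] == pytest.approx(v, abs=1e-12), (rep, k)

    def test_periodic_beats_noise_on_determinism(self):
        for seed in range(3):
            rng = np.random.default_rng(40 + seed)
            t = np.arange(800)
            per = np.sin(2 * np.pi * t / 60) + 0.005 * rng.standard_normal(t.size)
            noi = rng.standard_normal(t.size)
            p = EmbeddingParams(15, 3)
            det_p = rqa_features(recurrence_matrix(per, p, 0.05))["DET"]
            det_n = rqa_features(recurrence_matrix(noi, p, 0.05))["DET"]
            assert det_p >= 0.95
            assert det_p > det_n

    def test_entr_zero_when_single_line_length(self):
        # two isolated diagonal lines of equal length -> zero entropy
        n = 10
        R = np.zeros((n, n), dtype=bool)
        for i in range(2):
            R[i, i + 5] = R[i + 5, i] = True
        for i in range(3, 5):
            R[i, i + 5] = R[i + 5, i] = True
        f = rqa_features(make_plot(R, theiler=0))
        assert f["ENTR"] == 0.0
        assert f["Lmax"] == 2


class TestProtocol:
    def test_degenerate_single_window_equals_direct_features(self):
        rec = gen_eeg_recording(0.8, n_channels=1, duration=24.0, fs=128, seed=10)
        f_prot = rqa_protocol(rec, seg_len=10.0, n_iter=1, head_trim=4.0,
                              tail_trim=10.0, seed=0)
        lo = int(4.0 * 128)
        x = rec.data[0][lo: lo + 1280]
        f_direct, _ = analyze_segment(x)
        pd.testing.assert_series_equal(f_prot, f_direct.astype(float),
                                       check_names=False)

    def test_too_short_recording_rejected(self):
        rec = gen_eeg_recording(0.5, n_channels=1, duration=20.0, fs=128, seed=1)
        with pytest.raises(ValueError, match="too short"):
            rqa_protocol(rec, seg_len=10.0, n_iter=2)

    def test_seeded_determinism(self):
        rec = gen_eeg_recording(0.6, n_channels=2, duration=30.0, fs=128, seed=2)
        a = rqa_protocol(rec, n_iter=3, seed=5, embed_mode="per_channel")
        b = rqa_protocol(rec, n_iter=3, seed=5, embed_mode="per_channel")
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_protocol_mean_approaches_stationary_value(self):
        """On a stationary signal the random-window average stays close to
        any other window's value (Monte-Carlo consistency)."""
        rec = gen_eeg_recording(1.0, n_channels=1, duration=40.0, fs=128, seed=3)
        f = rqa_protocol(rec, n_iter=8, seed=1, embed_mode="per_channel")
        g = rqa_protocol(rec, n_iter=8, seed=99, embed_mode="per_channel")
        assert abs(f["DET"] - g["DET"]) < 0.15
        assert abs(f["RR"] - 0.05) < 0.005


def test_embedding_shape_identity():
    x = np.arange(100.0)
    Y = embed(x, tau=3, m=4)
    assert Y.shape == (100 - 9, 4)
    assert np.array_equal(Y[0], [0, 3, 6, 9])
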