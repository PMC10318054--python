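import numpy as np
import pytest

from pwavekit.core import Episode
from pwavekit.photometry import (
    SpectralField,
    _lagged_design,
    compute_dff,
    consecutive_bin_test,
    crosscorr_dff_pwaves,
    downsample_to_grid,
    event_triggered,
    fit_spectral_field,
    predict_response,
)
from pwavekit.spectral import Spectrogram


def make_norm_spec(rng, n_f=8, n_t=800, step=0.4):
    E = rng.gamma(2.0, 0.5, size=(n_f, n_t))
    E /= E.mean(axis=1, keepdims=True)
    freqs = 0.5 + np.arange(n_f) * 0.5
    times = np.arange(n_t) * step + 1.0
    return Spectrogram(E, freqs, times, 2.0, step, "recording_mean")


class TestComputeDff:
    def test_identical_channels_give_zero(self, rng):
        x = 1.0 + 0.1 * np.abs(rng.standard_normal(30_000))
        tr = compute_dff(x, x, 1500.0)
        assert np.abs(tr.dff).max() < 1e-9

    def test_scaled_channel_absorbed_by_regression(self, rng):
        x = 2.0 + 0.05 * rng.standard_normal(30_000)
        tr = compute_dff(2.0 * x, x, 1500.0)
        assert np.abs(tr.dff).max() < 1e-9
        assert tr.fit_slope == pytest.approx(2.0, rel=1e-6)

    def test_common_gain_invariance(self, rng):
        n = 30_000
        s465 = 2.0 + 0.1 * np.sin(np.arange(n) / 5000) + 0.01 * rng.standard_normal(n)
        s405 = 1.0 + 0.005 * rng.standard_normal(n)
        a = compute_dff(s465, s405, 1500.0)
        b = compute_dff(7.3 * s465, 7.3 * s405, 1500.0)
        assert np.allclose(a.dff, b.dff, atol=1e-10)

    def test_roundtrip_against_generator_truth(self, short_session):
        cfg, rec, gt = short_session
        tr = compute_dff(
            rec["photo_465"].data, rec["photo_405"].data, cfg.rate_photo_hz
        )
        assert np.corrcoef(tr.dff, gt.calcium_true)[0, 1] >= 0.9

    def test_zero_crossing_fit_rejected(self):
        n = 10_000
        s405 = np.linspace(-1, 1, n)
        s465 = np.linspace(-1, 1, n)
        with pytest.raises(ValueError, match="dF/F undefined"):
            compute_dff(s465, s405, 1500.0)


class TestEventTriggered:
    def test_constant_dff_zscores_to_zero(self):
        mat, t, mean = event_triggered(
            np.full(10_000, 2.0), 1000.0, [5.0], window_s=(-1, 1)
        )
        assert np.allclose(mat, 0.0)

    def test_single_event_row_equals_raw_slice(self, rng):
        dff = rng.standard_normal(10_000)
        mat, t, _ = event_triggered(dff, 1000.0, [5.0], window_s=(-1, 1), z_score=False)
        assert mat.shape == (1, 2000)
        assert np.array_equal(mat[0], dff[4000:6000])

    def test_edge_events_dropped(self, rng):
        dff = rng.standard_normal(10_000)
        mat, _, _ = event_triggered(
            dff, 1000.0, [0.5, 5.0, 9.9], window_s=(-1, 1), z_score=False
        )
        assert mat.shape[0] == 1


class TestConsecutiveBinTest:
    def test_bins_identical_to_baseline_never_significant(self, rng):
        # each event's trace is constant in time: every bin equals the
        # baseline exactly, so no paired difference exists
        n_ev, n_t = 30, 2000
        mat = np.tile(rng.standard_normal((n_ev, 1)), (1, n_t))
        t = (np.arange(n_t) - 500) / 100.0
        out = consecutive_bin_test(mat, t, (-5.0, -2.5), 2.5)
        assert not out["significant"].any()

    def test_noise_false_positive_rate_at_most_alpha(self, rng):
        # iid noise: Bonferroni holds the family-wise error at alpha, so
        # across replicates at most ~5% have any significant bin
        hits = 0
        reps = 60
        t = (np.arange(1500) - 500) / 100.0
        for _ in range(reps):
            mat = rng.standard_normal((25, 1500))
            out = consecutive_bin_test(mat, t, (-5.0, -2.5), 2.5)
            hits += out["significant"].any()
        assert hits / reps <= 0.15

    def test_large_shift_detected_and_bonferroni_applied(self, rng):
        n_ev, n_t = 20, 1500
        mat = rng.standard_normal((n_ev, n_t))
        t = (np.arange(n_t) - 500) / 100.0
        mat[:, (t >= 2.5) & (t < 5.0)] += 10.0
        out = consecutive_bin_test(mat, t, (-5.0, -2.5), 2.5)
        hit = out[(out["bin_start_s"] == 2.5)]
        assert hit["significant"].all()
        # corrected level is alpha / number of bins tested
        k = len(out)
        null_rows = out[out["bin_start_s"] != 2.5]
        assert ((null_rows["p"] < 0.05 / k) == null_rows["significant"]).all()


class TestCrossCorrelation:
    def test_recovers_injected_kernel_lag(self, rng):
        rate = 1500.0
        dur = 400.0
        n = int(dur * rate)
        ev = np.sort(rng.uniform(20, dur - 20, 60))
        ev = ev[np.concatenate([[True], np.diff(ev) > 1.5])]
        dff = np.zeros(n)
        # kernel peaking exactly 0.5 s after the event
        tt = np.arange(0, 2.0, 1 / rate)
        kern = np.exp(-((tt - 0.5) ** 2) / (2 * 0.05**2))
        for te in ev:
            i = int(te * rate)
            dff[i : i + kern.size] += kern[: n - i]
        eps = [Episode("R", 0.0, dur)]
        lags, cc = crosscorr_dff_pwaves(dff, rate, ev, eps)
        assert abs(lags[np.nanargmax(cc)] - 0.5) <= 0.005 + 1e-9

    def test_normalization_independent_of_event_count(self, rng):
        rate = 1500.0
        dur = 600.0
        tt = np.arange(0, 1.0, 1 / rate)
        kern = np.exp(-((tt - 0.3) ** 2) / (2 * 0.05**2))

        def build(n_ev, seed):
            r = np.random.default_rng(seed)
            ev = np.sort(r.uniform(10, dur - 10, n_ev))
            ev = ev[np.concatenate([[True], np.diff(ev) > 1.2])]
            dff = np.zeros(int(dur * rate))
            for te in ev:
                i = int(te * rate)
                dff[i : i + kern.size] += kern
            lags, cc = crosscorr_dff_pwaves(dff, rate, ev, [Episode("R", 0, dur)])
            return np.nanmax(cc)

        a, b = build(40, 1), build(120, 2)
        # overlap of neighbouring kernels adds a small baseline; the
        # per-event normalization keeps the peak amplitude comparable
        assert a == pytest.approx(b, rel=0.15)

    def test_independent_signals_flat(self, rng):
        rate = 1500.0
        dur = 600.0
        dff = rng.standard_normal(int(dur * rate)) * 0.01
        ev = np.sort(rng.uniform(10, dur - 10, 100))
        lags, cc, mat = crosscorr_dff_pwaves(
            dff, rate, ev, [Episode("R", 0, dur)], return_episodes=True
        )
        assert np.nanstd(cc) < 0.01

    def test_no_qualifying_episode_warns(self, rng):
        with pytest.warns(UserWarning, match="no qualifying"):
            lags, cc = crosscorr_dff_pwaves(
                np.zeros(1000), 100.0, np.array([1.0]), [Episode("R", 0.0, 5.0)]
            )
        assert np.all(np.isnan(cc))


class TestSpectralField:
    def test_noiseless_ols_recovery(self, rng):
        spec = make_norm_spec(rng)
        n_lag = 5
        H_true = rng.standard_normal((8, 11)) * np.exp(
            -np.abs(np.arange(-n_lag, n_lag + 1)) / 3.0
        )
        X, valid = _lagged_design(spec.power, n_lag)
        y = np.zeros(spec.power.shape[1])
        y[valid] = 0.3 + X @ H_true.T.reshape(-1)
        f = fit_spectral_field(spec, y, n_lag=n_lag, lambdas=[1e-10])
        assert np.abs(f.H - H_true).max() < 1e-6
        assert f.r0 == pytest.approx(0.3, abs=1e-8)
        # independent closed-form oracle: ordinary least squares
        A = np.column_stack([np.ones(X.shape[0]), X])
        beta, *_ = np.linalg.lstsq(A, y[valid], rcond=None)
        assert np.abs(f.H.T.reshape(-1) - beta[1:]).max() < 1e-6

    def test_prediction_consistency_and_shift_equivariance(self, rng):
        spec = make_norm_spec(rng)
        y = rng.standard_normal(spec.power.shape[1])
        f = fit_spectral_field(spec, y, n_lag=4, lambdas=[1.0])
        valid, rhat = predict_response(f, spec)
        # refit residuals equal fit residuals on the training span
        X, v2 = _lagged_design(spec.power, 4)
        assert np.array_equal(valid, v2)
        # shifting the spectrogram by one step shifts the prediction
        spec_shift = Spectrogram(
            np.roll(spec.power, 1, axis=1), spec.freqs_hz, spec.times_s,
            spec.window_s, spec.step_s, "recording_mean",
        )
        _, rhat_shift = predict_response(f, spec_shift)
        assert np.allclose(rhat_shift[2:], rhat[1:-1])

    def test_zero_kernel_predicts_offset(self, rng):
        spec = make_norm_spec(rng, n_t=100)
        f = SpectralField(
            np.zeros((8, 9)), 1.7, spec.freqs_hz, np.arange(-4, 5) * 0.4, 0.0,
            np.zeros(5),
        )
        _, rhat = predict_response(f, spec)
        assert np.allclose(rhat, 1.7)

    def test_unpredictable_response_has_no_cv_skill(self, rng):
        spec = make_norm_spec(rng, n_t=600)
        y = rng.standard_normal(600)
        f = fit_spectral_field(spec, y, n_lag=5)
        assert np.mean(f.cv_r2) < 0.05

    def test_underdetermined_without_ridge_raises(self, rng):
        spec = make_norm_spec(rng, n_t=60)
        y = rng.standard_normal(60)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_spectral_field(spec, y, n_lag=10, lambdas=[0.0])

    def test_requires_recording_mean_normalization(self, rng):
        spec = make_norm_spec(rng, n_t=100)
        spec.normalization = "raw"
        with pytest.raises(ValueError, match="recording_mean"):
            fit_spectral_field(spec, np.zeros(100))

    def test_noisy_recovery_with_cv_lambda_beats_unregularized(self, rng):
        n_sims = 6
        corr_cv, corr_0 = [], []
        for k in range(n_sims):
            r = np.random.default_rng(100 + k)
            spec = make_norm_spec(r, n_t=700)
            n_lag = 5
            H_true = r.standard_normal((8, 11)) * np.exp(
                -np.abs(np.arange(-n_lag, n_lag + 1)) / 3.0
            )
            X, valid = _lagged_design(spec.power, n_lag)
            clean = X @ H_true.T.reshape(-1)
            y = np.zeros(spec.power.shape[1])
            y[valid] = clean + r.standard_normal(valid.size) * clean.std()  # SNR 1
            f = fit_spectral_field(spec, y, n_lag=n_lag)
            f0 = fit_spectral_field(spec, y, n_lag=n_lag, lambdas=[1e-10])
            corr_cv.append(np.corrcoef(f.H.ravel(), H_true.ravel())[0, 1])
            corr_0.append(np.corrcoef(f0.H.ravel(), H_true.ravel())[0, 1])
        assert np.median(corr_cv) >= 0.8
        assert np.median(corr_cv) > np.median(corr_0)


class TestDownsample:
    def test_grid_averages_constant(self):
        x = np.full(15_000, 3.0)
        grid = np.arange(1.0, 9.0, 0.4)
        out = downsample_to_grid(x, 1500.0, grid, 2.0)
        assert np.allclose(out, 3.0)
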