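"""mTRF estimation: lagged designs, ridge solutions, CV, prediction, scoring."""
import numpy as np
import pytest

from trfsize.containers import EEGRecording, FeatureMatrix, NoiseSpec
from trfsize.encoding import (LaggedDesign, RidgeConfig,
                              TemporalReceptiveField, build_lagged_design,
                              default_alpha_grid, predict, ridge_fit, score,
                              select_alpha)
from trfsize.synth import simulate_eeg, simulate_stimulus

FS = 128.0


def random_design(rng, n=200, n_feat=3, n_delays=10):
    X = rng.standard_normal((n, n_feat * n_delays))
    return LaggedDesign(X, np.arange(n_delays) / FS,
                        [f"f{i}" for i in range(n_feat)])


class TestLaggedDesign:
    def test_impulse_shifts_across_delay_columns(self):
        fm = FeatureMatrix(np.array([[1.0, 0, 0, 0]]), ["a"], FS)
        d = build_lagged_design(fm, (0.0, 1.0 / FS), FS)
        np.testing.assert_array_equal(
            d.matrix, [[1, 0], [0, 1], [0, 0], [0, 0]])

    def test_600ms_at_128hz_gives_77_delays(self):
        fm = FeatureMatrix(np.zeros((2, 100)), ["a", "b"], FS)
        d = build_lagged_design(fm, (0.0, 0.6), FS)
        assert d.n_delays == 77
        assert d.matrix.shape == (100, 2 * 77)
        assert d.delay_grid[0] == 0.0

    def test_zero_features_give_zero_design(self):
        fm = FeatureMatrix(np.zeros((1, 50)), ["a"], FS)
        d = build_lagged_design(fm, (0.0, 0.1), FS)
        assert np.all(d.matrix == 0)

    def test_too_small_delay_span_rejected(self):
        fm = FeatureMatrix(np.zeros((1, 50)), ["a"], FS)
        with pytest.raises(ValueError):
            build_lagged_design(fm, (0.0, 0.0), FS)


class TestRidgeFit:
    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            d = random_design(rng)
            Y = rng.standard_normal((4, 200))
            resp = EEGRecording(Y, [f"c{i}" for i in range(4)], FS)
            model = ridge_fit(d, resp, alpha=3.0)
            X = d.matrix
            oracle = np.linalg.inv(X.T @ X + 3.0 * np.eye(30)) @ X.T @ Y.T
            fitted = model.weights.reshape(30, 4)
            assert np.max(np.abs(fitted - oracle)) < 1e-8

    def test_identity_design_interpolates_as_alpha_vanishes(self):
        n = 24
        d = LaggedDesign(np.eye(n), np.arange(8) / FS,
                         ["a", "b", "c"])
        y = np.random.default_rng(1).standard_normal((1, n))
        model = ridge_fit(d, EEGRecording(y, ["c0"], FS), alpha=1e-10)
        np.testing.assert_allclose(model.weights.reshape(n), y[0],
                                   atol=1e-6)

    def test_weights_shrink_monotonically_with_alpha(self):
        rng = np.random.default_rng(2)
        d = random_design(rng)
        resp = EEGRecording(rng.standard_normal((2, 200)), ["a", "b"], FS)
        maxima = [np.abs(ridge_fit(d, resp, a).weights).max()
                  for a in [1e0, 1e2, 1e4, 1e6]]
        assert all(m1 > m2 for m1, m2 in zip(maxima, maxima[1:]))

    def test_nonfinite_input_rejected(self):
        d = random_design(np.random.default_rng(3))
        bad = np.zeros((1, 200))
        bad[0, 5] = np.nan
        with pytest.raises(ValueError):
            ridge_fit(d, _unchecked_recording(bad), 1.0)


def _unchecked_recording(values):
    rec = EEGRecording.__new__(EEGRecording)
    rec.values = values
    rec.channel_names = ["c0"]
    rec.sampling_rate = FS
    return rec


class TestSelectAlpha:
    def test_default_grid_is_15_log_spaced_1e2_to_1e8(self):
        grid = default_alpha_grid()
        assert len(grid) == 15
        assert grid[0] == pytest.approx(1e2)
        assert grid[-1] == pytest.approx(1e8)
        np.testing.assert_allclose(np.diff(np.log10(grid)),
                                   np.log10(grid[1] / grid[0]))

    def test_noiseless_data_prefers_weak_regularization(
            self, small_noiseless_trialset):
        trials, _ = small_noiseless_trialset
        config = RidgeConfig(n_folds=4)
        alpha, per_alpha = select_alpha(trials, config)
        grid = config.alphas
        assert alpha <= grid[1]
        assert per_alpha.shape == (15,)

    def test_constant_response_degenerates_to_strongest_alpha(self,
                                                              tiny_trf):
        stims = simulate_stimulus(6, 1.0, FS, ("envelope", "pitch"), seed=1)
        from trfsize.containers import Trial
        trials = []
        for i, s in enumerate(stims):
            flat = EEGRecording(np.ones((2, s.n_samples)), ["a", "b"], FS)
            trials.append(Trial(f"t{i}", s, flat, "train"))
        config = RidgeConfig(n_folds=3)
        alpha, _ = select_alpha(trials, config)
        assert alpha == config.alphas[-1]


class TestPredictScore:
    def test_zero_features_give_zero_prediction(self, tiny_trf):
        from trfsize.encoding import fit_trials
        stims = simulate_stimulus(4, 1.0, FS, ("envelope", "pitch"), seed=2)
        recs = simulate_eeg(tiny_trf, stims, NoiseSpec(np.inf), seed=0)
        from trfsize.containers import Trial
        trials = [Trial(f"t{i}", s, r, "train")
                  for i, (s, r) in enumerate(zip(stims, recs))]
        model = fit_trials(trials, alpha=1.0)
        zero = FeatureMatrix(np.zeros((2, 100)), ["envelope", "pitch"], FS)
        assert np.all(predict(model, zero).values == 0)

    def test_prediction_with_true_weights_reproduces_noiseless_eeg(
            self, tiny_trf):
        from trfsize.encoding import TRFModel
        stims = simulate_stimulus(3, 1.5, FS, ("envelope", "pitch"), seed=3)
        recs = simulate_eeg(tiny_trf, stims, NoiseSpec(np.inf), seed=0)
        model = TRFModel(tiny_trf.weights, tiny_trf.delay_grid, 1.0,
                         list(tiny_trf.feature_names))
        for s, r in zip(stims, recs):
            pred = predict(model, s)
            assert np.max(np.abs(pred.values - r.values)) < 1e-10

    def test_homogeneity(self, tiny_trf):
        from trfsize.encoding import TRFModel
        model = TRFModel(tiny_trf.weights, tiny_trf.delay_grid, 1.0,
                         list(tiny_trf.feature_names))
        stim = simulate_stimulus(1, 1.0, FS, ("envelope", "pitch"),
                                 seed=4)[0]
        scaled = FeatureMatrix(3.0 * stim.values, stim.feature_names, FS)
        np.testing.assert_allclose(predict(model, scaled).values,
                                   3.0 * predict(model, stim).values,
                                   atol=1e-12)

    def test_rate_mismatch_rejected(self, tiny_trf):
        from trfsize.encoding import TRFModel
        model = TRFModel(tiny_trf.weights, tiny_trf.delay_grid, 1.0,
                         list(tiny_trf.feature_names))
        stim = FeatureMatrix(np.zeros((2, 64)), ["envelope", "pitch"], 64.0)
        with pytest.raises(ValueError, match="rate"):
            predict(model, stim)

    def test_score_identity_and_sign_flip(self):
        rng = np.random.default_rng(5)
        x = EEGRecording(rng.standard_normal((3, 100)),
                         ["a", "b", "c"], FS)
        r, mean_r = score(x, x)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        neg = EEGRecording(-x.values, x.channel_names, FS)
        r2, mean2 = score(neg, x)
        np.testing.assert_allclose(r2, -1.0, atol=1e-12)

    def test_score_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.standard_normal((5, 77))
        a = rng.standard_normal((5, 77))
        r, mean_r = score(EEGRecording(p, list("abcde"), FS),
                          EEGRecording(a, list("abcde"), FS))
        for c in range(5):
            cov = np.mean((p[c] - p[c].mean()) * (a[c] - a[c].mean()))
            oracle = cov / (p[c].std() * a[c].std())
            assert abs(r[c] - oracle) < 1e-12
        assert mean_r == pytest.approx(np.mean(r))

    def test_zero_variance_channel_flagged_and_excluded(self):
        p = np.vstack([np.ones(50), np.arange(50.0)])
        a = np.vstack([np.arange(50.0), np.arange(50.0)])
        r, mean_r = score(EEGRecording(p, ["flat", "ok"], FS),
                          EEGRecording(a, ["flat", "ok"], FS))
        assert np.isnan(r[0]) and r[1] == pytest.approx(1.0)
        assert mean_r == pytest.approx(1.0)

    def test_score_too_few_samples_rejected(self):
        x = EEGRecording(np.zeros((1, 2)), ["a"], FS)
        with pytest.raises(ValueError):
            score(x, x)

    def test_mean_score_invariant_to_channel_permutation(
            self, small_noiseless_trialset):
        trials, _ = small_noiseless_trialset
        res = TemporalReceptiveField(trials).fit(alpha=1.0)
        _, mean_r = res.test_scores()
        # permute channels consistently in every trial
        import copy
        perm = [2, 0, 3, 1]
        shuffled = copy.deepcopy(trials)
        for t in shuffled.trials:
            t.eeg.values = t.eeg.values[perm]
            t.eeg.channel_names = [t.eeg.channel_names[i] for i in perm]
        res2 = TemporalReceptiveField(shuffled).fit(alpha=1.0)
        _, mean_r2 = res2.test_scores()
        assert mean_r == pytest.approx(mean_r2, abs=1e-10)


class TestModelResultsInterface:
    def test_summary_reports_fit_and_test_score(
            self, small_noiseless_trialset):
        trials, _ = small_noiseless_trialset
        res = TemporalReceptiveField(trials).fit(alpha=1.0)
        text = res.summary()
        assert "alpha" in text and "test mean r" in text
        _, mean_r = res.test_scores()
        assert mean_r > 0.999  # noiseless data is fit nearly perfectly
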