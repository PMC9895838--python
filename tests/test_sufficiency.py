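"""Learning curves, knee-point detection, grand averages, weight stability."""
import numpy as np
import pytest

from trfsize.encoding import RidgeConfig, TRFModel
from trfsize.sufficiency import (GrandAverageKnee, KneeResult, LearningCurve,
                                 curvature_knee, grand_average_knee,
                                 knee_point, learning_curve,
                                 weight_stability)

FS = 128.0


def dense_curvature_argmax(f, a, b, n=20_000):
    """Brute-force oracle: |K| argmax by dense central finite differences
    on the unit-square-normalized curve."""
    x = np.linspace(a, b, n)
    y = f(x)
    u = (x - a) / (b - a)
    v = (y - y.min()) / (y.max() - y.min())
    d1 = np.gradient(v, u)
    d2 = np.gradient(d1, u)
    K = d2 / (1 + d1 ** 2) ** 1.5
    return x[int(np.argmax(np.abs(K)))]


class TestKneePoint:
    @pytest.mark.parametrize("name,f,a,b,n", [
        ("parabola", lambda x: x ** 2, -1.0, 1.0, 41),
        ("sat-exp-5", lambda x: 1 - np.exp(-x / 5.0), 1.0, 100.0, 100),
        ("sat-exp-15", lambda x: 1 - np.exp(-x / 15.0), 1.0, 100.0, 100),
        ("sat-exp-40", lambda x: 1 - np.exp(-x / 40.0), 1.0, 100.0, 100),
        ("logistic", lambda x: 1 / (1 + np.exp(-(x - 30) / 6.0)),
         25.0, 100.0, 76),
    ])
    def test_analytic_curves_match_dense_oracle(self, name, f, a, b, n):
        x = np.linspace(a, b, n)
        res = curvature_knee(x, f(x), smooth_window=5)
        oracle = dense_curvature_argmax(f, a, b)
        step = x[1] - x[0]
        assert res.valid
        assert abs(res.knee_size - oracle) <= step + 1e-9

    def test_straight_line_is_invalid(self):
        x = np.arange(50.0)
        res = curvature_knee(x, 2.0 + 0.3 * x, smooth_window=5)
        assert not res.valid
        assert "straight line" in res.reason or "zero" in res.reason

    def test_flat_curve_no_rise_is_invalid(self):
        x = np.arange(30.0)
        res = curvature_knee(x, np.full(30, 0.5), smooth_window=5)
        assert not res.valid

    def test_planted_plateau_rank_order_preserved(self):
        taus = (5.0, 15.0, 40.0)
        ordered = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            knees = []
            for tau in taus:
                x = np.arange(1.0, 101.0)
                y = 1 - np.exp(-x / tau) + rng.normal(0, 0.02, len(x))
                res = curvature_knee(x, y)  # adaptive default smoothing
                knees.append(res.knee_size if res.valid else np.nan)
            if not np.any(np.isnan(knees)) and \
                    knees[0] < knees[1] < knees[2]:
                ordered += 1
        assert ordered >= 18

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            curvature_knee(np.arange(5.0), np.arange(5.0) ** 2)

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            curvature_knee(np.arange(10.0), np.arange(10.0) ** 2,
                           smooth_window=21)

    def test_learning_curve_wrapper_reports_seconds(self):
        sizes = np.arange(10, 60)
        y = 1 - np.exp(-(sizes - 9) / 8.0)
        scores = np.tile(y[:, None], (1, 3))
        curve = LearningCurve(sizes, sizes * 2.0, scores, 3, alpha=100.0)
        res = knee_point(curve, smooth_window=7)
        assert res.valid
        assert res.knee_seconds == pytest.approx(res.knee_size * 2.0)


class TestGrandAverage:
    def test_mean_of_valid_knees(self):
        results = [KneeResult(k, None, np.empty(0), True)
                   for k in (90.0, 100.0, 98.0)]
        g = grand_average_knee(results)
        assert g.mean == pytest.approx(96.0)
        assert g.n_valid == 3 and g.n_invalid == 0

    def test_invalid_subjects_excluded_and_counted(self):
        results = [KneeResult(k, None, np.empty(0), True)
                   for k in (90.0, 100.0, 98.0)]
        results.append(KneeResult(None, None, np.empty(0), False, "flat"))
        g = grand_average_knee(results)
        assert g.mean == pytest.approx(96.0)
        assert g.n_invalid == 1

    def test_single_valid_knee_has_undefined_se(self):
        g = grand_average_knee([KneeResult(42.0, None, np.empty(0), True)])
        assert g.mean == 42.0
        assert np.isnan(g.se)

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            grand_average_knee([KneeResult(None, None, np.empty(0), False)])


def _model(weights, size):
    n_feat, n_delays, _ = weights.shape
    return TRFModel(weights, np.arange(n_delays) / FS, 1.0,
                    [f"f{i}" for i in range(n_feat)], n_train_trials=size)


class TestWeightStability:
    def test_identical_weights_correlate_perfectly(self):
        w = np.random.default_rng(0).standard_normal((2, 10, 3))
        curve = weight_stability([_model(w, 10), _model(w.copy(), 11)])
        assert curve.adjacent_r[0] == pytest.approx(1.0)
        assert curve.stabilization_size == 11.0

    def test_independent_weights_correlate_near_zero(self):
        rng = np.random.default_rng(1)
        models = [_model(rng.standard_normal((10, 100, 10)), 10 + i)
                  for i in range(3)]
        curve = weight_stability(models)
        assert np.all(np.abs(curve.adjacent_r) < 0.05)
        assert curve.stabilization_size is None

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            weight_stability([_model(rng.standard_normal((2, 10, 3)), 10),
                              _model(rng.standard_normal((2, 11, 3)), 11)])


@pytest.fixture(scope="module")
def curve_and_models(small_noisy_trialset):
    trials, _ = small_noisy_trialset
    curve, models = learning_curve(trials, start_size=5, step=2,
                                   n_boot=4, seed=7, alpha=100.0)
    return trials, curve, models


class TestLearningCurve:
    def test_replicate_counts_and_size_grid(self, curve_and_models):
        trials, curve, models = curve_and_models
        assert curve.scores.shape == (len(curve.sizes), 4)
        np.testing.assert_array_equal(
            curve.sizes, np.arange(5, len(trials.train_trials) + 1, 2))
        assert [m.n_train_trials for m in models] == list(curve.sizes)

    def test_reproducible_from_seed(self, curve_and_models):
        trials, curve, _ = curve_and_models
        again, _ = learning_curve(trials, start_size=5, step=2, n_boot=4,
                                  seed=7, alpha=100.0)
        np.testing.assert_array_equal(curve.scores, again.scores)

    def test_different_seed_changes_replicates(self, curve_and_models):
        trials, curve, _ = curve_and_models
        other, _ = learning_curve(trials, start_size=5, step=2, n_boot=4,
                                  seed=8, alpha=100.0)
        assert not np.array_equal(curve.scores, other.scores)

    def test_test_trial_order_does_not_change_scores(self,
                                                     curve_and_models):
        # reported numbers must not depend on how test trials are ordered
        from trfsize.containers import TrialSet
        trials, curve, _ = curve_and_models
        reordered = TrialSet(
            [t for t in trials.trials if t.role != "train"][::-1]
            + trials.train_trials,
            trials.sampling_rate, dict(trials.repeat_groups))
        again, _ = learning_curve(reordered, start_size=5, step=2, n_boot=4,
                                  seed=7, alpha=100.0)
        np.testing.assert_allclose(curve.scores, again.scores, atol=1e-12)

    def test_noiseless_curve_rises_monotone_in_information(
            self, small_noiseless_trialset):
        trials, _ = small_noiseless_trialset
        curve, _ = learning_curve(trials, start_size=2, step=4, n_boot=3,
                                  seed=1, alpha=1.0)
        assert curve.mean[-1] >= curve.mean[0]
        assert curve.mean[-1] > 0.95

    def test_with_replacement_mode_runs_and_differs(self, curve_and_models):
        trials, curve, _ = curve_and_models
        wr, _ = learning_curve(trials, start_size=5, step=2, n_boot=4,
                               seed=7, alpha=100.0, with_replacement=True)
        assert wr.scores.shape == curve.scores.shape
        assert not np.array_equal(wr.scores, curve.scores)

    def test_start_size_larger_than_pool_rejected(self, curve_and_models):
        trials, _, _ = curve_and_models
        with pytest.raises(ValueError):
            learning_curve(trials, start_size=10_000, alpha=100.0)


class TestSufficiencyResults:
    def test_end_to_end_summary_and_frame(self, small_noisy_trialset):
        from trfsize.sufficiency import SufficiencyAnalysis
        trials, _ = small_noisy_trialset
        res = SufficiencyAnalysis(trials, start_size=5, step=1, n_boot=4,
                                  alpha=100.0).fit(seed=3)
        frame = res.to_frame()
        assert set(frame.columns) == {"size", "seconds", "replicate",
                                      "score"}
        assert len(frame) == len(res.curve.sizes) * 4
        text = res.summary()
        assert "knee point" in text
        d = res.summary_dict()
        assert d["n_boot"] == 4
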