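import numpy as np
import pytest
from scipy import stats

from mrcpdecode.decoding import (
    OneVsOneSLDA,
    SLDAModel,
    WindowScheme,
    chance_upper_bound,
    confusion_at,
    cross_validated_curve,
    extract_window_features,
    fit_slda,
    peak_performance,
)
from mrcpdecode.io import EpochSet


def _epochs(data, labels, fs=100.0, t0=-1.5):
    data = np.asarray(data, dtype=float)
    chs = [f"ch{i}" for i in range(data.shape[1])]
    t = t0 + np.arange(data.shape[2]) / fs
    return EpochSet(data, t, chs, fs, labels=np.asarray(labels))


def _gaussian_epochs(rng, n_per_class, n_classes, n_ch=4, sep=0.0):
    """400-sample epochs on [−1.5, 2.5) with class-dependent offsets."""
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    data = rng.normal(size=(n, n_ch, 400))
    for c in range(n_classes):
        data[labels == c + 1] += sep * c
    return _epochs(data, labels)


class TestWindowScheme:
    def test_default_yields_70_end_labeled_windows(self):
        s = WindowScheme()
        times = s.window_end_times()
        assert len(times) == 70
        assert times[0] == pytest.approx(-0.95)
        assert times[-1] == pytest.approx(2.50)

    def test_halving_step_doubles_window_count(self):
        assert WindowScheme(step_s=0.025).n_windows == 140

    def test_feature_dimension(self):
        s = WindowScheme()
        assert s.n_features(33) == 330
        assert s.n_features(1) == 10

    def test_every_window_fits_inside_epoch(self, rng):
        epochs = _gaussian_epochs(rng, 3, 2)
        s = WindowScheme()
        for t in s.window_end_times():
            X = extract_window_features(epochs, t, s)
            assert X.shape == (6, 40)


class TestFeatureExtraction:
    def test_channel_identity_mapping(self):
        data = np.zeros((2, 3, 400))
        for c in range(3):
            data[:, c] = c
        epochs = _epochs(data, [1, 2])
        X = extract_window_features(epochs, 0.0)
        for c in range(3):
            np.testing.assert_array_equal(X[:, c * 10:(c + 1) * 10], c)

    def test_window_outside_epoch_rejected(self, rng):
        epochs = _gaussian_epochs(rng, 3, 2)
        with pytest.raises(ValueError):
            extract_window_features(epochs, 3.5)


class TestFitSLDA:
    def test_separable_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-1, 0.01, (20, 6)), rng.normal(1, 0.01, (20, 6))])
        y = np.repeat([0, 1], 20)
        m = fit_slda(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_full_shrinkage_weights_proportional_to_mean_difference(self, rng):
        X = rng.normal(size=(50, 8))
        y = rng.integers(0, 2, 50)
        y[:4] = [0, 0, 1, 1]
        m = fit_slda(X, y, shrinkage=1.0)
        delta = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        cos = np.dot(m.weights, delta) / np.linalg.norm(m.weights) / np.linalg.norm(delta)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_lda_oracle_at_large_n(self, rng):
        # n ≫ d Gaussian data: λ* small and w aligned with Σ⁻¹Δμ
        d, n = 5, 2000
        A = rng.normal(size=(d, d))
        cov = A @ A.T + np.eye(d)
        mu = np.array([0.5, -0.3, 0.2, 0.0, 0.1])
        Xa = rng.multivariate_normal(np.zeros(d), cov, n // 2)
        Xb = rng.multivariate_normal(mu, cov, n // 2)
        X = np.vstack([Xa, Xb])
        y = np.repeat([0, 1], n // 2)
        m = fit_slda(X, y)
        assert m.shrinkage < 0.05
        # closed-form oracle: the known Σ applied to the empirical Δμ̂, so
        # the comparison isolates the covariance/shrinkage machinery
        delta = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        w_oracle = np.linalg.solve(cov, delta)
        cos = np.dot(m.weights, w_oracle) / np.linalg.norm(m.weights) / np.linalg.norm(w_oracle)
        assert cos > 0.999

    def test_shrinkage_matches_ledoit_wolf_reference(self, rng):
        from sklearn.covariance import ledoit_wolf
        X = rng.normal(size=(60, 12)) @ rng.normal(size=(12, 12))
        y = np.repeat([0, 1], 30)
        # same-mean classes so both estimators see the same residuals
        m = fit_slda(X - X.mean(axis=0), y)
        _, lw = ledoit_wolf(X - X.mean(axis=0), assume_centered=False)
        assert m.shrinkage == pytest.approx(lw, abs=0.05)

    def test_errors(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            fit_slda(X, np.zeros(10))  # one class
        with pytest.raises(ValueError):
            fit_slda(X[:3], np.array([0, 1, 0]))  # too few trials


class TestOneVsOne:
    def test_five_classes_need_ten_models(self, rng):
        X = rng.normal(size=(50, 6))
        y = np.repeat(np.arange(5), 10)
        ovo = OneVsOneSLDA().fit(X, y)
        assert ovo.n_models == 10

    def test_unanimous_class_wins(self, rng):
        X = np.vstack([rng.normal(c * 4, 0.05, (10, 3)) for c in range(4)])
        y = np.repeat(np.arange(4), 10)
        ovo = OneVsOneSLDA().fit(X, y)
        assert ovo.predict(X[5:6])[0] == 0

    def test_cycle_tie_broken_by_summed_margin(self):
        # hand-built 3-class cycle: A>B, B>C, C>A — one vote each; the
        # winner must be the class with the largest summed signed margin
        ovo = OneVsOneSLDA()
        ovo.classes_ = np.array([0, 1, 2])
        w = np.zeros(2)

        def model(bias):
            return SLDAModel(w.copy(), bias, 0.0, 1.0, (None, None))

        # decision > 0 → second class of the pair wins
        ovo.models = {
            (0, 1): model(-1.0),   # 0 beats 1, margin 1
            (1, 2): model(-0.5),   # 1 beats 2, margin 0.5
            (0, 2): model(3.0),    # 2 beats 0, margin 3
        }
        x = np.zeros((1, 2))
        # margins: class0 = +1 − 3 = −2, class1 = −1 + 0.5 = −0.5, class2 = −0.5 + 3 = +2.5
        assert ovo.predict(x)[0] == 2
        for _ in range(3):  # deterministic across repeated calls
            assert ovo.predict(x)[0] == 2

    def test_missing_pair_detected(self, rng):
        ovo = OneVsOneSLDA()
        with pytest.raises(RuntimeError):
            ovo.predict(np.zeros((1, 2)))


class TestCrossValidatedCurve:
    def test_separable_features_flat_at_one(self, rng):
        epochs = _gaussian_epochs(rng, 12, 2, sep=30.0)
        curve = cross_validated_curve(epochs, folds=4, repetitions=1, seed=0)
        np.testing.assert_allclose(curve.accuracy, 1.0)

    def test_default_scheme_70_entries(self, rng):
        epochs = _gaussian_epochs(rng, 8, 2)
        curve = cross_validated_curve(epochs, folds=4, repetitions=1, seed=0)
        assert len(curve) == 70
        assert curve.window_time_s[0] == pytest.approx(-0.95)
        assert curve.window_time_s[-1] == pytest.approx(2.50)

    def test_deterministic_given_seed(self, rng):
        epochs = _gaussian_epochs(rng, 10, 3)
        c1 = cross_validated_curve(epochs, folds=5, repetitions=2, seed=9)
        c2 = cross_validated_curve(epochs, folds=5, repetitions=2, seed=9)
        np.testing.assert_array_equal(c1.accuracy, c2.accuracy)

    def test_shuffled_labels_within_chance_band(self, rng):
        epochs = _gaussian_epochs(rng, 20, 5, sep=2.0)
        perm = rng.permutation(epochs.n_trials)
        epochs.labels = epochs.labels[perm]
        curve = cross_validated_curve(epochs, folds=5, repetitions=2, seed=3)
        bound = chance_upper_bound(curve.n_trials, 5).bound
        assert np.mean(curve.accuracy <= bound) >= 0.95

    def test_too_small_class_rejected(self, rng):
        epochs = _gaussian_epochs(rng, 3, 2)
        with pytest.raises(ValueError, match="stratify"):
            cross_validated_curve(epochs, folds=5, repetitions=1, seed=0)


class TestPairDiscriminability:
    """Grasp-vs-grasp accuracy tracks the post-onset template difference:
    pairs generated with identical waveforms stay at chance while pairs
    with distinct shapes exceed it."""

    @staticmethod
    def _decode_pair(pair, make_identical):
        import dataclasses

        from mrcpdecode.behavior import compute_rt, compute_virtual_onsets
        from mrcpdecode.io import epoch
        from mrcpdecode.preprocess import (
            BANDPASS_MRCP,
            LOWPASS_40,
            apply_filter,
            common_average_reference,
            downsample,
            select_channels,
        )
        from mrcpdecode.synthetic import (
            BehaviorModel,
            ExperimentConfig,
            NoiseAndArtifactModel,
            generate_templates,
            simulate_subject,
        )

        cfg = ExperimentConfig(n_sessions=2)
        templates = generate_templates(cfg, effect_scale=1.0)
        if make_identical:
            temporal = templates.temporal.copy()
            temporal[pair[1] - 1] = temporal[pair[0] - 1]
            templates = dataclasses.replace(templates, temporal=temporal)
        noise = NoiseAndArtifactModel(
            blink_rate_per_min=0.0, burst_prob_per_trial=0.0, line_amp_uv=0.0
        )
        sim = simulate_subject(cfg, templates, BehaviorModel(slow_prob=0.0),
                               noise, seed=77)
        trials = compute_rt(sim.events, 1000.0)
        onsets, _ = compute_virtual_onsets(trials, 1000.0)
        rec = apply_filter(select_channels(sim.recording), LOWPASS_40)
        rec = common_average_reference(rec)
        rec = apply_filter(rec, BANDPASS_MRCP)
        rec = downsample(rec, 100.0)
        epochs = epoch(rec, onsets // 10, (-1.5, 2.5),
                       labels=trials["condition"].to_numpy())
        curve = cross_validated_curve(epochs, classes=list(pair), folds=5,
                                      repetitions=2, seed=1)
        return curve, chance_upper_bound(curve.n_trials, 2).bound

    def test_distinct_pair_decodable_identical_pair_not(self):
        distinct, bound = self._decode_pair((3, 4), make_identical=False)
        assert distinct.accuracy.max() > bound
        post = distinct.window_time_s > 0
        assert distinct.accuracy[post].mean() > bound
        identical, bound = self._decode_pair((3, 5), make_identical=True)
        # identical generating waveforms: the curve as a whole stays at
        # chance (single windows can poke above the bound by the max
        # statistic over 70 correlated windows)
        assert identical.accuracy.mean() <= bound
        assert identical.accuracy[post].mean() <= bound
        assert distinct.accuracy.max() > identical.accuracy.mean() + 0.1


class TestPeak:
    def test_monotone_curve_peaks_last(self):
        from mrcpdecode.decoding import AccuracyCurve
        c = AccuracyCurve(np.array([0.0, 0.5, 1.0]), np.array([0.3, 0.4, 0.6]),
                          np.zeros(3), 10, 2)
        assert peak_performance(c) == (0.6, 1.0)

    def test_tie_resolves_to_earliest(self):
        from mrcpdecode.decoding import AccuracyCurve
        c = AccuracyCurve(np.array([0.5, 1.0, 1.5]), np.array([0.4, 0.7, 0.7]),
                          np.zeros(3), 10, 2)
        assert peak_performance(c)[1] == 1.0

    def test_grand_peak_bounded_by_mean_subject_peak(self, rng):
        curves = rng.uniform(0.2, 0.6, size=(9, 70))
        grand_peak = curves.mean(axis=0).max()
        mean_subject_peak = curves.max(axis=1).mean()
        assert grand_peak <= mean_subject_peak


class TestConfusion:
    def test_perfect_classifier_identity(self, rng):
        epochs = _gaussian_epochs(rng, 10, 3, sep=30.0)
        cm = confusion_at(epochs, 0.0, folds=5, repetitions=2, seed=0)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        np.testing.assert_allclose(cm.tpr, 1.0)

    def test_rows_sum_to_one(self, rng):
        epochs = _gaussian_epochs(rng, 8, 4)
        cm = confusion_at(epochs, 1.0, folds=4, repetitions=1, seed=1)
        np.testing.assert_allclose(cm.normalized.sum(axis=1), 1.0, atol=1e-12)


class TestChanceBound:
    def test_large_n_limit(self):
        assert chance_upper_bound(10**8, 2).bound == pytest.approx(0.5, abs=1e-3)

    def test_decreasing_in_n(self):
        bounds = [chance_upper_bound(n, 2).bound for n in (20, 50, 100, 500)]
        assert all(a > b for a, b in zip(bounds, bounds[1:]))

    def test_matches_exact_binomial_quantile(self):
        b = chance_upper_bound(100, 2, alpha=0.05).bound
        oracle = stats.binom.ppf(0.95, 100, 0.5) / 100
        assert abs(b - oracle) < 0.02

    def test_bound_above_chance_rate(self):
        for k in (2, 5):
            for n in (20, 100, 1000):
                assert 1.0 / k < chance_upper_bound(n, k).bound < 1.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            chance_upper_bound(100, 2, alpha=0.7)
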