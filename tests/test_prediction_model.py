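import numpy as np
import pytest

from gaitbci.errors import DegenerateDataError, ParameterError
from gaitbci.io_signals import IDLE, WALK
from gaitbci.prediction_model import (
    BayesParams,
    ModelConfig,
    classify,
    crossvalidate,
    extract_feature,
    fit_aida,
    fit_bayes,
    fit_cpca,
    fit_pipeline,
    information_objective,
    optimize_band,
    posterior_walk,
    stratified_folds,
    train_model,
    training_windows,
    windows_to_features,
)


def _labels(n_idle, n_walk):
    return np.array([IDLE] * n_idle + [WALK] * n_walk)


# ---------------------------------------------------------------------------
# classwise PCA
# ---------------------------------------------------------------------------


class TestFitCpca:
    def test_exact_distinct_subspaces(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 2, 50)
        # class I along e1, class W along e2, zero global mean by symmetry
        xi = np.outer(np.concatenate([a, -a]), [1.0, 0.0])
        xw = np.outer(np.concatenate([a, -a]), [0.0, 1.0])
        X = np.vstack([xi, xw])
        y = _labels(100, 100)
        maps = fit_cpca(X, y, var_retained=0.9)
        assert maps.m == 1
        which = maps.assign(X)
        np.testing.assert_array_equal(which, [0] * 100 + [1] * 100)
        np.testing.assert_allclose(maps.reconstruction_error(X), 0, atol=1e-9)

    def test_identical_distributions_tie_to_idle(self):
        rng = np.random.default_rng(1)
        half = rng.standard_normal((40, 3))
        X = np.vstack([half, half])  # both classes are the same point set
        y = _labels(40, 40)
        maps = fit_cpca(X, y, var_retained=1.0)
        for ui, uw in zip(maps.bases[IDLE].T, maps.bases[WALK].T):
            assert abs(ui @ uw) == pytest.approx(1.0, abs=1e-9)
        assert np.all(maps.assign(X) == 0)  # ties break toward IDLE

    def test_full_rank_projection_is_isometry(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 4))
        y = _labels(30, 30)
        maps = fit_cpca(X, y, var_retained=1.0)
        Z = maps.transform(X)
        d_x = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        d_z = np.linalg.norm(Z[:, None] - Z[None, :], axis=-1)
        np.testing.assert_allclose(d_z, d_x, atol=1e-8)

    def test_rank_deficient_warns(self):
        X = np.zeros((10, 3))
        X[:5, 0] = np.arange(5)  # IDLE varies on e1 only, WALK constant
        y = _labels(5, 5)
        with pytest.warns(UserWarning, match="rank"):
            fit_cpca(X, y, var_retained=0.99)

    def test_needs_two_per_class(self):
        with pytest.raises(ParameterError):
            fit_cpca(np.zeros((3, 2)), np.array([IDLE, IDLE, WALK]))


# ---------------------------------------------------------------------------
# discriminant
# ---------------------------------------------------------------------------


class TestFitAida:
    def test_direction_recovers_mean_separation(self):
        rng = np.random.default_rng(3)
        n = 1000
        Z = np.vstack(
            [rng.standard_normal((n, 3)) - [1, 0, 0],
             rng.standard_normal((n, 3)) + [1, 0, 0]]
        )
        t = fit_aida(Z, _labels(n, n))
        angle = np.degrees(np.arccos(min(1.0, abs(t[0]))))
        assert angle < 5.0
        assert t[0] > 0  # WALK on the positive side

    def test_agrees_with_lda_for_equal_covariance(self):
        rng = np.random.default_rng(4)
        n = 800
        A = rng.standard_normal((3, 3))
        Z = np.vstack(
            [rng.standard_normal((n, 3)) @ A - [0.5, 1, 0],
             rng.standard_normal((n, 3)) @ A + [0.5, 1, 0]]
        )
        y = _labels(n, n)
        assert abs(fit_aida(Z, y, "aida") @ fit_aida(Z, y, "lda")) > 0.99

    def test_shuffled_labels_objective_is_null_typical(self):
        rng = np.random.default_rng(0)
        n = 200
        Z = rng.standard_normal((2 * n, 2))
        y = _labels(n, n)

        def objective(labels):
            zc = Z - Z.mean(axis=0)
            total = np.cov(zc, rowvar=False, bias=True)
            means, covs, priors = [], [], []
            for lab in (IDLE, WALK):
                sel = Z[labels == lab]
                means.append(sel.mean(axis=0))
                covs.append(np.cov(sel, rowvar=False, bias=True))
                priors.append(len(sel) / len(Z))
            t = fit_aida(Z, labels)
            return information_objective(t, means, covs, priors, total)

        obs = objective(rng.permutation(y))
        null = [objective(rng.permutation(y)) for _ in range(200)]
        frac_above = np.mean(np.array(null) >= obs)
        assert frac_above > 0.05  # not significant against the null

    def test_zero_between_class_scatter_raises(self):
        Z = np.tile(np.random.default_rng(6).standard_normal((30, 2)), (2, 1))
        with pytest.raises(DegenerateDataError, match="indistinguishable"):
            fit_aida(Z, _labels(30, 30))

    def test_unit_norm(self):
        rng = np.random.default_rng(7)
        Z = np.vstack(
            [rng.standard_normal((50, 4)), rng.standard_normal((50, 4)) + 2]
        )
        assert np.linalg.norm(fit_aida(Z, _labels(50, 50))) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# scalar feature
# ---------------------------------------------------------------------------


class TestExtractFeature:
    @pytest.fixture()
    def centered_pipeline(self):
        rng = np.random.default_rng(8)
        half_i = rng.standard_normal((60, 3)) - [2, 0, 0]
        half_w = rng.standard_normal((60, 3)) + [2, 0, 0]
        # exactly zero global mean: include each point and its negation
        X = np.vstack([half_i, -half_w, half_w, -half_i])
        y = _labels(120, 120)
        return fit_pipeline(X, y, ModelConfig(var_retained=1.0, discriminant="lda")), X

    def test_deterministic_definition(self, centered_pipeline):
        pipe, X = centered_pipeline
        d = X[5]
        assert extract_feature(d, pipe) == extract_feature(d, pipe)
        assert extract_feature(d, pipe) == pytest.approx(float(pipe.feature(d[None])[0]))

    def test_linearity_about_center(self, centered_pipeline):
        pipe, X = centered_pipeline
        assert pipe.cpca.mean == pytest.approx(0.0, abs=1e-12)
        d = X[7]
        assert extract_feature(2 * d, pipe) == pytest.approx(
            2 * extract_feature(d, pipe), rel=1e-9
        )

    def test_zero_vector_maps_to_zero(self, centered_pipeline):
        pipe, _ = centered_pipeline
        assert extract_feature(np.zeros(3), pipe) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Bayesian classifier
# ---------------------------------------------------------------------------


class TestBayes:
    def test_symmetric_midpoint(self):
        params = BayesParams((-1.0, 1.0), (1.0, 1.0), (0.5, 0.5))
        assert posterior_walk(0.0, params) == pytest.approx(0.5)

    def test_monotone_posterior(self):
        params = BayesParams((-1.0, 1.0), (1.0, 1.0), (0.5, 0.5))
        f = np.linspace(-5, 5, 101)
        p = posterior_walk(f, params)
        assert np.all(np.diff(p) > 0)
        assert p[-1] > 0.99

    def test_empirical_priors(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal(100)
        y = np.array([IDLE] * 30 + [WALK] * 70)
        assert fit_bayes(f, y).priors == pytest.approx((0.3, 0.7))

    def test_tie_goes_to_walk(self):
        params = BayesParams((-1.0, 1.0), (1.0, 1.0), (0.5, 0.5))
        assert classify(0.0, params) == WALK
        assert classify(-0.1, params) == IDLE
        assert classify(0.1, params) == WALK


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


class TestCrossvalidate:
    def test_separable_classes_perfect(self):
        rng = np.random.default_rng(10)
        X = np.vstack(
            [rng.standard_normal((100, 2)) * 0.1 - [3, 0],
             rng.standard_normal((100, 2)) * 0.1 + [3, 0]]
        )
        rep = crossvalidate(X, _labels(100, 100), ModelConfig(seed=0))
        assert rep.mean_accuracy == 100.0

    def test_identical_distributions_chance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((400, 3))
        rep = crossvalidate(X, _labels(200, 200), ModelConfig(seed=0))
        assert rep.mean_accuracy == pytest.approx(50.0, abs=5.0)

    def test_stratification_within_one_sample(self):
        y = _labels(83, 117)
        for fold in stratified_folds(y, 10, seed=1):
            frac = np.mean(y[fold] == WALK)
            assert abs(frac * len(fold) - 117 / 200 * len(fold)) <= 1.0

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(12)
        X = np.vstack(
            [rng.standard_normal((60, 4)), rng.standard_normal((60, 4)) + 0.8]
        )
        y = _labels(60, 60)
        cfg = ModelConfig(seed=3, discriminant="lda", var_retained=1.0)
        base = crossvalidate(X, y, cfg)
        perm = rng.permutation(4)
        permuted = crossvalidate(X[:, perm], y, cfg)
        assert permuted.fold_accuracies == pytest.approx(base.fold_accuracies)

    def test_rescaling_invariance_when_normalized(self):
        rng = np.random.default_rng(13)
        X = np.vstack(
            [rng.standard_normal((60, 4)), rng.standard_normal((60, 4)) + 0.8]
        )
        y = _labels(60, 60)
        cfg = ModelConfig(seed=3, discriminant="lda", var_retained=1.0,
                          variance_normalize=True)
        base = crossvalidate(X, y, cfg)
        scaled = crossvalidate(X * [2.0, 0.5, 7.0, 1.0], y, cfg)
        assert scaled.fold_accuracies == pytest.approx(base.fold_accuracies)


# ---------------------------------------------------------------------------
# band optimization
# ---------------------------------------------------------------------------


def _tone_windows(tones, n_per_class=120, n_ch=2, rate=128.0, seed=0):
    """Raw windows with class-modulated tones given as (freq, amp) pairs."""
    rng = np.random.default_rng(seed)
    n_t = int(0.75 * rate)
    t = np.arange(n_t) / rate
    windows, labels = [], []
    for label, gain in ((IDLE, 1.0), (WALK, 3.0)):
        for _ in range(n_per_class):
            w = rng.standard_normal((n_ch, n_t))
            for f0, amp in tones:
                w[0] += amp * gain * np.sin(
                    2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)
                )
            windows.append(w)
            labels.append(label)
    return np.stack(windows), np.array(labels), rate


class TestOptimizeBand:
    def test_expands_to_cover_signal_band(self):
        # weak tone inside the seed band, strong tone just above it
        windows, labels, rate = _tone_windows([(9.0, 0.3), (11.0, 1.5)])
        band, rep = optimize_band(
            windows, labels, rate, ModelConfig(seed=2, band=(8.0, 10.0))
        )
        assert band[0] <= 8.0 and band[1] >= 12.0
        assert rep.mean_accuracy > 90.0

    def test_no_signal_stays_at_seed_band(self):
        # chance-level CV fluctuations stay under the 0.5-pp tolerance at
        # this sample size and seed, so the greedy search stops immediately
        rng = np.random.default_rng(2)
        windows = rng.standard_normal((400, 2, 96))
        labels = _labels(200, 200)
        band, _ = optimize_band(
            windows, labels, 128.0, ModelConfig(seed=2, band=(8.0, 10.0))
        )
        assert band == (8.0, 10.0)

    def test_disjoint_bands_returns_contiguous(self):
        windows, labels, rate = _tone_windows([(11.0, 1.0), (25.0, 1.0)])
        band, _ = optimize_band(
            windows, labels, rate, ModelConfig(seed=2, band=(10.0, 12.0))
        )
        assert band[0] <= 10.0 or band[1] >= 26.0  # contains >= 1 signal band
        assert band[1] - band[0] >= 2.0

    def test_too_narrow_seed_band(self):
        with pytest.raises(ParameterError):
            optimize_band(
                np.zeros((4, 1, 96)), _labels(2, 2), 128.0,
                ModelConfig(band=(8.0, 9.0)),
            )


# ---------------------------------------------------------------------------
# end-to-end training
# ---------------------------------------------------------------------------


class TestTrainModel:
    def test_strong_fixture_high_accuracy(self, strong_model):
        assert strong_model.cv_report.mean_accuracy >= 90.0

    def test_salience_map_peaks_on_modulated_channel(self, strong_model, strong_cfg):
        sal = strong_model.salience_map()[WALK]
        _, c = np.unravel_index(np.argmax(sal), sal.shape)
        modulated = {f"CH{i:02d}" for i in strong_cfg.modulated_channels}
        assert strong_model.retained_channels[c] in modulated

    def test_serialization_round_trip(self, tmp_path, strong_model, strong_training):
        path = tmp_path / "model.json"
        strong_model.save(path)
        from gaitbci.prediction_model import PredictionModel

        back = PredictionModel.load(path)
        rec, cues = strong_training
        windows, _ = training_windows(rec.pick(back.retained_channels), cues)
        p0 = strong_model.posterior_from_windows(windows[:20], rec.rate)
        p1 = back.posterior_from_windows(windows[:20], rec.rate)
        np.testing.assert_allclose(p1, p0, rtol=1e-12)

    def test_window_count(self, strong_training):
        rec, cues = strong_training
        windows, labels = training_windows(rec, cues)
        assert windows.shape[0] == 800  # 20 epochs x 40 windows
        assert (labels == WALK).sum() == 400

    def test_feature_dimensions(self, strong_training):
        rec, cues = strong_training
        windows, _ = training_windows(rec, cues)
        X, edges = windows_to_features(windows[:4], rec.rate, (8.0, 12.0))
        assert X.shape == (4, 2 * rec.n_channels)
        np.testing.assert_allclose(edges, [8.0, 10.0, 12.0])
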