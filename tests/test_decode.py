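"""Decoder correctness: LDA posteriors, CV schemes, interpolation, LCMV."""

import numpy as np
import pytest
from scipy import stats as sps

from mvinfo.containers import (
    ConfusionTensor,
    EpochedData,
    circular_difference,
)
from mvinfo.decode import (
    CVScheme,
    ShrinkageLDA,
    accuracy_timecourse,
    crossvalidated_confusion,
    interpolate_confusion,
    lcmv_filters,
    searchlight_decode,
    stratify_oversample,
    subsample_units,
)
from mvinfo.synthdata import (
    CONFIG_A,
    CONFIG_B,
    MixingModel,
    PopulationConfig,
    generate_stimulus_stream,
    simulate_session,
    simulate_tuned_responses,
)


def bayes_posterior_oracle(X_train, y_train, X_test, shrinkage):
    """Independent Gaussian-Bayes oracle: direct density evaluation.

    Pooled within-class covariance, the same shrinkage target, then
    per-class multivariate-normal densities normalized across classes.
    """
    classes = np.unique(y_train)
    n, p = X_train.shape
    means = np.stack([X_train[y_train == c].mean(axis=0) for c in classes])
    resid = np.concatenate(
        [X_train[y_train == c] - means[i] for i, c in enumerate(classes)]
    )
    cov = resid.T @ resid / (n - classes.size)
    cov = (1 - shrinkage) * cov + shrinkage * np.trace(cov) / p * np.eye(p)
    dens = np.stack(
        [sps.multivariate_normal(mean=m, cov=cov).pdf(X_test) for m in means],
        axis=-1,
    )
    dens = np.atleast_2d(dens)
    return dens / dens.sum(axis=1, keepdims=True)


class TestShrinkageLDA:
    def test_posteriors_match_bayes_oracle_on_toy_problem(self):
        # 4 classes, 8 trials, 2 integer features
        X = np.array(
            [[0, 0], [1, 0], [5, 0], [6, 1], [0, 5], [1, 6], [5, 5], [6, 6]],
            dtype=float,
        )
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        Xt = np.array([[0.5, 0.5], [5.5, 0.2], [3.0, 3.0], [0.0, 6.0]])
        model = ShrinkageLDA(shrinkage=0.2).fit(X, y)
        expected = bayes_posterior_oracle(X, y, Xt, 0.2)
        assert np.allclose(model.predict_proba(Xt), expected, atol=1e-8)

    def test_separable_classes_saturate_posterior(self, rng):
        X = np.concatenate(
            [rng.normal(0, 0.1, (200, 2)), rng.normal(20, 0.1, (200, 2))]
        )
        y = np.repeat([0, 1], 200)
        model = ShrinkageLDA(0.1).fit(X, y)
        p = model.predict_proba(np.array([[0.0, 0.0]]))
        assert p[0, 0] > 0.999999

    def test_collinear_features_fit_with_shrinkage(self, rng):
        base = rng.normal(size=(30, 2))
        X = np.hstack([base, base])  # perfect collinearity
        y = np.repeat([0, 1, 2], 10)
        ShrinkageLDA(0.1).fit(X, y)  # must not raise

    def test_singular_covariance_error_advises_shrinkage(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        y = np.array([0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="shrinkage > 0"):
            ShrinkageLDA(0.0).fit(X, y)

    def test_midpoint_between_two_near_classes_splits_evenly(self):
        X = np.array(
            [[0.0, 0], [0.2, 0], [4.0, 0], [3.8, 0], [100.0, 50], [99.8, 50]]
        )
        y = np.array([0, 0, 1, 1, 2, 2])
        model = ShrinkageLDA(0.05).fit(X, y)
        p = model.predict_proba(np.array([[2.0, 0.0]]))[0]
        assert p[0] == pytest.approx(p[1], abs=1e-9)
        assert p[2] < 1e-6

    def test_probabilities_sum_to_one(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 4, 40)
        model = ShrinkageLDA(0.3).fit(X, y)
        p = model.predict_proba(rng.normal(size=(15, 3)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert p.min() >= 0

    def test_agrees_with_sklearn_lda_at_zero_shrinkage(self, rng):
        # independent cross-check against sklearn's eigen-solver LDA
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 3, 60)
        ours = ShrinkageLDA(0.0).fit(X, y).predict_proba(X)
        ref = (
            LinearDiscriminantAnalysis(solver="svd", priors=[1 / 3] * 3)
            .fit(X, y)
            .predict_proba(X)
        )
        # sklearn pools with 1/n rather than 1/(n-k); posteriors still agree
        # because a common covariance rescaling shifts all discriminants alike
        assert np.allclose(np.argmax(ours, 1), np.argmax(ref, 1))


class TestStratifyOversample:
    def test_balanced_input_unchanged(self):
        labels = np.repeat([0, 1], 8)
        pos = np.tile([1, 2], 8)
        folds = np.tile([0, 0, 1, 1], 4)
        out = stratify_oversample(labels, pos, folds, seed=0)
        assert sorted(np.concatenate(out)) == sorted(range(16))

    def test_cells_filled_to_fold_maximum(self):
        labels = np.array([0] * 3 + [1] * 5)
        pos = np.ones(8, dtype=int)
        folds = np.zeros(8, dtype=int)
        out = stratify_oversample(labels, pos, folds, seed=0)
        assert out[0].size == 10  # both cells at size 5, 2 duplicates added
        aug_labels = labels[out[0]]
        assert (aug_labels == 0).sum() == (aug_labels == 1).sum() == 5

    def test_duplicates_never_cross_folds(self):
        labels = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        pos = np.ones(8, dtype=int)
        folds = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        out = stratify_oversample(labels, pos, folds, seed=1)
        assert set(out[0]) <= {0, 1, 2, 3}
        assert set(out[1]) <= {4, 5, 6, 7}

    def test_empty_cell_reported_by_name(self):
        labels = np.array([0, 0, 1, 1])
        pos = np.array([1, 1, 1, 2])
        folds = np.zeros(4, dtype=int)
        with pytest.raises(ValueError, match="stimulus=0, position=2"):
            stratify_oversample(labels, pos, folds, seed=0)


class TestCrossvalidatedConfusion:
    def test_rows_sum_to_one_everywhere(self, color_session):
        conf = crossvalidated_confusion(
            color_session, "color", CVScheme(n_folds=2, seed=0)
        )
        assert np.allclose(conf.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_noise_free_separable_classes_decode_perfectly(self):
        pop = PopulationConfig(tuned_feature="color", noise_sd=0.01, kappa=4.0)
        ep = simulate_session(CONFIG_B, [pop], n_events=320, seed=3)
        conf = crossvalidated_confusion(ep, "color", CVScheme(n_folds=2, seed=0))
        peak = np.einsum("tkk->tk", conf.probs).mean(axis=1).max()
        assert peak > 0.999

    def test_shuffled_labels_sit_at_chance(self, rng):
        ep = simulate_session(CONFIG_B, [PopulationConfig()], n_events=1000, seed=8)
        tr = ep.trials.copy()
        tr["color_angle"] = tr["color_angle"].to_numpy()[
            rng.permutation(len(tr))
        ]
        shuffled = EpochedData(ep.data, ep.time, tr, ep.channels)
        conf = crossvalidated_confusion(shuffled, "color", CVScheme(10, seed=0))
        mean_acc = np.einsum("tkk->tk", conf.probs).mean()
        assert mean_acc == pytest.approx(1 / 8, abs=0.01)

    def test_class_relabelling_permutes_confusion(self, color_session):
        conf = crossvalidated_confusion(
            color_session, "color", CVScheme(n_folds=2, seed=3)
        )
        angles = np.sort(np.unique(color_session.labels("color")))
        perm = np.roll(np.arange(8), 3)
        mapping = dict(zip(angles, angles[perm]))
        tr = color_session.trials.copy()
        tr["color_angle"] = tr["color_angle"].map(mapping)
        relabelled = EpochedData(
            color_session.data, color_session.time, tr, color_session.channels
        )
        conf2 = crossvalidated_confusion(
            relabelled, "color", CVScheme(n_folds=2, seed=3)
        )
        assert np.allclose(
            conf2.probs[:, perm][:, :, perm], conf.probs, atol=1e-10
        )

    def test_too_few_trials_per_class_rejected(self):
        ep = simulate_session(CONFIG_B, [PopulationConfig()], n_events=70, seed=0)
        with pytest.raises(ValueError, match="fold"):
            crossvalidated_confusion(ep, "color", CVScheme(n_folds=10, seed=0))

    def test_seed_determinism(self, color_session):
        a = crossvalidated_confusion(color_session, "color", CVScheme(2, seed=5))
        b = crossvalidated_confusion(color_session, "color", CVScheme(2, seed=5))
        assert np.array_equal(a.probs, b.probs)


class TestSubsampleUnits:
    def test_five_channels_equal_direct_decoding(self):
        ep = simulate_session(
            CONFIG_B, [PopulationConfig(n_units=5)], n_events=320, seed=4
        )
        scheme = CVScheme(n_folds=2, seed=0)
        sub = subsample_units(ep, feature="color", scheme=scheme, seed=0)
        direct = crossvalidated_confusion(ep, "color", scheme)
        assert sub.meta["n_combos"] == 1
        assert np.allclose(sub.probs, direct.probs)

    def test_six_channels_enumerate_all_six_combos(self):
        ep = simulate_session(
            CONFIG_B, [PopulationConfig(n_units=6)], n_events=320, seed=5
        )
        sub = subsample_units(ep, feature="color", scheme=CVScheme(2, seed=0), seed=0)
        assert sub.meta["n_combos"] == 6

    def test_many_channels_capped_at_forty_distinct_combos(self):
        ep = simulate_session(
            CONFIG_B, [PopulationConfig(n_units=12, noise_sd=2.0)],
            n_events=160, seed=6,
        )
        sub = subsample_units(ep, feature="color", scheme=CVScheme(2, seed=0), seed=7)
        sub2 = subsample_units(ep, feature="color", scheme=CVScheme(2, seed=0), seed=7)
        assert sub.meta["n_combos"] == 40
        assert np.array_equal(sub.probs, sub2.probs)

    def test_too_few_channels_rejected(self):
        ep = simulate_session(
            CONFIG_B, [PopulationConfig(n_units=4)], n_events=160, seed=0
        )
        with pytest.raises(ValueError):
            subsample_units(ep, feature="color", scheme=CVScheme(2, seed=0))


class TestInterpolateConfusion:
    def test_uniform_stays_uniform(self):
        probs = np.full((3, 12, 12), 1 / 12)
        conf = ConfusionTensor(probs, np.arange(3.0), CONFIG_A.class_angles)
        out = interpolate_confusion(conf)
        assert out.probs.shape == (3, 8, 8)
        assert np.allclose(out.probs, 1 / 8)

    def test_smooth_kernel_survives_regridding(self):
        ang12 = CONFIG_A.class_angles

        def build(angles):
            m = 1 + 0.5 * np.cos(
                np.deg2rad(circular_difference(angles[None, :], angles[:, None]))
            )
            return m / m.sum(axis=1, keepdims=True)

        conf12 = ConfusionTensor(
            build(ang12)[None], np.zeros(1), ang12
        )
        out = interpolate_confusion(conf12)
        expected = build(45.0 * np.arange(8))
        assert np.abs(out.probs[0] - expected).max() < 0.03

    def test_rows_renormalized(self, rng):
        probs = rng.uniform(0.01, 1.0, size=(2, 12, 12))
        probs /= probs.sum(axis=2, keepdims=True)
        out = interpolate_confusion(
            ConfusionTensor(probs, np.arange(2.0), CONFIG_A.class_angles)
        )
        assert np.allclose(out.probs.sum(axis=2), 1.0, atol=1e-12)

    def test_wrong_class_count_rejected(self):
        conf = ConfusionTensor(
            np.full((1, 8, 8), 1 / 8), np.zeros(1), CONFIG_B.class_angles
        )
        with pytest.raises(ValueError, match="12"):
            interpolate_confusion(conf)


class TestAccuracyTimecourse:
    def test_identity_matrices_score_one(self):
        probs = np.repeat(np.eye(8)[None], 4, axis=0)
        tc = accuracy_timecourse(
            ConfusionTensor(probs, np.arange(4.0), CONFIG_B.class_angles)
        )
        assert np.allclose(tc.values, 1.0)

    def test_uniform_matrices_score_chance(self):
        probs = np.full((4, 8, 8), 1 / 8)
        tc = accuracy_timecourse(
            ConfusionTensor(probs, np.arange(4.0), CONFIG_B.class_angles)
        )
        assert np.allclose(tc.values, 0.125)
        assert tc.chance == 0.125

    def test_matches_direct_diagonal_means(self, rng):
        probs = rng.uniform(size=(5, 8, 8))
        probs /= probs.sum(axis=2, keepdims=True)
        tc = accuracy_timecourse(
            ConfusionTensor(probs, np.arange(5.0), CONFIG_B.class_angles)
        )
        expected = [np.mean([probs[t, k, k] for k in range(8)]) for t in range(5)]
        assert np.allclose(tc.values, expected)


class TestLcmv:
    def test_identity_leadfield_identity_covariance(self):
        model = MixingModel(np.eye(4), np.arange(4))
        w = lcmv_filters(model, np.eye(4))
        assert np.allclose(w, np.eye(4))

    def test_unit_gain_constraint_random_leadfield(self, rng):
        gain = rng.normal(size=(5, 12))
        model = MixingModel(gain, np.arange(5))
        cov = rng.normal(size=(12, 12))
        cov = cov @ cov.T + 0.1 * np.eye(12)
        w = lcmv_filters(model, cov, regularization=0.01)
        assert np.allclose(np.einsum("sc,sc->s", w, gain), 1.0, atol=1e-9)

    def test_single_source_reconstruction(self, rng):
        # one active source; its filter output should track it best
        n_sens, n_src, n_samp = 12, 4, 2000
        gain = rng.normal(size=(n_src, n_sens))
        src = np.zeros((n_src, n_samp))
        src[1] = rng.normal(size=n_samp)
        sens = gain.T @ src + 0.01 * rng.normal(size=(n_sens, n_samp))
        cov = np.cov(sens)
        w = lcmv_filters(MixingModel(gain, np.arange(n_src)), cov, 0.001)
        recon = w @ sens
        corrs = [abs(np.corrcoef(recon[s], src[1])[0, 1]) for s in range(n_src)]
        assert corrs[1] > 0.99
        assert corrs[1] == max(corrs)

    def test_singular_covariance_rejected(self):
        model = MixingModel(np.eye(3), np.arange(3))
        with pytest.raises(ValueError):
            lcmv_filters(model, np.zeros((3, 3)))


class TestSearchlight:
    @staticmethod
    def _source_session(shapes, seed=0, n_events=320):
        pops = [
            PopulationConfig(
                area=f"src{i}", n_units=1, signal_class="SOURCE",
                tuned_feature="color", tuning_shape=s,
            )
            for i, s in enumerate(shapes)
        ]
        ep = simulate_session(CONFIG_B, pops, n_events=n_events, seed=seed)
        ch = ep.channels.copy()
        ch["position"] = np.linspace(0, 1, len(shapes))
        return EpochedData(ep.data, ep.time, ep.trials, ch)

    def test_full_group_gives_identical_timecourses(self):
        ep = self._source_session(["unimodal"] * 4, seed=1)
        res = searchlight_decode(ep, CVScheme(2, seed=0), group_size=4)
        ref = res[0][0].values
        for tc, _ in res[1:]:
            assert np.allclose(tc.values, ref)

    def test_untuned_sources_stay_at_chance(self):
        ep = self._source_session(["untuned"] * 4, seed=2, n_events=640)
        res = searchlight_decode(ep, CVScheme(2, seed=0), group_size=1)
        for tc, _ in res:
            assert abs(tc.values.mean() - 0.125) < 0.01

    def test_information_localizes_to_tuned_sources(self):
        ep = self._source_session(
            ["unimodal", "unimodal", "untuned", "untuned"], seed=3, n_events=640
        )
        res = searchlight_decode(ep, CVScheme(2, seed=0), group_size=1)
        peaks = [tc.values.max() for tc, _ in res]
        assert min(peaks[:2]) > max(peaks[2:])

    def test_oversized_group_rejected(self):
        ep = self._source_session(["unimodal"] * 3, seed=4)
        with pytest.raises(ValueError):
            searchlight_decode(ep, CVScheme(2, seed=0), group_size=5)
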