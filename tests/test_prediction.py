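"""Family-aware splits, nested model selection, permutation significance."""

import numpy as np
import pytest

from fmripredict import (
    BehaviorPrediction,
    CohortConfig,
    ModelSpec,
    evaluate_feature_target,
    fit_predict_one_split,
    generate_cohort,
    make_family_splits,
    permutation_test,
    r_squared,
)

SMALL_KRR = ModelSpec("krr", grid={"alpha": [0.1, 1.0, 10.0]})
SMALL_ENET = ModelSpec("elasticnet_reg", grid={"alpha": [0.001, 0.1, 1.0], "l1_ratio": [0.5]})


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_negative_value(self):
        # y={0,1,2}, yhat=0: 1 - 5/2 = -1.5
        assert r_squared([0, 1, 2], [0, 0, 0]) == pytest.approx(-1.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [0.0, 2.0])


class TestFamilySplits:
    def test_singleton_families_exact_test_size(self):
        ids = list(range(100))
        fams = [f"f{i}" for i in range(100)]
        scheme = make_family_splits(ids, fams, n_outer_splits=5, test_fraction=0.15, seed=1)
        for tr, te in scheme.splits:
            assert len(te) == 15
            assert len(tr) == 85
            assert not set(tr) & set(te)

    def test_families_never_straddle(self):
        rng = np.random.default_rng(3)
        fams = []
        f = 0
        while len(fams) < 60:
            size = int(rng.integers(1, 6))
            fams.extend([f"f{f}"] * size)
            f += 1
        fams = fams[:60]
        ids = list(range(60))
        scheme = make_family_splits(ids, fams, n_outer_splits=10, seed=4)
        for tr, te in scheme.splits:
            train_fams = {fams[i] for i in tr}
            test_fams = {fams[i] for i in te}
            assert not train_fams & test_fams

    def test_single_family_rejected(self):
        with pytest.raises(ValueError):
            make_family_splits(list(range(8)), ["f0"] * 8, n_outer_splits=2, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_family_splits([1, 2], ["a", "b"], test_fraction=1.5)

    def test_seed_determinism(self):
        ids = list(range(40))
        fams = [f"f{i // 2}" for i in range(40)]
        a = make_family_splits(ids, fams, seed=9)
        b = make_family_splits(ids, fams, seed=9)
        for (tra, tea), (trb, teb) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)


class TestFitPredictOneSplit:
    def _linear_problem(self, n=80, dim=5, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, dim))
        w = np.zeros(dim)
        w[:3] = [2.0, -1.0, 0.5]
        y = x @ w + noise * rng.normal(size=n)
        return x[:60], y[:60], x[60:], y[60:]

    def test_realizable_linear_target(self):
        xtr, ytr, xte, yte = self._linear_problem()
        fit = fit_predict_one_split(xtr, ytr, xte, yte, SMALL_ENET)
        assert fit.score >= 0.99

    def test_permuted_target_near_chance(self):
        # Monte-Carlo over 20 seeds: shuffled targets should not be
        # predictable; mean test R^2 stays at or below ~0
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            xtr, ytr, xte, yte = self._linear_problem(seed=seed)
            ytr = rng.permutation(ytr)
            yte = rng.permutation(yte)
            fit = fit_predict_one_split(xtr, ytr, xte, yte, SMALL_KRR)
            scores.append(fit.score)
        assert np.mean(scores) <= 0.05

    def test_scaler_and_hyperparameters_ignore_test_rows(self):
        xtr, ytr, xte, yte = self._linear_problem(noise=0.5, seed=2)
        fit1 = fit_predict_one_split(xtr, ytr, xte, yte, SMALL_ENET)
        fit2 = fit_predict_one_split(
            xtr, ytr, xte + 100.0, yte, SMALL_ENET
        )
        assert fit1.best_params == fit2.best_params
        np.testing.assert_array_equal(fit1.scaler_mean, fit2.scaler_mean)
        np.testing.assert_array_equal(fit1.scaler_scale, fit2.scaler_scale)

    def test_constant_target_rejected(self):
        xtr, ytr, xte, yte = self._linear_problem()
        with pytest.raises(ValueError, match="constant"):
            fit_predict_one_split(xtr, np.ones_like(ytr), xte, yte, SMALL_KRR)

    def test_classifier_accuracy_on_separable_data(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(120, 4))
        y = (x[:, 0] > 0).astype(int)
        fit = fit_predict_one_split(
            x[:80], y[:80], x[80:], y[80:], ModelSpec("svm", grid={"C": [1.0]})
        )
        assert fit.score >= 0.9


class TestPermutationTest:
    def _problem(self, n=60, dim=6, seed=0, signal=True):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, dim))
        y = x[:, 0] * 2 + 0.3 * rng.normal(size=n) if signal else rng.normal(size=n)
        fams = [f"f{i}" for i in range(n)]
        scheme = make_family_splits(list(range(n)), fams, n_outer_splits=4, seed=seed)
        return x, y, scheme

    def test_null_size_and_summary_consistency(self):
        x, y, scheme = self._problem()
        result, null = permutation_test(x, y, scheme, SMALL_KRR, n_permutations=5)
        assert null.null_scores.shape == (20,)
        s = result.per_split_scores
        assert result.mean == pytest.approx(np.mean(s))
        assert result.sd == pytest.approx(np.std(s, ddof=1))
        assert result.median == pytest.approx(np.median(s))
        assert result.q1 == pytest.approx(np.percentile(s, 25))
        assert result.q3 == pytest.approx(np.percentile(s, 75))

    def test_strong_signal_is_significant(self):
        x, y, scheme = self._problem(signal=True)
        result, null = permutation_test(x, y, scheme, SMALL_KRR, n_permutations=10)
        assert result.per_split_scores.min() > null.null_scores.max()
        assert result.significant
        assert result.p_value == pytest.approx(1.0 / 41.0)

    def test_invalid_permutation_count(self):
        x, y, scheme = self._problem()
        with pytest.raises(ValueError):
            permutation_test(x, y, scheme, SMALL_KRR, n_permutations=0)


def test_monotone_in_effect_size():
    """Increasing the generator's effect size must not decrease the mean
    test R^2 of the informative feature (fixed seeds, deterministic)."""
    means = []
    for effect in (0.0, 0.3, 0.6):
        cfg = CohortConfig(
            n_subjects=60, n_regions=10, n_sessions=1, frames_per_session=80,
            n_communities=2, seed=17,
        )
        cfg.effect_size_per_target = {**cfg.effect_size_per_target, "cognition": effect}
        cohort = generate_cohort(cfg)
        result, _ = evaluate_feature_target(
            cohort, "fc", "cognition", SMALL_KRR,
            n_outer_splits=3, seed=17,
        )
        means.append(result.mean)
    assert means[0] <= means[1] <= means[2]


def test_behavior_prediction_model_surface():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(50, 5))
    y = x[:, 1] + 0.2 * rng.normal(size=50)
    fams = [f"f{i // 2}" for i in range(50)]
    model = BehaviorPrediction(
        x, y, fams, model=SMALL_KRR, n_outer_splits=4, seed=2,
        feature_name="fc", target_name="cognition",
    )
    res = model.fit(n_permutations=3)
    assert res.null.null_scores.size == 12
    assert res.mean_score == pytest.approx(res.per_split_scores.mean())
    text = res.summary()
    assert "cognition" in text and "krr" in text
    frame = res.summary_frame()
    assert frame.loc[0, "mean"] == pytest.approx(res.mean_score)
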