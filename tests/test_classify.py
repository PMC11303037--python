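import numpy as np
import pytest
from scipy.stats import binom, multivariate_normal

from otolunar import classify as clf
from otolunar.classify import (
    ConfusionMatrix,
    adjacency_fraction,
    assign_cohort,
    compare_distributions,
    fit,
    loocv,
    predict,
    predict_many,
)
from otolunar.lunar import QUARTER_ORDER, LunarQuarter

NEW, WAXING, FULL, WANING = QUARTER_ORDER


def bayes_oracle(Xtr, ytr, x, prior="equal"):
    """Brute-force Gaussian-density Bayes posterior, independent of the
    package's discriminant implementation."""
    Xtr = np.asarray(Xtr, dtype=float)
    center = Xtr.mean(axis=0)
    scale = Xtr.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (Xtr - center) / scale
    z = (np.asarray(x, dtype=float) - center) / scale
    classes = list(QUARTER_ORDER)
    n, p = Z.shape
    pooled = np.zeros((p, p))
    means, counts = [], []
    for q in classes:
        Zi = Z[[l == q for l in ytr]]
        means.append(Zi.mean(axis=0))
        counts.append(len(Zi))
        D = Zi - Zi.mean(axis=0)
        pooled += D.T @ D
    pooled /= n - len(classes)
    pri = np.ones(4) / 4 if prior == "equal" else np.array(counts) / n
    dens = np.array(
        [multivariate_normal.pdf(z, mean=m, cov=pooled, allow_singular=True) for m in means]
    )
    post = dens * pri
    return post / post.sum()


def four_class_data(rng, n_per=20, p=3, sep=4.0):
    centers = rng.normal(scale=sep, size=(4, p))
    X, y = [], []
    for q, c in zip(QUARTER_ORDER, centers):
        X.append(c + rng.normal(size=(n_per, p)))
        y.extend([q] * n_per)
    return np.vstack(X), y


class TestFit:
    def test_missing_class(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        y = [NEW] * 6 + [WAXING] * 3 + [FULL] * 3
        with pytest.raises(ValueError, match="WANING"):
            fit(X, y)

    def test_small_class(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        y = [NEW] * 4 + [WAXING] * 3 + [FULL] * 2 + [WANING]
        with pytest.raises(ValueError, match="WANING"):
            fit(X, y)

    def test_nan_rejected(self):
        rng = np.random.default_rng(0)
        X, y = four_class_data(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit(X, y)

    def test_duplicated_rows_give_identical_posteriors(self):
        rng = np.random.default_rng(1)
        X, y = four_class_data(rng)
        m1 = fit(X, y)
        m2 = fit(np.vstack([X, X]), y + y)
        x = rng.normal(size=X.shape[1])
        _, p1 = predict(m1, x)
        _, p2 = predict(m2, x)
        # sufficiency up to degrees-of-freedom conventions: the duplicated fit
        # differs only through the (n-1)/(n-k) divisors, vanishing in n
        np.testing.assert_allclose(m2.class_means, m1.class_means, rtol=1e-2)
        np.testing.assert_allclose(p2, p1, atol=5e-2)

    def test_priors_sum_to_one(self):
        rng = np.random.default_rng(2)
        X, y = four_class_data(rng, n_per=7)
        model = fit(X, y)
        assert model.training_priors.sum() == pytest.approx(1.0)

    def test_singular_covariance_regularized(self):
        rng = np.random.default_rng(3)
        X, y = four_class_data(rng, n_per=5, p=2)
        X = np.column_stack([X, X[:, 0]])  # exactly collinear trait
        model = fit(X, y)  # should succeed via ridge
        _, post = predict(model, X[0])
        assert post.sum() == pytest.approx(1.0)


class TestPredict:
    def test_class_mean_strongly_assigned(self):
        rng = np.random.default_rng(4)
        X, y = four_class_data(rng, sep=10.0)
        model = fit(X, y)
        for i, q in enumerate(model.class_labels):
            x = model.center + model.class_means[i] * model.scale
            pred, post = predict(model, x)
            assert pred is q
            assert post[i] > 0.99

    def test_midpoint_symmetric_posteriors(self):
        # two near classes, two very distant ones; probe at the near midpoint
        X, y = [], []
        rng = np.random.default_rng(5)
        for q, mu in zip(QUARTER_ORDER, [-1.0, 1.0, 100.0, -100.0]):
            X.append(mu + 0.5 * rng.normal(size=(25, 1)))
            y.extend([q] * 25)
        X = np.vstack(X)
        model = fit(X, y)
        mid = 0.5 * (
            (model.center + model.class_means[0] * model.scale)
            + (model.center + model.class_means[1] * model.scale)
        )
        _, post = predict(model, mid)
        assert post[0] == pytest.approx(post[1], rel=1e-9)
        assert post[2] + post[3] < 1e-6

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(6)
        X, y = four_class_data(rng)
        model = fit(X, y)
        _, post = predict_many(model, rng.normal(size=(20, X.shape[1])))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_training_prior_can_flip_borderline_call(self):
        # oracle-built borderline case: unbalanced classes, probe at the
        # equal-prior decision boundary between the two near classes
        rng = np.random.default_rng(7)
        X, y = [], []
        for q, mu, n in zip(QUARTER_ORDER, [-1.0, 1.0, 50.0, -50.0], [90, 10, 10, 10]):
            X.append(mu + 0.8 * rng.normal(size=(n, 1)))
            y.extend([q] * n)
        X = np.vstack(X)
        model = fit(X, y)
        mid = 0.5 * (
            (model.center + model.class_means[0] * model.scale)
            + (model.center + model.class_means[1] * model.scale)
        )
        # nudge toward the rare class so equal prior picks it
        x = mid + 0.05 * (model.class_means[1] - model.class_means[0]) * model.scale
        pred_eq, post_eq = predict(model, x, prior="equal")
        pred_tr, post_tr = predict(model, x, prior="training")
        assert pred_eq is WAXING
        assert pred_tr is NEW  # 9:1 training prior overrides the nudge
        np.testing.assert_allclose(post_eq, bayes_oracle(X, y, x, "equal"), atol=1e-8)
        np.testing.assert_allclose(post_tr, bayes_oracle(X, y, x, "training"), atol=1e-8)

    def test_prior_monotonicity(self):
        rng = np.random.default_rng(8)
        X, y = four_class_data(rng, n_per=30)
        # unbalance class 0 upward: training prior for NEW > 1/4
        X = np.vstack([X, X[:30] + 0.01])
        y = y + [NEW] * 30
        model = fit(X, y)
        for _ in range(20):
            x = rng.normal(size=X.shape[1])
            _, p_eq = predict(model, x, prior="equal")
            _, p_tr = predict(model, x, prior="training")
            assert p_tr[0] >= p_eq[0] - 1e-12  # raising NEW's prior never lowers it

    def test_nan_rejected(self):
        rng = np.random.default_rng(9)
        X, y = four_class_data(rng)
        model = fit(X, y)
        with pytest.raises(ValueError, match="NaN"):
            predict(model, np.full(X.shape[1], np.nan))


class TestBayesOracleEquivalence:
    def test_fifty_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = int(rng.integers(1, 4))
            n_per = int(rng.integers(4, 12))
            X, y = four_class_data(rng, n_per=n_per, p=p, sep=float(rng.uniform(0.5, 5)))
            model = fit(X, y)
            for prior in ("equal", "training"):
                x = rng.normal(size=p)
                _, post = predict(model, x, prior=prior)
                np.testing.assert_allclose(post, bayes_oracle(X, y, x, prior), atol=1e-8)


class TestLoocv:
    def test_perfect_separation(self):
        rng = np.random.default_rng(11)
        X, y = four_class_data(rng, n_per=12, sep=50.0)
        acc, cm, preds = loocv(X, y)
        assert acc == 1.0
        assert np.trace(cm.counts) == cm.n == len(y)
        assert all(p is not None for p in preds)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(12)
        X, y = four_class_data(rng, n_per=50, sep=5.0)
        y_perm = list(rng.permutation([q.name for q in y]))
        acc, _, _ = loocv(X, y_perm)
        n = len(y_perm)
        # never significantly ABOVE chance; LOOCV is pessimistically biased
        # under permuted labels (the held-out fish pulls its class mean away),
        # so allow a margin below the binomial interval
        hi = binom.ppf(0.995, n, 0.25) / n
        assert 0.10 <= acc <= hi

    def test_loocv_not_better_than_resubstitution(self):
        rng = np.random.default_rng(13)
        diffs = []
        for _ in range(20):
            X, y = four_class_data(rng, n_per=15, sep=1.5)
            acc_cv, _, _ = loocv(X, y)
            model = fit(X, y)
            preds, _ = predict_many(model, X)
            acc_resub = np.mean([a is b for a, b in zip(preds, y)])
            diffs.append(acc_resub - acc_cv)
        assert np.mean(diffs) >= 0
        assert min(diffs) >= -0.1  # no fold pathology

    def test_small_class_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(11, 2))
        y = [NEW] * 3 + [WAXING] * 3 + [FULL] * 3 + [WANING] * 2
        with pytest.raises(ValueError, match="3"):
            loocv(X, y)


class TestConfusion:
    def test_adjacency_all_adjacent(self):
        c = np.diag([5, 5, 5, 5])
        c[0, 1] = 3  # NEW -> WAXING
        assert adjacency_fraction(ConfusionMatrix(c)) == 1.0

    def test_adjacency_all_opposite(self):
        c = np.diag([5, 5, 5, 5])
        c[0, 2] = 2  # NEW -> FULL
        assert adjacency_fraction(ConfusionMatrix(c)) == 0.0

    def test_adjacency_hand_count(self):
        c = np.diag([5, 5, 5, 5])
        c[0, 1] = 3  # adjacent
        c[0, 2] = 1  # opposite
        assert adjacency_fraction(ConfusionMatrix(c)) == pytest.approx(0.75)

    def test_no_misclassifications_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            adjacency_fraction(ConfusionMatrix(np.diag([5, 5, 5, 5])))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.full((4, 4), -1))


class TestAssignCohort:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(15)
        X, y = four_class_data(rng)
        model = fit(X, y)
        props = assign_cohort(model, rng.normal(size=(30, X.shape[1])))
        assert props.sum() == pytest.approx(1.0)

    def test_clones_are_degenerate(self):
        rng = np.random.default_rng(16)
        X, y = four_class_data(rng, sep=10.0)
        model = fit(X, y)
        props = assign_cohort(model, np.tile(X[0], (10, 1)))
        assert sorted(props) == pytest.approx([0, 0, 0, 1])

    def test_empty_rejected(self):
        rng = np.random.default_rng(17)
        X, y = four_class_data(rng)
        model = fit(X, y)
        with pytest.raises(ValueError, match="non-empty"):
            assign_cohort(model, np.empty((0, X.shape[1])))


class TestCompareDistributions:
    def test_identical(self):
        assert compare_distributions([0.25] * 4, [0.25] * 4) == 0.0

    def test_disjoint(self):
        assert compare_distributions([1, 0, 0, 0], [0, 1, 0, 0]) == 1.0

    def test_hand_sum(self):
        # 0.5 * (0.15 + 0.05 + 0.05 + 0.15) = 0.2
        assert compare_distributions(
            [0.4, 0.3, 0.2, 0.1], [0.25, 0.25, 0.25, 0.25]
        ) == pytest.approx(0.2)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([0.5, 0.5, 0.5, 0.5], [0.25] * 4)
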