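import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pipmorph.lda import (
    LabelledFeatures,
    classify,
    f_to_enter,
    f_to_remove,
    fit_lda,
    loocv,
    stepwise_select,
    tolerance,
    wilks_lambda,
)


def two_group_1d():
    """Hand-checkable case: groups {0, 1} vs {10, 11} on one variable."""
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array(["a", "a", "b", "b"])
    return LabelledFeatures(X, y)


def gaussian_two_class(rng, n_per_class, p=6, delta=2.0):
    """Shared-covariance classes separated by Mahalanobis delta on axis 0."""
    Xa = rng.standard_normal((n_per_class, p))
    Xb = rng.standard_normal((n_per_class, p))
    Xb[:, 0] += delta
    X = np.vstack([Xa, Xb])
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return LabelledFeatures(X, y)


class TestWilksLambda:
    def test_hand_example(self):
        # W = 0.5 + 0.5 = 1, T = 101 -> lambda = 1/101
        assert wilks_lambda(two_group_1d(), [0]) == pytest.approx(1 / 101)

    def test_equal_group_means_lambda_one(self):
        X = np.array([[1.0], [3.0], [1.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        assert wilks_lambda(LabelledFeatures(X, y), [0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_manova_eigenvalue_identity(self, seed):
        # lambda = prod 1/(1+eig_i) with eig_i the eigenvalues of W^-1 B
        rng = np.random.default_rng(seed)
        data = gaussian_two_class(rng, 30, p=4)
        data = LabelledFeatures(
            np.vstack([data.X, rng.standard_normal((30, 4)) + 1.0]),
            np.concatenate([data.y, ["c"] * 30]),
        )
        subset = [0, 1, 2]
        from pipmorph.lda import _sscp

        W, T = _sscp(data)
        Ws = W[np.ix_(subset, subset)]
        Bs = (T - W)[np.ix_(subset, subset)]
        eigs = np.linalg.eigvals(np.linalg.solve(Ws, Bs)).real
        expected = np.prod(1.0 / (1.0 + eigs))
        assert wilks_lambda(data, subset) == pytest.approx(expected)

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            wilks_lambda(two_group_1d(), [])


class TestFStatistics:
    def test_hand_example_equals_anova_f(self):
        # lambda = 1/101 with n=4, g=2, p=0 -> F = 2 * 100 = 200,
        # identical to the one-way ANOVA F = (100/1)/(1/2)
        assert f_to_enter(two_group_1d(), [], 0) == pytest.approx(200.0)

    def test_enter_remove_consistency(self, rng):
        data = gaussian_two_class(rng, 40, p=4)
        f_in = f_to_enter(data, [1, 2], 0)
        f_out = f_to_remove(data, [0, 1, 2], 0)
        assert f_in == pytest.approx(f_out)

    def test_duplicate_variable_has_zero_tolerance(self, rng):
        data = gaussian_two_class(rng, 30, p=3)
        X = np.column_stack([data.X, data.X[:, 0]])
        dup = LabelledFeatures(X, data.y)
        assert tolerance(dup, [0], 3) == pytest.approx(0.0, abs=1e-10)
        # and stepwise never enters it
        selected, _ = stepwise_select(dup, f_enter=0.1, f_remove=0.01)
        assert not (0 in selected and 3 in selected)

    def test_null_rejection_rate_matches_f_distribution(self):
        # P(F > 3.84) for one candidate, two groups of 50 from the same
        # Gaussian, is the F(1, 98) tail, about 0.053.
        rng = np.random.default_rng(99)
        n_rep, hits = 2000, 0
        for _ in range(n_rep):
            X = rng.standard_normal((100, 1))
            y = np.array(["a"] * 50 + ["b"] * 50)
            if f_to_enter(LabelledFeatures(X, y), [], 0) > 3.84:
                hits += 1
        from scipy.stats import f as f_dist

        expected = f_dist.sf(3.84, 1, 98)
        assert hits / n_rep == pytest.approx(expected, abs=0.012)

    def test_insufficient_dof_raises(self, rng):
        # n - g - p = 5 - 3 - 2 = 0 residual degrees of freedom
        X = rng.standard_normal((5, 3))
        y = np.array(["a", "a", "b", "b", "c"])
        with pytest.raises(ValueError, match="degrees of freedom"):
            f_to_enter(LabelledFeatures(X, y), [0, 1], 2)


class TestStepwiseSelect:
    def test_informative_feature_entered_first(self, rng):
        n = 100
        X = rng.standard_normal((2 * n, 5))
        X[n:, 0] += 5.0
        y = np.array(["a"] * n + ["b"] * n)
        selected, trace = stepwise_select(LabelledFeatures(X, y))
        assert selected[0] == 0
        assert trace[0].action == "enter" and trace[0].variable == 0

    def test_no_entry_when_threshold_infinite(self, rng):
        data = gaussian_two_class(rng, 30, p=4, delta=0.0)
        selected, _ = stepwise_select(data, f_enter=np.inf)
        assert selected == []

    @pytest.mark.parametrize("seed", range(4))
    def test_each_entry_maximises_f_exhaustively(self, seed):
        rng = np.random.default_rng(seed)
        g = 3 if seed % 2 else 2
        parts = []
        labels = []
        for j in range(g):
            block = rng.standard_normal((25, 6))
            block[:, j % 6] += 1.5
            parts.append(block)
            labels += [f"g{j}"] * 25
        data = LabelledFeatures(np.vstack(parts), np.array(labels))
        selected, trace = stepwise_select(data)
        model = []
        for ev in trace:
            if ev.action == "remove":
                model.remove(ev.variable)
                continue
            if ev.action != "enter":
                continue
            fs = {
                j: f_to_enter(data, model, j)
                for j in range(data.p)
                if j not in model and tolerance(data, model, j) >= 0.001
            }
            best = max(fs, key=fs.get)
            assert ev.variable == best
            assert ev.f_statistic == pytest.approx(fs[best])
            assert fs[best] > 3.84
            model.append(best)
        assert model == selected

    def test_wilks_lambda_non_increasing_at_entries(self, rng):
        data = gaussian_two_class(rng, 60, p=8, delta=1.5)
        _, trace = stepwise_select(data)
        lams = [ev.wilks for ev in trace if ev.action == "enter"]
        assert all(b <= a + 1e-12 for a, b in zip(lams, lams[1:]))

    def test_affine_stability(self, rng):
        data = gaussian_two_class(rng, 50, p=5)
        scaled = LabelledFeatures(data.X * [10.0, 0.2, 1.0, 5.0, 1.0], data.y)
        sel_a, tr_a = stepwise_select(data)
        sel_b, tr_b = stepwise_select(scaled)
        assert sel_a == sel_b
        for ea, eb in zip(tr_a, tr_b):
            assert ea.f_statistic == pytest.approx(eb.f_statistic)
        ma = fit_lda(data, sel_a)
        mb = fit_lda(scaled, sel_b)
        ra = classify(ma, data.X)
        rb = classify(mb, scaled.X)
        assert np.array_equal(ra.labels, rb.labels)


class TestFitAndClassify:
    def test_symmetric_groups_boundary_at_zero(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_lda(LabelledFeatures(X, y), [0])
        res = classify(model, np.array([[-0.01], [0.01]]))
        assert list(res.labels) == ["a", "b"]

    def test_group_means_classified_to_own_group(self, rng):
        data = gaussian_two_class(rng, 50, p=4, delta=8.0)
        model = fit_lda(data, list(range(4)))
        res = classify(model, model.group_means)
        assert list(res.labels) == list(model.groups)
        assert np.all(np.max(res.posteriors, axis=1) > 0.99)

    def test_posterior_matches_gaussian_bayes(self, rng):
        data = gaussian_two_class(rng, 40, p=3, delta=1.0)
        sel = [0, 1, 2]
        model = fit_lda(data, sel)
        x = rng.standard_normal((5, 3))
        res = classify(model, x)
        inv = np.linalg.inv(model.pooled_cov)
        for i in range(5):
            logd = np.array(
                [
                    -0.5 * (x[i] - mu) @ inv @ (x[i] - mu) + np.log(pi)
                    for mu, pi in zip(model.group_means, model.priors)
                ]
            )
            e = np.exp(logd - logd.max())
            np.testing.assert_allclose(
                res.posteriors[i], e / e.sum(), atol=1e-10
            )

    def test_agreement_with_mahalanobis_classifier(self, rng):
        data = gaussian_two_class(rng, 100, p=5, delta=1.0)
        model = fit_lda(data, list(range(5)))
        x = rng.standard_normal((200, 5)) + 1.0
        res = classify(model, x)
        inv = np.linalg.inv(model.pooled_cov)
        d2 = np.array(
            [
                [(xi - mu) @ inv @ (xi - mu) for mu in model.group_means]
                for xi in x
            ]
        )
        expected = model.groups[np.argmin(d2, axis=1)]
        assert np.array_equal(res.labels, expected)

    def test_tie_broken_toward_lowest_group_index(self):
        X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_lda(LabelledFeatures(X, y), [0])
        res = classify(model, np.array([[0.0]]))
        assert res.labels[0] == "a"

    def test_nonfinite_sample_excluded(self, rng):
        data = gaussian_two_class(rng, 20, p=2, delta=5.0)
        model = fit_lda(data, [0, 1])
        x = np.array([[0.0, 0.0], [np.nan, 1.0]])
        res = classify(model, x)
        assert res.excluded == [1]
        assert res.labels[1] is None
        assert res.labels[0] is not None

    def test_agreement_with_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        data = gaussian_two_class(rng, 80, p=6, delta=1.5)
        model = fit_lda(data, list(range(6)), priors="proportional")
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(data.X, data.y)
        x = rng.standard_normal((100, 6)) + 0.7
        ours = classify(model, x)
        # sklearn scales the pooled covariance by n rather than n - g; the
        # argmax is invariant to that scale, so predicted labels must agree
        assert np.array_equal(ours.labels, sk.predict(x))

    def test_singular_covariance_raises(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(np.linalg.LinAlgError, match="fewer features"):
            fit_lda(LabelledFeatures(X, y), [0, 1])


class TestLOOCV:
    def test_separated_classes_perfect_accuracy(self, rng):
        data = gaussian_two_class(rng, 30, p=3, delta=100.0)
        res = loocv(data, [0, 1, 2])
        assert res.accuracy == 1.0
        assert res.confusion.values.diagonal().sum() == 60

    def test_matches_naive_refit_loop(self, rng):
        data = gaussian_two_class(rng, 30, p=4, delta=1.0)
        fast = loocv(data, [0, 1, 2, 3])
        naive = []
        for i in range(data.n):
            keep = np.arange(data.n) != i
            sub = LabelledFeatures(data.X[keep], data.y[keep])
            model = fit_lda(sub, [0, 1, 2, 3])
            naive.append(classify(model, data.X[i : i + 1]).labels[0])
        assert np.array_equal(fast.assigned, np.array(naive, dtype=object))

    def test_accuracy_matches_bayes_rate(self):
        # two Gaussian classes, shared covariance, Delta = 2 -> Phi(1);
        # averaged over replicates so Monte-Carlo error is ~0.008
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            data = gaussian_two_class(rng, 400, p=6, delta=2.0)
            accs.append(loocv(data, list(range(6))).accuracy)
        assert np.mean(accs) == pytest.approx(norm.cdf(1.0), abs=0.03)

    def test_loocv_not_above_resubstitution_on_average(self):
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            data = gaussian_two_class(rng, 20, p=4, delta=1.0)
            sel = list(range(4))
            cv = loocv(data, sel).accuracy
            model = fit_lda(data, sel)
            resub = np.mean(classify(model, data.X).labels == data.y)
            diffs.append(resub - cv)
        assert np.mean(diffs) >= 0

    def test_reselection_mode_matches_naive_loop(self, rng):
        data = gaussian_two_class(rng, 15, p=3, delta=2.0)
        res = loocv(data, reselect=True)
        naive = []
        for i in range(data.n):
            keep = np.arange(data.n) != i
            sub = LabelledFeatures(data.X[keep], data.y[keep])
            sel, _ = stepwise_select(sub)
            model = fit_lda(sub, sel)
            naive.append(classify(model, data.X[i : i + 1]).labels[0])
        assert np.array_equal(res.assigned, np.array(naive, dtype=object))

    def test_empty_selection_classifies_by_priors(self, rng):
        data = gaussian_two_class(rng, 10, p=2, delta=0.0)
        res = loocv(data, [])
        assert res.accuracy == pytest.approx(0.5)
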