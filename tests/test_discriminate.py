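"""MANOVA, canonical variates, Mahalanobis classification, typicality."""

import io
import math

import numpy as np
import pytest
from scipy import stats

from wingid._geometry import preshape
from wingid.discriminate import (
    classify,
    fit_cva,
    load_reference_set,
    save_reference_set,
    typicality,
    wilks_manova,
)
from wingid.superimposition import gpa
from wingid.synthetic_wings import (
    BASE_WING,
    SyntheticSpec,
    make_taxon_means,
    sample_dataset,
    shape_subspace,
)


class TestWilksManova:
    def test_univariate_two_group_equals_t_statistic(self, rng):
        """For p=1, g=2: lambda = 1 / (1 + t^2/(n-2)), and Rao's F is exact."""
        x1 = rng.normal(0.0, 1.0, 14)
        x2 = rng.normal(0.7, 1.0, 11)
        X = np.concatenate([x1, x2])[:, None]
        labels = ["a"] * 14 + ["b"] * 11
        res = wilks_manova(X, labels, max_rank=1)
        t_stat, p_t = stats.ttest_ind(x1, x2)
        n = 25
        assert res.wilks_lambda == pytest.approx(1.0 / (1.0 + t_stat**2 / (n - 2)), abs=1e-10)
        assert res.p_value == pytest.approx(p_t, abs=1e-10)
        assert res.df1 == 1 and res.df2 == n - 2

    def test_permuted_labels_give_uniform_p_values(self):
        """Under the null (labels shuffled) p-values are approximately uniform."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 4))
        labels = ["A"] * 20 + ["B"] * 20
        pvals = []
        for _ in range(500):
            perm = rng.permutation(40)
            pvals.append(wilks_manova(X, [labels[i] for i in perm], max_rank=4).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_lambda_in_unit_interval_and_monotone_in_separation(self, rng):
        lams = []
        for shift in (0.0, 1.0, 3.0):
            X = rng.standard_normal((60, 3))
            X[30:] += shift
            labels = ["A"] * 30 + ["B"] * 30
            res = wilks_manova(X, labels, max_rank=3)
            assert 0.0 < res.wilks_lambda <= 1.0
            lams.append(res.wilks_lambda)
        assert lams[0] > lams[1] > lams[2]

    def test_singleton_class_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="'B'"):
            wilks_manova(X, ["A", "A", "A", "A", "B"], max_rank=3)


class TestFitCva:
    def test_two_groups_give_single_axis(self, small_labelled_shapes):
        X, labels, consensus = small_labelled_shapes
        keep = [i for i, l in enumerate(labels) if l in ("A", "B")]
        model = fit_cva(X[keep], [labels[i] for i in keep], consensus=consensus, max_rank=4)
        assert model.canonical_axes.shape[1] == 1
        assert model.eigenvalues.shape == (1,)

    def test_eigenvalues_match_dense_generalized_solve(self, small_labelled_shapes):
        """Non-symmetric dense eig of pinv(W) @ B reproduces the canonical eigenvalues."""
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        class_labels = sorted(set(labels))
        grand = X.mean(axis=0)
        p = X.shape[1]
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        for lab in class_labels:
            sub = X[[i for i, l in enumerate(labels) if l == lab]]
            dev = sub - sub.mean(axis=0)
            W += dev.T @ dev
            B += len(sub) * np.outer(sub.mean(axis=0) - grand, sub.mean(axis=0) - grand)
        dense = np.linalg.eigvals(np.linalg.pinv(W, rcond=1e-8) @ B)
        dense = np.sort(np.real(dense))[::-1][: model.eigenvalues.size]
        np.testing.assert_allclose(model.eigenvalues, dense, atol=1e-8)

    def test_identical_clouds_have_no_between_signal(self, rng):
        X = rng.standard_normal((30, 5))
        X2 = np.vstack([X, X])
        labels = ["A"] * 30 + ["B"] * 30
        model = fit_cva(X2, labels, max_rank=5)
        assert model.eigenvalues[0] < 1e-8

    def test_canonical_scores_standardized(self, small_labelled_shapes):
        """Unit pooled within-class variance per axis; diagonal between-class scatter."""
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        scores = (X - model.grand_mean) @ model.canonical_axes
        g = len(model.class_labels)
        n = X.shape[0]
        pooled = np.zeros((scores.shape[1], scores.shape[1]))
        for lab in model.class_labels:
            sub = scores[[i for i, l in enumerate(labels) if l == lab]]
            dev = sub - sub.mean(axis=0)
            pooled += dev.T @ dev
        pooled /= n - g
        np.testing.assert_allclose(pooled, np.eye(scores.shape[1]), atol=1e-6)
        means = np.array(
            [scores[[i for i, l in enumerate(labels) if l == lab]].mean(axis=0)
             for lab in model.class_labels]
        )
        between = np.cov(means.T, ddof=0) if means.shape[1] > 1 else None
        if between is not None:
            off = between - np.diag(np.diag(between))
            assert np.abs(off).max() < 1e-6

    def test_wilks_lambda_factorizes_over_eigenvalues(self):
        """lambda = prod 1/(1+l_i): MANOVA and CVA consume identical reduced variables."""
        spec = SyntheticSpec(
            taxa=(("A", 20), ("B", 20), ("C", 20)), separation=3.0, seed=9, bilateral=False
        )
        fit = gpa([r.right for r in sample_dataset(spec)])
        manova = wilks_manova(fit)
        model = fit_cva(fit)
        assert manova.log_wilks_lambda == pytest.approx(
            -float(np.sum(np.log1p(model.eigenvalues))), abs=1e-8
        )

    def test_mahalanobis_between_means_reconstructed_from_canonical_scores(
        self, small_labelled_shapes
    ):
        """Class-mean separations in canonical space equal pooled-Mahalanobis distances."""
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        for i in range(len(model.class_labels)):
            for j in range(len(model.class_labels)):
                canonical = float(
                    ((model.class_means_cv[i] - model.class_means_cv[j]) ** 2).sum()
                )
                diff = (model.class_means[i] - model.class_means[j]) @ model.basis
                dense = float((diff**2 / model.within_eigvals).sum())
                assert canonical == pytest.approx(dense, abs=1e-8)


class TestClassify:
    def test_class_mean_classified_to_itself(self, small_labelled_shapes):
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        for i, lab in enumerate(model.class_labels):
            res = classify(model, model.class_means[i])
            assert res.predicted == lab
            assert res.distances[lab] < 1e-16
            assert res.typicality[lab] == pytest.approx(1.0)

    def test_identity_covariance_reduces_to_nearest_mean(self):
        """With identity pooled covariance, Mahalanobis = Euclidean nearest mean."""
        rng = np.random.default_rng(21)
        centers = rng.uniform(-4, 4, size=(4, 6))
        devs = [rng.standard_normal((50, 6)) for _ in centers]
        devs = [d - d.mean(axis=0) for d in devs]
        pooled = sum(d.T @ d for d in devs) / (200 - 4)
        evals, evecs = np.linalg.eigh(pooled)
        whiten = evecs @ np.diag(evals**-0.5) @ evecs.T  # pooled covariance -> exactly I
        X = np.vstack([c + d @ whiten for c, d in zip(centers, devs)])
        labels = [f"c{i}" for i in range(4) for _ in range(50)]
        model = fit_cva(X, labels, max_rank=6)
        np.testing.assert_allclose(model.within_eigvals, 1.0, atol=1e-10)
        queries = rng.uniform(-5, 5, size=(1000, 6))
        class_means = np.array([X[50 * i : 50 * (i + 1)].mean(axis=0) for i in range(4)])
        for q in queries:
            nearest = f"c{int(np.argmin(((class_means - q) ** 2).sum(axis=1)))}"
            assert classify(model, q).predicted == nearest

    def test_distances_match_dense_pseudoinverse_oracle(self, small_labelled_shapes):
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        class_labels = model.class_labels
        n, g = X.shape[0], len(class_labels)
        p = X.shape[1]
        W = np.zeros((p, p))
        for lab in class_labels:
            sub = X[[i for i, l in enumerate(labels) if l == lab]]
            dev = sub - sub.mean(axis=0)
            W += dev.T @ dev
        S_inv = np.linalg.pinv(W / (n - g), rcond=1e-8)
        for row in X[:10]:
            res = classify(model, row)
            for i, lab in enumerate(class_labels):
                diff = row - model.class_means[i]
                dense = float(diff @ S_inv @ diff)
                assert res.distances[lab] == pytest.approx(dense, abs=1e-8)

    def test_invariant_to_similarity_transform_of_query(self, rng):
        spec = SyntheticSpec(
            taxa=(("A", 15), ("B", 15)), separation=4.0, seed=2, bilateral=False
        )
        fit = gpa([r.right for r in sample_dataset(spec)])
        model = fit_cva(fit)
        query = BASE_WING + rng.normal(0, 0.003, BASE_WING.shape)
        base = classify(model, query)
        theta = rng.uniform(-np.pi, np.pi)
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = 3.1 * query @ rot.T + [40.0, -7.0]
        res = classify(model, moved)
        assert res.predicted == base.predicted
        for lab in model.class_labels:
            assert abs(res.distances[lab] - base.distances[lab]) < 1e-6

    def test_landmark_count_mismatch_rejected(self, small_labelled_shapes):
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        with pytest.raises(ValueError, match="landmarks"):
            classify(model, BASE_WING)  # 15 landmarks vs 4-landmark model

    def test_agrees_with_sklearn_lda(self):
        """Independent cross-check: equal-prior LDA makes the same assignments."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(31)
        centers = rng.uniform(-3, 3, size=(3, 5))
        X = np.vstack([c + rng.standard_normal((40, 5)) @ np.diag([1, 2, 0.5, 1, 1.5])
                       for c in centers])
        labels = [f"c{i}" for i in range(3) for _ in range(40)]
        model = fit_cva(X, labels, max_rank=5)
        lda = sklearn.LinearDiscriminantAnalysis(priors=[1 / 3] * 3, solver="svd")
        lda.fit(X, labels)
        queries = rng.uniform(-4, 4, size=(300, 5))
        ours = [classify(model, q).predicted for q in queries]
        theirs = list(lda.predict(queries))
        # the argmin is invariant to the scalar factor between covariance estimators
        assert ours == theirs


class TestTypicality:
    def test_class_mean_has_typicality_one(self, small_labelled_shapes):
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        probs, ambiguous = typicality(model, model.class_means[0])
        assert probs[model.class_labels[0]] == pytest.approx(1.0)

    def test_far_outlier_flagged(self, small_labelled_shapes):
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        far = model.grand_mean + 50.0 * (X[0] - model.grand_mean)
        probs, ambiguous = typicality(model, far)
        assert max(probs.values()) < 1e-6
        assert ambiguous

    def test_null_draws_have_uniform_typicality(self):
        """Specimens from a class's own distribution score uniform typicality."""
        k6 = BASE_WING[:6]
        spec = SyntheticSpec(
            taxa=(("A", 600), ("B", 600)), base_shape=k6, separation=5.0,
            within_sd=0.01, digitization_sd=0.0, bilateral=False, seed=11,
        )
        recs = sample_dataset(spec)
        configs = [r.right for r in recs]
        fit = gpa(configs)
        model = fit_cva(fit.coordinate_matrix(), [c.taxon for c in configs],
                        consensus=fit.consensus, max_rank=8)
        mean = make_taxon_means(spec)["A"]
        mean_pre = preshape(mean)
        basis = shape_subspace(mean)
        rng = np.random.default_rng(123)
        probs = []
        for _ in range(2000):
            z = spec.within_sd * rng.standard_normal(8)
            raw = mean_pre + (basis @ z).reshape(-1, 2)
            probs.append(classify(model, raw).typicality["A"])
        assert stats.kstest(probs, "uniform").pvalue > 0.01


class TestReferenceSet:
    def test_round_trip_preserves_classification(self, small_labelled_shapes, tmp_path):
        X, labels, consensus = small_labelled_shapes
        model = fit_cva(X, labels, consensus=consensus, max_rank=4)
        path = tmp_path / "reference.json"
        save_reference_set(model, path)
        loaded = load_reference_set(path)
        assert loaded.class_labels == model.class_labels
        for row in X[:20]:
            a = classify(model, row)
            b = classify(loaded, row)
            assert a.predicted == b.predicted
            assert a.distances == b.distances
            assert a.typicality == b.typicality

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="format"):
            load_reference_set(path)
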