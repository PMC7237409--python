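import numpy as np
import pytest

import molarmorph as mm
from molarmorph.classify import KnnModel


def two_groups(rng, n=30, sep=10.0, d=3):
    x = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    labels = np.array(["a"] * n + ["b"] * n)
    return x, labels


class TestPcaReduce:
    def test_rank_cap_with_warning(self, rng):
        low = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 10))
        with pytest.warns(UserWarning, match="rank"):
            space = mm.pca_reduce(low, n_components=10)
        assert space.n_components == 3

    def test_full_reconstruction(self, rng):
        x = rng.normal(size=(15, 6))
        space = mm.pca_reduce(x, n_components=6)
        rec = space.scores @ space.basis.T + space.mean
        np.testing.assert_allclose(rec, x, atol=1e-8)

    def test_variance_fraction_rule(self, rng):
        # spectrum ~ (0.6, 0.3, 0.08, 0.02): 95% needs 3 components
        n = 4000
        z = rng.normal(size=(n, 4)) * np.sqrt([0.6, 0.3, 0.08, 0.02])
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        space = mm.pca_reduce(z @ q, variance_fraction=0.95)
        assert space.n_components == 3

    def test_group_size_cap(self, rng):
        x = rng.normal(size=(12, 30))
        space = mm.pca_reduce(x, variance_fraction=0.999, n_groups=3)
        assert space.n_components <= 12 - 3 - 1

    def test_basis_orthonormal_and_evr_sorted(self, rng):
        x = rng.normal(size=(40, 8))
        space = mm.pca_reduce(x, n_components=5)
        np.testing.assert_allclose(space.basis.T @ space.basis, np.eye(5), atol=1e-8)
        assert np.all(np.diff(space.explained_variance_ratio) <= 1e-12)


class TestLda:
    def test_symmetric_boundary_is_perpendicular_bisector(self, rng):
        x, labels = two_groups(rng, n=50, sep=4.0, d=2)
        model = mm.lda_fit(x, labels)
        probes = rng.normal(2.0, 3.0, size=(50, 2))
        mu_a, mu_b = model.means
        closed_form = np.where(
            np.linalg.norm(probes - mu_a, axis=1) < np.linalg.norm(probes - mu_b, axis=1),
            "a",
            "b",
        )
        # spherical-ish data: compare against Mahalanobis-based calls instead
        ci = np.linalg.inv(model.pooled_cov)
        maha = [
            np.sum((probes - mu) @ ci * (probes - mu), axis=1) for mu in model.means
        ]
        oracle = model.groups[np.argmin(maha, axis=0)]
        np.testing.assert_array_equal(model.classify(probes), oracle)
        # and the Euclidean bisector agrees except near the boundary
        agree = np.mean(model.classify(probes) == closed_form)
        assert agree > 0.9

    def test_duplicating_specimens_leaves_boundary_unchanged(self, rng):
        x, labels = two_groups(rng, n=20, sep=3.0)
        m1 = mm.lda_fit(x, labels)
        m2 = mm.lda_fit(np.vstack([x, x]), np.concatenate([labels, labels]))
        probes = rng.normal(1.5, 2.0, size=(40, 3))
        np.testing.assert_array_equal(m1.classify(probes), m2.classify(probes))

    def test_matches_sklearn_predictions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x = np.vstack(
            [rng.normal(0, 1, (25, 4)), rng.normal(2, 1, (25, 4)), rng.normal([0, 3, 0, 0], 1, (25, 4))]
        )
        labels = np.repeat(["a", "b", "c"], 25)
        ours = mm.lda_fit(x, labels)
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(x, labels)
        probes = rng.normal(1.0, 2.0, size=(60, 4))
        assert np.mean(ours.classify(probes) == sk.predict(probes)) > 0.98

    def test_singularity_reported(self, rng):
        x = np.repeat(rng.normal(size=(4, 5)), 2, axis=0)  # rank-deficient
        labels = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        with pytest.raises(ValueError, match="singular|reduce"):
            mm.lda_fit(x, labels)


class TestLoocv:
    def test_separated_groups_perfect_rate(self):
        gen = np.random.default_rng(1234)
        x, labels = two_groups(gen, n=30, sep=10.0)
        rep = mm.loocv_lda(x, labels)
        assert rep.overall_rate == 1.0

    def test_permuted_labels_near_chance(self):
        gen = np.random.default_rng(99)
        x, labels = two_groups(gen, n=30, sep=10.0)
        perm = gen.permutation(labels)
        rep = mm.loocv_lda(x, perm)
        # binomial 3-sigma band around 0.5 for n=60 (band [0.35, 0.65])
        assert 0.35 <= rep.overall_rate <= 0.65

    def test_equals_independent_refit_oracle(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        gen = np.random.default_rng(7)
        for _ in range(50):
            g = gen.integers(2, 4)
            d = gen.integers(1, 4)
            sep = gen.uniform(0.0, 3.0)
            xs, ls = [], []
            for j in range(g):
                n = gen.integers(5, 12)
                xs.append(gen.normal(j * sep, 1.0, (n, d)))
                ls.extend([f"g{j}"] * n)
            x = np.vstack(xs)
            labels = np.array(ls)
            rep = mm.loocv_lda(x, labels)
            n_total = len(x)
            oracle = []
            for i in range(n_total):
                mask = np.ones(n_total, bool)
                mask[i] = False
                g_fold = len(set(labels[mask]))
                sk = LinearDiscriminantAnalysis(priors=[1 / g_fold] * g_fold)
                sk.fit(x[mask], labels[mask])
                oracle.append(sk.predict(x[i][None, :])[0])
            assert np.mean(rep.assignments == np.array(oracle)) == 1.0

    def test_confusion_row_sums_and_trace(self):
        gen = np.random.default_rng(5)
        x, labels = two_groups(gen, n=20, sep=2.0)
        rep = mm.loocv_lda(x, labels)
        assert rep.confusion.sum(axis=1).tolist() == [20, 20]
        assert rep.overall_rate == rep.confusion.values.trace() / 40


class TestManova:
    def test_single_variable_two_groups_equals_t_squared(self, rng):
        from scipy import stats

        x = np.vstack([rng.normal(0, 1, (15, 1)), rng.normal(1, 1, (18, 1))])
        labels = np.array(["a"] * 15 + ["b"] * 18)
        res = mm.manova_wilks(x, labels)
        t = stats.ttest_ind(x[:15, 0], x[15:, 0]).statistic
        assert res.f_statistic == pytest.approx(t**2, abs=1e-8)

    def test_null_lambda_near_one(self):
        gen = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            x = gen.normal(size=(90, 3))
            labels = np.repeat(["a", "b", "c"], 30)
            res = mm.manova_wilks(x, labels)
            assert 0 < res.wilks_lambda <= 1
            hits += res.p_value > 0.05
        assert hits >= 30  # ~95% expected, allow slack

    def test_strong_separation_small_lambda(self, rng):
        x = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(10, 1, (30, 3))])
        labels = np.repeat(["a", "b"], 30)
        assert mm.manova_wilks(x, labels).wilks_lambda < 0.05

    def test_lambda_decreasing_in_separation(self):
        gen = np.random.default_rng(3)
        lams = []
        base = gen.normal(size=(40, 2))
        for sep in (0.0, 2.0, 5.0):
            x = base.copy()
            x[20:] += sep
            lams.append(mm.manova_wilks(x, np.repeat(["a", "b"], 20)).wilks_lambda)
        assert lams[0] > lams[1] > lams[2]


class TestCva:
    def four_group_data(self, rng, d=10):
        centers = rng.normal(0, 3, size=(4, d))
        x = np.vstack([rng.normal(c, 1.0, (15, d)) for c in centers])
        return x, np.repeat([f"g{i}" for i in range(4)], 15)

    def test_axis_count(self, rng):
        x, labels = self.four_group_data(rng)
        cs = mm.cva(x, labels)
        assert cs.n_axes == 3
        assert np.all(np.diff(cs.eigenvalues) <= 1e-9)

    def test_unit_pooled_within_variance(self, rng):
        x, labels = self.four_group_data(rng)
        cs = mm.cva(x, labels)
        groups = sorted(set(labels))
        for j in range(cs.n_axes):
            pooled = sum(
                (np.sum(labels == g) - 1) * np.var(cs.scores[labels == g, j], ddof=1)
                for g in groups
            ) / (len(labels) - len(groups))
            assert pooled == pytest.approx(1.0, abs=1e-6)

    def test_two_groups_cv1_collinear_with_lda_direction(self, rng):
        x = np.vstack([rng.normal(0, 1, (25, 5)), rng.normal(1.5, 1, (25, 5))])
        labels = np.repeat(["a", "b"], 25)
        cs = mm.cva(x, labels)
        model = mm.lda_fit(x, labels)
        w = np.linalg.inv(model.pooled_cov) @ (model.means[1] - model.means[0])
        cos = abs(w @ cs.axes[:, 0]) / (np.linalg.norm(w) * np.linalg.norm(cs.axes[:, 0]))
        assert cos > 1 - 1e-8

    def test_centroid_rayleigh_quotient_matches_eigenvalues(self, rng):
        x, labels = self.four_group_data(rng, d=6)
        cs = mm.cva(x, labels)
        groups = sorted(set(labels))
        counts = np.array([np.sum(labels == g) for g in groups])
        n, g = len(labels), len(groups)
        # between-group variance of CV scores, per axis, equals the eigenvalue
        # scaled by (n - g): a Rayleigh-quotient identity of the CVA problem
        cent = cs.group_centroids.values
        for j in range(cs.n_axes):
            between = float(counts @ cent[:, j] ** 2)
            assert between == pytest.approx(cs.eigenvalues[j] * (n - g), rel=1e-6)

    def test_projection_of_new_data(self, rng):
        x, labels = self.four_group_data(rng)
        cs = mm.cva(x, labels)
        np.testing.assert_allclose(cs.transform(x), cs.scores, atol=1e-10)


class TestKnn:
    def test_k_from_sqrt_n(self):
        assert mm.knn_k(80) == 9
        assert mm.knn_k(1) == 1
        assert mm.knn_k(2) == 1

    def test_query_on_training_point_k1(self, rng):
        pts = rng.normal(size=(20, 2))
        labels = np.array(["x"] * 10 + ["y"] * 10)
        model = KnnModel(pts, labels, k=1)
        lab, votes, ids = mm.knn_classify(model, pts[13])
        assert lab == "y" and votes == {"y": 1} and ids[0] == 13

    def test_votes_match_brute_force_oracle(self):
        gen = np.random.default_rng(12)
        pts = gen.normal(size=(50, 2))
        labels = np.array([f"t{i%4}" for i in range(50)])
        model = KnnModel(pts, labels)
        for _ in range(100):
            q = gen.normal(scale=2.0, size=2)
            lab, votes, ids = mm.knn_classify(model, q)
            order = np.argsort([np.hypot(*(p - q)) for p in pts], kind="stable")
            near = order[: model.k]
            expect = {}
            for i in near:
                expect[labels[i]] = expect.get(labels[i], 0) + 1
            assert votes == expect
            assert sum(votes.values()) == model.k

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(30, 2))
        labels = np.array(["a", "b", "c"] * 10)
        model = KnnModel(pts, labels)
        th = 0.777
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        model_r = KnnModel(pts @ R.T, labels)
        for _ in range(20):
            q = rng.normal(size=2)
            l1, *_ = mm.knn_classify(model, q)
            l2, *_ = mm.knn_classify(model_r, R @ q)
            assert l1 == l2

    def test_tie_break_deterministic(self):
        pts = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        labels = np.array(["b", "b", "a", "a"])
        model = KnnModel(pts, labels, k=4)
        lab, votes, _ = mm.knn_classify(model, [0.0, 0.0])
        assert votes == {"a": 2, "b": 2}
        assert lab == "a"  # equal mean distances: lexicographic

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            KnnModel(np.empty((0, 2)), np.array([]))


class TestCompareMethods:
    def test_twelve_cells_and_determinism(self, training_study):
        model = mm.MethodComparison.from_study(training_study)
        r1 = model.fit()
        assert len(r1.table) == 12
        assert set(r1.table.representation) == {"BEM", "PDP", "EFAproc", "NEF"}
        assert set(r1.table.scheme) == {"LM1_SL63", "LM6_SL52", "LM5_SL48"}
        r2 = mm.MethodComparison.from_study(training_study).fit()
        assert r1.table.equals(r2.table)

    def test_restricted_grid(self, training_study):
        mo, meta = training_study.modern()
        res = mm.compare_methods(
            mo, [m.group for m in meta], representations=("NEF",),
        )
        assert len(res.table) == 3

    def test_winner_consistent_with_max_rate(self, training_study):
        res = mm.MethodComparison.from_study(training_study).fit()
        rep, scheme = res.winner
        row = res.table[(res.table.representation == rep) & (res.table.scheme == scheme)]
        assert row.overall_rate.iloc[0] == res.table.overall_rate.max()
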