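"""PCA, OPLS-DA, clustering, t tests, Spearman and the correlation network."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rheumqc.chemometrics import (
    RHO_MODERATE,
    RHO_STRONG,
    RHO_WEAK,
    CorrelationEdge,
    FeatureMatrix,
    classify_rho,
    correlation_network,
    oplsda,
    pca,
    spearman_rho,
    ttest_two_group,
    ward_hclust,
)


def _fm(X, labels=None, names=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        sample_ids=tuple(f"s{i}" for i in range(X.shape[0])),
        feature_names=tuple(names or (f"f{j}" for j in range(X.shape[1]))),
        values=X,
        class_labels=tuple(labels) if labels is not None else None,
    )


class TestPCA:
    def test_rank_one_data_single_component(self, rng):
        x = rng.normal(size=20)
        model = pca(_fm(np.column_stack([x, 2 * x])), scale=False)
        frac = model.explained_variance / model.explained_variance.sum()
        assert frac[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigen_decomposition_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        model = pca(_fm(X), center=True, scale=False)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False)))[::-1]
        assert np.allclose(np.sort(model.explained_variance)[::-1], evals[: len(model.explained_variance)], atol=1e-10)

    def test_total_variance_conserved_and_scores_uncorrelated(self, rng):
        X = rng.normal(size=(15, 5))
        model = pca(_fm(X), center=True, scale=True)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Xs = Xs - Xs.mean(0)
        assert model.explained_variance.sum() == pytest.approx(
            Xs.var(axis=0, ddof=1).sum(), rel=1e-10
        )
        C = np.corrcoef(model.scores, rowvar=False)
        off = C[~np.eye(C.shape[0], dtype=bool)]
        assert np.all(np.abs(off) < 1e-8)

    def test_constant_feature_dropped_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            model = pca(_fm(X), scale=True)
        assert len(model.feature_names) == 2


class TestOPLSDA:
    def _clouds(self, rng, n=30, effect=3.0):
        X = rng.normal(size=(n, 8))
        X[n // 2 :, :3] += effect
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        return _fm(X, labels=labels)

    def test_separated_clouds_high_q2(self, rng):
        model = oplsda(self._clouds(rng), seed=0)
        assert model.Q2 > 0.5
        assert model.Q2 <= model.R2

    def test_permuted_labels_null_q2(self, rng):
        fm = self._clouds(rng)
        q2s = []
        for rep in range(40):
            labels = tuple(rng.permutation(fm.class_labels))
            perm = _fm(fm.values, labels=labels)
            q2s.append(oplsda(perm, seed=rep).Q2)
        assert np.mean(q2s) <= 0.05

    def test_single_class_error(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            oplsda(_fm(X, labels=["a"] * 10))

    def test_no_signal_matrix(self):
        X = np.ones((10, 4))
        fm = _fm(X, labels=["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            oplsda(fm)

    def test_fold_assignment_deterministic(self, rng):
        fm = self._clouds(rng)
        m1 = oplsda(fm, seed=7)
        m2 = oplsda(fm, seed=7)
        assert m1.Q2 == m2.Q2
        assert m1.R2 == m2.R2

    def test_predictive_scores_match_pls_regression(self, rng):
        """With zero orthogonal components the predictive scores equal a
        one-component PLS regression of the class variable (up to sign/scale)."""
        from sklearn.cross_decomposition import PLSRegression

        fm = self._clouds(rng)
        model = oplsda(fm, n_orthogonal=0, cv_folds=5, seed=0)
        y = np.where(np.asarray(fm.class_labels) == "b", 1.0, -1.0)
        Xs = (fm.values - fm.values.mean(0)) / fm.values.std(0, ddof=1)
        pls = PLSRegression(n_components=1, scale=False).fit(Xs, y - y.mean())
        t_ref = pls.x_scores_[:, 0]
        t_our = model.scores[:, 0]
        r = np.corrcoef(t_ref, t_our)[0, 1]
        assert abs(r) > 1 - 1e-8


class TestWard:
    def test_two_points_single_merge(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        labels, Z = ward_hclust(_fm(X), k=2)
        assert sorted(labels) == [1, 2]
        # scipy's Ward height for a pair is their Euclidean distance
        assert Z[0, 2] == pytest.approx(5.0)

    def test_duplicates_merge_first_at_zero_height(self, rng):
        X = rng.normal(size=(5, 3))
        X[3] = X[0]
        _, Z = ward_hclust(_fm(X), k=2)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_separated_clusters_recovered(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(8, 1, (10, 4))])
        labels, _ = ward_hclust(_fm(X), k=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k_larger_than_n_errors(self, rng):
        with pytest.raises(ValueError):
            ward_hclust(_fm(rng.normal(size=(3, 2))), k=4)


class TestTTest:
    def test_identical_groups(self):
        t, df, p = ttest_two_group([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_pooled_t(self):
        t, df, p = ttest_two_group([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4

    def test_welch_variant_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 5, 30)
        _, df_s, _ = ttest_two_group(a, b, variant="student")
        _, df_w, _ = ttest_two_group(a, b, variant="welch")
        assert df_s == 38
        assert df_w != df_s

    def test_zero_variance_different_means(self):
        with pytest.warns(UserWarning):
            t, _, p = ttest_two_group([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_rho(x, [2.0, 4.0, 9.0, 100.0]) == pytest.approx(1.0)
        assert spearman_rho(x, [5.0, 3.0, 2.0, -1.0]) == pytest.approx(-1.0)

    def test_tied_fixture_matches_rank_then_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([3.0, 1.0, 4.0, 4.0])
        rx = stats.rankdata(x)  # independent ranking routine (mean ranks)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y))
        assert spearman_rho(x, y**3) == pytest.approx(spearman_rho(x, y))

    def test_constant_vector_not_computable(self):
        assert math.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestRhoClassification:
    EPS = 1e-9

    @pytest.mark.parametrize(
        "rho, strength",
        [
            (RHO_WEAK - 1e-9, "none"),
            (RHO_WEAK, "none"),  # strict '>' at the linear-relationship bound
            (RHO_WEAK + 1e-9, "weak"),
            (RHO_MODERATE - 1e-9, "weak"),
            (RHO_MODERATE, "moderate"),
            (RHO_STRONG - 1e-9, "moderate"),
            (RHO_STRONG, "strong"),
            (-0.75, "strong"),
            (0.29, "none"),
        ],
    )
    def test_boundaries(self, rho, strength):
        got_strength, sign = classify_rho(rho)
        assert got_strength == strength
        assert sign == ("negative" if rho < 0 else "positive")

    def test_flag_follows_strength(self):
        assert not CorrelationEdge("c", "Tau", 0.29, "none", "positive").is_linear
        assert CorrelationEdge("c", "Tau", -0.75, "strong", "negative").is_linear


class TestCorrelationNetwork:
    def test_planted_monotone_link_flags_all_properties(self, rng):
        n = 30
        g = rng.uniform(1, 100, n)
        noise = 0.05
        dl = pd.DataFrame(
            {
                "I0": 5000 - 800 * np.log(g) + rng.normal(0, 5000 * noise, n),
                "Tau": 1.0 - 0.1 * np.log(g) + rng.normal(0, noise, n),
                "Beta": 3.0 - 0.3 * np.log(g) + rng.normal(0, noise, n),
                "T": 1.0 - 0.15 * np.log(g) + rng.normal(0, noise, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        fm = _fm(g.reshape(-1, 1), names=["glycoside_total"])
        edges = correlation_network(fm, dl)
        assert len(edges) == 4
        for e in edges:
            assert e.sign == "negative"
            assert e.is_linear

    def test_sample_mismatch_lists_ids(self, rng):
        fm = _fm(rng.normal(size=(4, 2)))
        dl = pd.DataFrame(
            np.ones((4, 4)), columns=["I0", "Tau", "Beta", "T"], index=["x0", "x1", "x2", "x3"]
        )
        with pytest.raises(ValueError, match="x0"):
            correlation_network(fm, dl)
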