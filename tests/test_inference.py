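import numpy as np
import pytest
from scipy import stats

from _oracles import qap_exhaustive_p
from oasisnet import inference as inf


def _node_effect_matrix(rng, n, noise=1.0):
    u = rng.normal(size=n)
    m = u[:, None] + u[None, :] + noise * rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestMRQAP:
    def test_perfect_dependence(self, rng):
        X = _node_effect_matrix(rng, 10)
        res = inf.mrqap_dsp(X, [X.copy()], n_perm=499, rng=rng)
        assert res.betas[1] == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)
        assert res.p_values[0] == pytest.approx(1 / 500)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="square"):
            inf.mrqap_dsp(np.zeros((4, 4)), [np.zeros((5, 5))], n_perm=99, rng=rng)

    def test_constant_predictor(self, rng):
        Y = _node_effect_matrix(rng, 5)
        with pytest.raises(ValueError, match="constant predictor"):
            inf.mrqap_dsp(Y, [np.ones((5, 5))], n_perm=99, rng=rng)

    def test_collinear_predictor_named(self, rng):
        Y = _node_effect_matrix(rng, 6)
        X1 = _node_effect_matrix(rng, 6)
        with pytest.raises(ValueError, match="collinear"):
            inf.mrqap_dsp(Y, [X1, 2 * X1], n_perm=99, rng=rng)

    def test_small_n_matches_exhaustive_oracle(self):
        """n=5: DSP Monte-Carlo p equals the exhaustive 120-permutation QAP p
        within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        Y = _node_effect_matrix(rng, 5)
        X = _node_effect_matrix(rng, 5)
        p_exact = qap_exhaustive_p(Y, X)
        res = inf.mrqap_dsp(Y, [X], n_perm=10_000, rng=np.random.default_rng(8))
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_values[0] - p_exact) < 4 * se + 2e-4

    def test_node_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        n = 8
        Y, X = _node_effect_matrix(rng, n), _node_effect_matrix(rng, n)
        res1 = inf.mrqap_dsp(Y, [X], n_perm=999, rng=np.random.default_rng(1))
        perm = np.random.default_rng(2).permutation(n)
        res2 = inf.mrqap_dsp(
            Y[np.ix_(perm, perm)], [X[np.ix_(perm, perm)]], n_perm=999, rng=np.random.default_rng(1)
        )
        assert res1.betas[1] == pytest.approx(res2.betas[1])
        assert res1.r == pytest.approx(res2.r)
        assert abs(res1.p_values[0] - res2.p_values[0]) < 0.05

    def test_two_predictors_control(self):
        """Semi-partialling: a predictor that only mirrors the other does not
        earn a small p once the true one is controlled for."""
        rng = np.random.default_rng(11)
        n = 16
        X1 = _node_effect_matrix(rng, n)
        X2 = X1 + 0.5 * _node_effect_matrix(rng, n)
        Y = 2.0 * X1 + 0.1 * rng.normal(size=(n, n))
        Y = (Y + Y.T) / 2
        np.fill_diagonal(Y, 0.0)
        res = inf.mrqap_dsp(Y, [X1, X2], n_perm=999, rng=rng, predictor_names=("x1", "x2"))
        assert res.p_values[0] <= 0.01
        assert res.p_values[1] > 0.05
        assert res.betas[1] == pytest.approx(2.0, abs=0.1)


class TestNodePermTTest:
    def test_identical_groups(self, rng):
        vals = np.array([1.0, 1.0, 1.0, 1.0])
        res = inf.node_perm_ttest(vals, np.array(["a", "a", "b", "b"]), n_perm=199, rng=rng)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_extreme_split_exhaustive(self, rng):
        """{0,0,0,0} vs {10,10,10,10}: only the two perfectly separated label
        splits reach |t| = inf, so the exhaustive two-sided p is 2/70."""
        vals = np.array([0.0] * 4 + [10.0] * 4)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = inf.node_perm_ttest(vals, labels, rng=rng, exhaustive=True)
        assert res.p == pytest.approx(2 / 70)
        assert res.n_perm == 70

    def test_small_group_errors(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            inf.node_perm_ttest(np.arange(4.0), np.array(["a", "b", "b", "b"]), rng=rng)

    def test_statistic_is_welch(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(1.0, 2.0, size=14)
        res = inf.node_perm_ttest(
            np.concatenate([a, b]), np.array(["a"] * 9 + ["b"] * 14), n_perm=99, rng=rng
        )
        want = stats.ttest_ind(a, b, equal_var=False).statistic
        assert res.statistic == pytest.approx(want)


class TestNodePermKruskal:
    def test_identical_groups_h_zero(self, rng):
        vals = np.array([2.0] * 6)
        res = inf.node_perm_kruskal(vals, np.array(["a", "a", "b", "b", "c", "c"]), n_perm=99, rng=rng)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_h(self, rng):
        """Groups {1,2},{3,4},{5,6}: H = 12/(6*7) * 16 = 32/7, no ties."""
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        res = inf.node_perm_kruskal(vals, labels, n_perm=199, rng=rng, posthoc=False)
        assert res.statistic == pytest.approx(32 / 7)

    def test_matches_scipy_statistic(self, rng):
        """Tie-corrected H equals scipy's on 50 random datasets."""
        for _ in range(50):
            sizes = rng.integers(3, 8, size=3)
            vals = np.concatenate([rng.integers(0, 6, size=s).astype(float) for s in sizes])
            labels = np.concatenate([[f"g{k}"] * s for k, s in enumerate(sizes)])
            if np.ptp(vals) == 0:
                continue
            want = stats.kruskal(*[vals[labels == g] for g in np.unique(labels)]).statistic
            assert inf.kruskal_h(vals, labels) == pytest.approx(want)

    def test_posthoc_bonferroni_present(self, rng):
        vals = np.concatenate([rng.normal(size=5), rng.normal(3, 1, 5), rng.normal(6, 1, 5)])
        labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = inf.node_perm_kruskal(vals, labels, n_perm=199, rng=rng)
        assert set(res.extra["posthoc_bonferroni"]) == {"a|b", "a|c", "b|c"}
        assert all(0 < p <= 1 for p in res.extra["posthoc_bonferroni"].values())


class TestNodePermRegression:
    def test_exact_fit(self, rng):
        x = np.arange(10.0)
        res = inf.node_perm_regression(2 * x, x, n_perm=499, rng=rng)
        assert res.statistic == pytest.approx(2.0)
        assert res.extra["adj_r2"] == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 500)

    def test_constant_x_errors(self, rng):
        with pytest.raises(ValueError, match="constant x"):
            inf.node_perm_regression(np.arange(5.0), np.ones(5), n_perm=99, rng=rng)

    def test_adj_r2_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=25)
        y = 1.5 * x + rng.normal(size=25)
        res = inf.node_perm_regression(y, x, n_perm=99, rng=rng)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.extra["adj_r2"] == pytest.approx(fit.rsquared_adj)
        assert res.statistic == pytest.approx(fit.params[1])


class TestPermutationInvariants:
    def test_vector_tests_invariant_to_relabelling(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        perm = rng.permutation(12)
        r1 = inf.node_perm_ttest(vals, labels, exhaustive=True)
        r2 = inf.node_perm_ttest(vals[perm], labels[perm], exhaustive=True)
        assert r1.p == pytest.approx(r2.p)

    def test_y_permutation_equals_dsp_for_single_predictor(self):
        """For one predictor, permuting Y is the mirror image of permuting the
        residualized X; exhaustive p-values agree on small symmetric inputs."""
        rng = np.random.default_rng(5)
        n = 6
        Y = _node_effect_matrix(rng, n)
        X = _node_effect_matrix(rng, n)
        p_x_perm = qap_exhaustive_p(Y, X)
        p_y_perm = qap_exhaustive_p(X, Y)  # same |slope| stat up to scaling per perm
        res = inf.mrqap_dsp(Y, [X], n_perm=10_000, rng=np.random.default_rng(6))
        assert abs(res.p_values[0] - p_x_perm) < 0.02
        assert abs(p_x_perm - p_y_perm) < 0.05
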