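import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

import hubgene as hg
from hubgene.association import huber_irls
from hubgene.synth import gaussian_random_field
from hubgene._utils import rng_for


class TestRobustGLM:
    def test_noiseless_exact(self):
        deg = np.tile(np.linspace(0, 100, 27), 2)
        ages = np.repeat([16.0, 21.0], 27)
        y = 2.0 * deg + 1.0
        res = hg.robust_glm(y, deg, ages)
        assert res["beta_degree"] == pytest.approx(2.0, abs=1e-8)

    def test_close_to_ols_without_outliers(self):
        rng = np.random.default_rng(0)
        deg = np.tile(np.linspace(0, 100, 30), 4)
        y = 0.05 * deg + rng.normal(0, 1, size=len(deg))
        res = hg.robust_glm(y, deg)
        X = sm.add_constant(deg)
        ols = sm.OLS(y, X).fit()
        assert abs(res["beta_degree"] - ols.params[1]) < 2 * ols.bse[1]

    def test_matches_statsmodels_rlm(self):
        # independent cross-check of the IRLS implementation
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 60)
        y = 1.0 + 0.7 * x + rng.standard_normal(60)
        y[5] += 25.0
        X = np.column_stack([np.ones_like(x), x])
        beta, se, *_ = huber_irls(X, y)
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        # scale estimators differ slightly between implementations
        assert beta == pytest.approx(rlm.params, rel=2e-2)

    def test_outlier_resistance_beats_ols(self):
        rng = np.random.default_rng(3)
        deg = np.linspace(0, 100, 27)
        beta_true = 0.02
        y = beta_true * deg + rng.normal(0, 0.1, 27)
        y[26] *= 10.0  # one gross high-leverage outlier
        res = hg.robust_glm(y, deg)
        ols = sm.OLS(y, sm.add_constant(deg)).fit()
        assert abs(res["beta_degree"] - beta_true) < abs(ols.params[1] - beta_true)

    def test_single_age_drops_covariate(self):
        deg = np.linspace(0, 10, 20)
        y = deg * 1.5 + 2
        with pytest.warns(UserWarning, match="age"):
            res = hg.robust_glm(y, deg, ages=np.full(20, 16.0))
        assert res["beta_degree"] == pytest.approx(1.5, abs=1e-6)

    def test_too_few_observations_missing(self):
        res = hg.robust_glm(np.array([1.0, 2.0, np.nan]), np.array([0.0, 1.0, 2.0]))
        assert np.isnan(res["beta_degree"])
        assert res["n_obs"] == 2


class TestFDR:
    def test_worked_case(self):
        got = hg.fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_constant(self):
        assert hg.fdr_correct([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(hg.fdr_correct([0.2, 0.2, 0.2]), 0.2)

    def test_matches_step_up_formula(self):
        rng = np.random.default_rng(7)

        def bh(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 200)))
            assert np.allclose(hg.fdr_correct(p), bh(p))

    def test_nan_passthrough(self):
        out = hg.fdr_correct([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])


class TestVariogram:
    def test_constant_map_zero(self):
        dist = squareform(pdist(np.random.default_rng(0).random((12, 3))))
        _, g = hg.variogram(np.full(12, 3.0), dist)
        assert np.allclose(g, 0.0)

    def test_two_region_case(self):
        dist = np.array([[0.0, 1.0], [1.0, 0.0]])
        _, g = hg.variogram(np.array([0.0, 2.0]), dist, n_bins=1)
        assert g[0] == pytest.approx(2.0)

    def test_nonnegative_and_increasing_for_smooth_field(self):
        rng = rng_for(4, "vario")
        coords = rng.uniform(0, 100, (40, 3))
        dist = squareform(pdist(coords))
        f = gaussian_random_field(coords, 40.0, rng, 1)[:, 0]
        h, g = hg.variogram(f, dist, n_bins=8)
        assert np.all(g >= 0)
        assert g[:2].mean() < g[-2:].mean()  # semivariance grows with distance


class TestSurrogates:
    def test_constant_map(self):
        rng = rng_for(0, "s")
        coords = rng.uniform(0, 100, (15, 3))
        dist = squareform(pdist(coords))
        ens = hg.generate_surrogates(np.full(15, 2.0), dist, n_surr=5, seed=1)
        assert np.allclose(ens.maps, 2.0)

    def test_determinism(self):
        rng = rng_for(1, "s")
        coords = rng.uniform(0, 100, (20, 3))
        dist = squareform(pdist(coords))
        m = gaussian_random_field(coords, 30.0, rng, 1)[:, 0]
        a = hg.generate_surrogates(m, dist, n_surr=10, seed=5)
        b = hg.generate_surrogates(m, dist, n_surr=10, seed=5)
        assert np.array_equal(a.maps, b.maps)

    def test_moments_and_variogram_match(self):
        rng = rng_for(2, "s")
        coords = rng.uniform(0, 100, (27, 3))
        dist = squareform(pdist(coords))
        # strongly spatially structured map: gradient plus correlated field
        grf = gaussian_random_field(coords, 30.0, rng, 1)[:, 0]
        m = (coords[:, 0] - 50) / 50 * 1.5 + 0.5 * grf
        ens = hg.generate_surrogates(m, dist, n_surr=50, seed=3)
        assert np.allclose(ens.maps.mean(axis=1), m.mean(), atol=1e-8)
        assert np.allclose(ens.maps.std(axis=1), m.std(), atol=1e-8)
        assert ens.diagnostics["vario_r"].median() > 0.9

    def test_degenerate_distances_fall_back(self):
        dist = np.ones((12, 12)) - np.eye(12)
        m = np.arange(12, dtype=float)
        with pytest.warns(UserWarning, match="permutation"):
            ens = hg.generate_surrogates(m, dist, n_surr=4, seed=0)
        assert np.array_equal(np.sort(ens.maps, axis=1), np.tile(np.sort(m), (4, 1)))


class TestSpatialPvalue:
    def test_extreme_and_null_cases(self):
        nulls = np.random.default_rng(0).normal(size=1000)
        assert hg.spatial_pvalue(99.0, nulls) == pytest.approx(1 / 1001)
        assert hg.spatial_pvalue(0.0, nulls) == pytest.approx(1.0)


class TestRunAssociation:
    def test_planted_signs_and_recovery(self, small_expression):
        df, truth, degree = small_expression
        tensor = hg.ExpressionPrep().fit_transform(df)
        tab = hg.run_association(
            tensor, degree, coords=truth.region_coords, n_surr=100, seed=2
        )
        assert set(tab.columns) == {
            "gene", "zone", "beta_degree", "se", "t", "p", "p_fdr", "p_spatial",
            "n_obs", "class",
        }
        planted = truth.planted_gene_effects
        hits = tab[tab["class"] != ""]
        for _, row in hits.iterrows():
            if row["gene"] in planted:
                zone, beta = planted[row["gene"]]
                if row["zone"] == zone:
                    want = "hub+" if beta > 0 else "hub-"
                    assert row["class"] == want

    def test_unmatched_region_error(self, small_expression):
        df, truth, degree = small_expression
        tensor = hg.ExpressionPrep().fit_transform(df)
        with pytest.raises(ValueError, match="R00"):
            hg.run_association(tensor, degree.drop("R00"), n_surr=0)

    def test_shuffled_regions_kill_detections(self, small_expression):
        df, truth, degree = small_expression
        tensor = hg.ExpressionPrep().fit_transform(df)
        rng = np.random.default_rng(9)
        shuffled = pd.Series(
            rng.permutation(degree.to_numpy()), index=degree.index
        )
        tab = hg.run_association(tensor, shuffled, dist=None, coords=truth.region_coords,
                                 n_surr=50, seed=4)
        planted = set(truth.planted_gene_effects)
        hits = set(tab.loc[tab["class"] != "", "gene"]) & planted
        tab0 = hg.run_association(tensor, degree, coords=truth.region_coords,
                                  n_surr=50, seed=4)
        hits0 = set(tab0.loc[tab0["class"] != "", "gene"]) & planted
        assert len(hits) < len(hits0)

    def test_estimator_wrapper(self, small_expression):
        df, truth, degree = small_expression
        tensor = hg.ExpressionPrep().fit_transform(df)
        est = hg.DegreeAssociation(n_surrogates=0).fit(tensor, degree_map=degree)
        assert len(est.results_) == tensor.sizes["gene"] * 5
        params = est.get_params()
        assert params["n_surrogates"] == 0
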