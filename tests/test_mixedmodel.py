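import numpy as np
import pytest

from admixgwas import kinship as kin, mixedmodel as mm


def _identity_kset(n, background="D"):
    return kin.KinshipSet(np.eye(n), [f"l{i}" for i in range(n)],
                          np.array([background] * n, dtype=object), "common")


class TestRemlFit:
    def test_identity_kinship_collapses_to_sample_variance(self):
        """With K = I the genetic and error variances are confounded;
        only their sum is identified and ReML recovers the n-1 sample
        variance of the residuals around the mean."""
        rng = np.random.default_rng(0)
        n = 80
        y = 3.0 + rng.normal(0, 2.0, n)
        fit = mm.reml_fit(y, np.ones((n, 1)), _identity_kset(n))
        total = fit.Sigma_G[0, 0] + fit.sigma2_E
        assert total == pytest.approx(np.var(y, ddof=1), rel=1e-3)
        assert fit.beta[0] == pytest.approx(y.mean(), rel=1e-6)

    def test_optimum_beats_any_supplied_point(self, sim_panel):
        G, ped = sim_panel.genotypes, sim_panel.pedigree
        kset = kin.kinship_matrix(G, ped)
        bg = ped.background_of(G.lines)
        X = np.stack([(bg == k).astype(float) for k in ("D", "A", "F")], axis=1)
        y = sim_panel.phenotypes.to_numpy()
        fit = mm.reml_fit(y, X, kset)
        assert fit.converged
        for sg, se in [(np.eye(3), 1.0),
                       (0.5 * np.eye(3) + 0.2, 2.0),
                       (sim_panel.truth.sigma_G, sim_panel.truth.sigma2_E)]:
            ll_at = mm.restricted_loglik_at(y, X, kset, sg, se)
            assert fit.loglik >= ll_at - 1e-6

    def test_plugged_covariance_matches_hand_assembly(self):
        rng = np.random.default_rng(1)
        n = 6
        A = rng.normal(size=(n, n + 2))
        K = A @ A.T / (n + 2)
        bgs = np.array(["D", "D", "A", "A", "F", "F"], dtype=object)
        kset = kin.KinshipSet(K, [f"l{i}" for i in range(n)], bgs, "by-background")
        sigma = np.array([[1.0, 0.5, 0.2], [0.5, 0.8, 0.3], [0.2, 0.3, 1.2]])
        fit = mm.PolygenicFit(["D", "A", "F"], sigma, 0.7, None, None,
                              0.0, True, 0, False)
        V = mm.plug_covariances(fit, kset).V
        order = {"D": 0, "A": 1, "F": 2}
        for i in range(n):
            for j in range(n):
                expected = sigma[order[bgs[i]], order[bgs[j]]] * K[i, j] \
                    + (0.7 if i == j else 0.0)
                assert V[i, j] == pytest.approx(expected, abs=1e-12)

    def test_block_diagonal_when_sigma_diagonal(self):
        rng = np.random.default_rng(2)
        n = 6
        K = np.eye(n) + 0.1
        bgs = np.array(["D", "D", "D", "F", "F", "F"], dtype=object)
        kset = kin.KinshipSet(K, [f"l{i}" for i in range(n)], bgs, "by-background")
        fit = mm.PolygenicFit(["D", "F"], np.diag([1.0, 2.0]), 0.5, None, None,
                              0.0, True, 0, False)
        G = mm.plug_covariances(fit, kset).G
        assert np.all(G[:3, 3:] == 0)


class TestGLS:
    def test_identity_v_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n)
        fit = mm.gls_fit(y, X)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-10)

    def test_matches_weighted_regression_oracle(self):
        # n = 5 toy with heteroscedastic diagonal V: GLS == WLS closed form
        X = np.column_stack([np.ones(5), [0.0, 1, 2, 3, 4]])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0])
        V = np.diag(1 / w)
        fit = mm.gls_fit(y, X, V=V)
        WX = X * w[:, None]
        beta_wls = np.linalg.solve(X.T @ WX, WX.T @ y)
        np.testing.assert_allclose(fit.beta, beta_wls, atol=1e-10)

    def test_duplicated_column_contrast_not_estimable(self):
        rng = np.random.default_rng(4)
        n = 20
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, x])
        y = x + rng.normal(size=n)
        fit = mm.gls_fit(y, X)
        assert not fit.estimable(np.array([0.0, 1.0, -1.0]))
        assert fit.estimable(np.array([0.0, 1.0, 1.0]))
        with pytest.raises(mm.ModelError, match="estimable"):
            mm.wald_contrast(fit, np.array([0.0, 1.0, -1.0]))


class TestWald:
    def test_zero_estimate_gives_p_one(self):
        fit = mm.GLSFit(np.zeros(2), np.eye(2), 1.0, 2, 10,
                        _rowspace=np.eye(2))
        res = mm.wald_contrast(fit, np.array([1.0, 0.0]))
        assert res.wald == 0.0 and res.p == 1.0

    def test_equals_squared_z_from_ols_oracle(self):
        rng = np.random.default_rng(5)
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        sigma2 = 2.3
        y = 0.4 * x + rng.normal(0, np.sqrt(sigma2), n)
        fit = mm.gls_fit(y, X, V=sigma2 * np.eye(n))
        res = mm.wald_contrast(fit, np.array([0.0, 1.0]))
        bhat = np.linalg.lstsq(X, y, rcond=None)[0][1]
        xc = x - x.mean()
        z2 = bhat ** 2 * (xc @ xc) / sigma2
        assert res.wald == pytest.approx(z2, rel=1e-10)

    def test_scale_equivariance(self, sim_panel):
        """Multiplying y by a rescales the estimate by a and leaves W, p
        unchanged when the variance parameters scale along (two-step
        with per-SNP scale re-estimation)."""
        from admixgwas import gwas

        panel = sim_panel
        res1 = gwas.run_gwas(panel.phenotypes, panel.genotypes, panel.pedigree,
                             panel.tracks, model="M2",
                             test_markers=[panel.genotypes.markers.marker_ids[5]])
        a = 3.7
        res2 = gwas.run_gwas(panel.phenotypes * a, panel.genotypes,
                             panel.pedigree, panel.tracks, model="M2",
                             test_markers=[panel.genotypes.markers.marker_ids[5]])
        r1 = res1.results.set_index("hypothesis")
        r2 = res2.results.set_index("hypothesis")
        if len(r1):
            np.testing.assert_allclose(r2["estimate"], a * r1["estimate"],
                                       rtol=1e-3)
            np.testing.assert_allclose(r2["wald"], r1["wald"], rtol=1e-3)


class TestComponentsReml:
    def test_single_component_matches_closed_form(self):
        rng = np.random.default_rng(6)
        n = 60
        y = rng.normal(0, 1.7, n)
        fit = mm.reml_components(y, np.ones((n, 1)), [np.eye(n)], ["s2"])
        assert fit.variances["s2"] == pytest.approx(np.var(y, ddof=1), rel=1e-4)

    def test_loglik_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        n = 40
        y = rng.normal(0, 1.3, n)
        X = np.ones((n, 1))
        fit = mm.reml_components(y, X, [np.eye(n)], ["s2"])
        s2 = fit.variances["s2"]
        # direct restricted log-likelihood of iid model at the optimum
        ll = -0.5 * ((n - 1) * np.log(2 * np.pi * s2) + np.log(n)
                     + (n - 1) * np.var(y, ddof=1) / s2)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)
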