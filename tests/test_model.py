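"""The one-step mixed model: REML, GBLUPs, marker effects and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import gsdesign as g
from gsdesign.model import NON_GENETIC
from gsdesign.simulate import grid_layout, simulate_phenotypes_from_components

from conftest import random_genotypes


def reml_loglik_oracle(y, X, V):
    """Independent dense REML log-likelihood (up to the usual constant)."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    return -0.5 * (np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XtViX)[1]
                   + resid @ Vi @ y)


class TestRemlFit:
    def test_pure_noise_pins_genetic_variance(self, rng):
        G = random_genotypes(rng, 80, 120)
        K = g.build_kinship(G)
        layout = grid_layout(G.line_ids, n_cols=8, seed=0)
        y = rng.standard_normal(80)
        fit = g.fit_one_step(y, layout, K, spatial=False)
        assert fit.vc.sigma2_a < 0.05 * np.var(y)

    def test_matches_grid_search_oracle_on_tiny_instance(self, rng):
        # <= 30 observations, independent residuals: the solver's optimum
        # must reach the best point of a dense grid over the variance ratio
        n, m = 24, 40
        G = random_genotypes(rng, n, m)
        K = g.build_kinship(G)
        layout = grid_layout(G.line_ids, n_cols=6, seed=1)
        vc = g.VarianceComponents(sigma2=1.0, sigma2_u=0, sigma2_a=2.0,
                                  sigma2_p=0.0, rho_r=0.0, rho_c=0.0)
        y, _ = simulate_phenotypes_from_components(K, layout, vc, seed=3)
        fit = g.fit_one_step(y, layout, K, spatial=False,
                             frozen={"sigma2_p": 0.0})

        order = {v: i for i, v in enumerate(K.line_ids)}
        Zg = np.zeros((n, n))
        for i, lid in enumerate(layout.line_ids):
            Zg[i, order[lid]] = 1.0
        ZKZ = Zg @ K.values @ Zg.T
        X = np.ones((n, 1))
        best = -np.inf
        for lam in np.geomspace(1e-3, 1e3, 200):       # sigma2_a / sigma2
            for s2 in np.geomspace(0.05, 20.0, 120) * np.var(y):
                ll = reml_loglik_oracle(y, X, s2 * (lam * ZKZ + np.eye(n)))
                best = max(best, ll)
        assert fit.loglik >= best - 1e-4

    def test_parameter_recovery_smoke(self):
        # single replicate sanity check; the replicated recovery study lives
        # in the acceptance suite
        cfg = g.SimulationConfig(n_pops=2, n_lines_per_pop=100, n_markers=300,
                                 n_chromosomes=5, n_cohorts=1,
                                 selected_trait=None, seed=3)
        G, _, truth = g.simulate_panel(cfg)
        K = g.build_kinship(G)
        layout = grid_layout(G.line_ids, n_cols=10, seed=2)
        vc = g.VarianceComponents(sigma2=0.5, sigma2_u=0, sigma2_a=1.0,
                                  sigma2_p=0.25, rho_r=0.5, rho_c=0.5)
        y, a = simulate_phenotypes_from_components(K, layout, vc, seed=4)
        fit = g.fit_one_step(y, layout, K)
        assert fit.converged
        # GBLUPs track the simulated additive effects
        r = stats.pearsonr(fit.gblup_additive.to_numpy(), a.to_numpy())[0]
        assert r > 0.7

    def test_masked_plots_are_excluded(self, small_bundle, small_kinship):
        y = small_bundle.phenotypes["trait_quant"].to_numpy().copy()
        y[:30] = np.nan
        fit = g.fit_one_step(y, small_bundle.layout, small_kinship,
                             max_iter=50)
        assert np.isfinite(fit.loglik)

    def test_layout_rejects_duplicate_positions(self):
        with pytest.raises(ValueError, match="duplicate"):
            g.TrialLayout(np.array([0, 0]), np.array([1, 1]),
                          np.array(["a", "b"]), np.array([False, False]),
                          n_rows=2, n_cols=2)


class TestTrainingProtocol:
    def test_zero_mask_reproduces_full_fit_gblups(self, small_bundle,
                                                  small_kinship,
                                                  small_full_model):
        frozen = {k: getattr(small_full_model.vc, k) for k in NON_GENETIC}
        y = small_bundle.phenotypes["trait_quant"].to_numpy()
        refit = g.fit_training_model(y, small_bundle.layout, small_kinship,
                                     frozen)
        r = stats.pearsonr(refit.gblup_additive.to_numpy(),
                           small_full_model.gblup_additive.to_numpy())[0]
        assert r > 0.999

    def test_validation_lines_in_kinship_rejected(self, small_bundle,
                                                  small_kinship,
                                                  small_full_model):
        frozen = small_full_model.vc.as_dict()
        y = small_bundle.phenotypes["trait_quant"].to_numpy()
        with pytest.raises(ValueError, match="validation lines"):
            g.fit_training_model(y, small_bundle.layout, small_kinship,
                                 frozen,
                                 validation_ids=small_kinship.line_ids[:3])

    def test_missing_frozen_parameters_rejected(self, small_bundle,
                                                small_kinship):
        y = small_bundle.phenotypes["trait_quant"].to_numpy()
        with pytest.raises(ValueError, match="frozen"):
            g.fit_training_model(y, small_bundle.layout, small_kinship,
                                 frozen={"sigma2": 1.0})

    def test_perturbed_frozen_parameters_degrade_accuracy(
            self, small_bundle, small_kinship, small_full_model):
        """Inflating the frozen residual variance far from its estimate
        must not improve validation accuracy."""
        b = small_bundle
        checks = set(b.layout.check_line_ids())
        ids = [i for i in b.G.line_ids if i not in checks]
        rng = np.random.default_rng(5)
        perm = rng.permutation(ids)
        train, valid = list(perm[:120]), list(perm[120:160])
        y = b.phenotypes["trait_quant"].to_numpy().copy()
        y[~np.isin(b.layout.line_ids, train + sorted(checks))] = np.nan
        M_t = b.G.subset_lines(train + sorted(checks))
        K_t = g.build_kinship(M_t)
        M_v = b.G.subset_lines(valid)
        ref = small_full_model.gblup_additive.loc[valid].to_numpy()

        accs = []
        for factor in (1.0, 300.0):
            frozen = small_full_model.vc.as_dict()
            frozen["sigma2"] *= factor
            fit = g.fit_training_model(y, b.layout, K_t, frozen,
                                       validation_ids=valid)
            q = g.backsolve_marker_effects(
                M_t, K_t, fit.gblup_additive.loc[M_t.line_ids].to_numpy(),
                ridge=True)
            pred = g.predict_lines(M_v, q)
            accs.append(stats.pearsonr(pred.to_numpy(), ref)[0])
        assert accs[0] >= accs[1] - 0.02


class TestMarkerEffects:
    def test_backsolve_square_invertible_case(self):
        # orthogonal-rowed square marker matrix: unique linear solution
        M = np.array([[1.0, 1.0], [1.0, -1.0]])
        G = g.GenotypeMatrix(["a", "b"], ["m1", "m2"], M)
        K = g.build_kinship(G)
        a = np.array([0.3, -0.9])
        q = g.backsolve_marker_effects(G, K, a)
        np.testing.assert_allclose(M @ q.effects, K.s * a, rtol=1e-10)

    def test_backsolve_matches_dense_solve(self, rng):
        G = random_genotypes(rng, 6, 10)
        K = g.build_kinship(G)
        a = rng.standard_normal(6)
        q = g.backsolve_marker_effects(G, K, a)
        expected = G.calls.T @ np.linalg.solve(K.values, a)
        np.testing.assert_allclose(q.effects, expected, rtol=1e-8)

    def test_scale_s_identity(self, rng):
        # M q = s a for any full-rank training kinship
        G = random_genotypes(rng, 12, 30)
        K = g.build_kinship(G)
        a = rng.standard_normal(12)
        q = g.backsolve_marker_effects(G, K, a)
        np.testing.assert_allclose(G.calls @ q.effects, K.s * a, rtol=1e-6)

    def test_singular_kinship_needs_ridge(self, rng):
        calls = rng.choice([-1.0, 1.0], size=(4, 2))  # rank <= 2 < 4 lines
        G = g.GenotypeMatrix(list("abcd"), ["m1", "m2"], calls)
        K = g.build_kinship(G)
        a = rng.standard_normal(4)
        with pytest.raises(linalg.LinAlgError):
            g.backsolve_marker_effects(G, K, a)
        q = g.backsolve_marker_effects(G, K, a, ridge=True)
        assert np.all(np.isfinite(q.effects))

    def test_prediction_zero_effects(self, rng):
        G = random_genotypes(rng, 5, 4)
        q = g.MarkerEffects(G.marker_ids, np.zeros(4), source="backsolved")
        assert (g.predict_lines(G, q) == 0).all()

    def test_prediction_single_marker_scalar_case(self):
        G = g.GenotypeMatrix(["a", "b"], ["m1"], np.array([[1.0], [-1.0]]))
        q = g.MarkerEffects(["m1"], [0.7], source="direct")
        np.testing.assert_allclose(g.predict_lines(G, q).to_numpy(),
                                   [0.7, -0.7])

    def test_prediction_rejects_marker_mismatch(self, rng):
        G = random_genotypes(rng, 3, 4)
        q = g.MarkerEffects(["x1", "x2", "x3", "x4"], np.zeros(4),
                            source="direct")
        with pytest.raises(ValueError, match="marker sets"):
            g.predict_lines(G, q)

    def test_duplicated_lines_predict_their_training_gblups(self, rng):
        # validation genotypes copied from training reproduce s * a_t
        G = random_genotypes(rng, 15, 40)
        K = g.build_kinship(G)
        a = rng.standard_normal(15)
        q = g.backsolve_marker_effects(G, K, a)
        clones = g.GenotypeMatrix([f"c{i}" for i in range(5)],
                                  G.marker_ids, G.calls[:5].copy())
        pred = g.predict_lines(clones, q)
        np.testing.assert_allclose(pred.to_numpy(), K.s * a[:5], rtol=1e-6)


class TestModelEquivalence:
    def test_backsolve_and_direct_routes_agree(self, small_bundle,
                                               small_kinship,
                                               small_full_model):
        """With more markers than training lines, the kinship back-solve and
        the reduced-rank marker-effects formulation give the same validation
        predictions (up to the kinship scale constant)."""
        b = small_bundle
        checks = sorted(set(b.layout.check_line_ids()))
        ids = [i for i in b.G.line_ids if i not in set(checks)]
        rng = np.random.default_rng(2)
        perm = rng.permutation(ids)
        train, valid = list(perm[:120]), list(perm[120:160])
        y = b.phenotypes["trait_quant"].to_numpy().copy()
        y[~np.isin(b.layout.line_ids, train + checks)] = np.nan
        frozen = small_full_model.vc.as_dict()
        M_t = b.G.subset_lines(train + checks)
        M_v = b.G.subset_lines(valid)

        K_t = g.build_kinship(M_t)
        fit = g.fit_training_model(y, b.layout, K_t, frozen,
                                   validation_ids=valid)
        q_back = g.backsolve_marker_effects(
            M_t, K_t, fit.gblup_additive.loc[M_t.line_ids].to_numpy())
        pred_back = g.predict_lines(M_v, q_back)

        q_direct = g.fit_marker_model(y, b.layout, M_t, frozen,
                                      validation_ids=valid)
        pred_direct = g.predict_lines(M_v, q_direct)

        r = stats.pearsonr(pred_back.to_numpy(), pred_direct.to_numpy())[0]
        assert r > 0.999
        # variance components agree once the scale constant is applied
        assert q_direct.model.vc.sigma2_a * K_t.s == pytest.approx(
            fit.vc.sigma2_a, rel=0.05)

    def test_zero_signal_shrinks_direct_effects(self, rng):
        G = random_genotypes(rng, 30, 50)
        layout = grid_layout(G.line_ids, n_cols=6, seed=3)
        y = rng.standard_normal(30)  # no genetic signal at all
        frozen = {"sigma2": 1.0, "rho_r": 0.0, "rho_c": 0.0}
        q = g.fit_marker_model(y, layout, G, frozen, spatial=False)
        assert np.abs(q.effects).max() < 0.1 * np.std(y)
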