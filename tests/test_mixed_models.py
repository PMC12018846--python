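"""REML, GBLUP, BayesB, LASSO, entry BLUPs and the cross-validation engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cholesky

from spdchg import (
    McmConfig,
    bayesb_fit,
    cross_validate,
    em_reml,
    env_blup,
    gblup_predict,
    lasso_fit,
    reml_fit,
)
from spdchg.genotypes import additive_kinship, dominance_kinship
from spdchg.errors import ConfigError, ModelError


def draw_kernel_phenotype(rng, Ka, Kd, phi_a, phi_d, s2):
    n = Ka.shape[0]
    V = phi_a * Ka + phi_d * Kd + s2 * np.eye(n)
    return cholesky(V + 1e-10 * np.eye(n), lower=True) @ rng.normal(size=n)


class TestEmReml:
    def test_loglik_monotone_non_decreasing(self, rng):
        n = 80
        Za = rng.choice([0.0, 1.0, 2.0], size=(n, 120))
        Ka, _ = additive_kinship(Za)
        Kd, _ = dominance_kinship((Za == 1).astype(float))
        y = draw_kernel_phenotype(rng, Ka, Kd, 1.5, 0.5, 1.0)
        *_, path = em_reml(y, None, [Ka, Kd], max_iter=120)
        diffs = np.diff(path)
        assert (diffs > -1e-6).all()

    def test_constant_phenotype_components_vanish(self):
        rng = np.random.default_rng(0)
        Za = rng.choice([0.0, 1.0, 2.0], size=(30, 40))
        Ka, _ = additive_kinship(Za)
        phi, s2, *_ = em_reml(np.full(30, 3.0), None, [Ka], max_iter=60)
        assert phi[0] < 1e-8 and s2 < 1e-8

    def test_dropping_kernel_equals_fixing_zero(self, rng):
        n = 60
        Za = rng.choice([0.0, 1.0, 2.0], size=(n, 80))
        Ka, _ = additive_kinship(Za)
        Kd, _ = dominance_kinship((Za == 1).astype(float))
        y = draw_kernel_phenotype(rng, Ka, Kd, 2.0, 0.0, 1.0)
        phi1, s21, *_ = em_reml(y, None, [Ka], max_iter=300, tol=1e-9)
        phi2, s22, *_ = em_reml(y, None, [Ka, Kd], max_iter=300, tol=1e-9,
                                fixed={1: 0.0})
        assert phi1[0] == pytest.approx(phi2[0], abs=1e-5)
        assert s21 == pytest.approx(s22, abs=1e-5)

    def test_input_validation(self, rng):
        Ka, _ = additive_kinship(rng.choice([0.0, 2.0], size=(20, 30)))
        with pytest.raises(ModelError):
            em_reml(np.r_[np.nan, np.ones(19)], None, [Ka])
        X = np.ones((20, 2))  # rank-deficient fixed design
        with pytest.raises(ModelError):
            em_reml(np.ones(20) + rng.normal(size=20), X, [Ka])


class TestGblup:
    def test_interpolation_limit_reproduces_training_point(self, rng):
        # noiseless phenotype: a test row identical to a training row gets
        # back (nearly) that row's value
        n, m = 60, 200
        Za = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        Zd = (Za == 1).astype(float)
        b = rng.normal(size=m) * 0.3
        y = (Za - Za.mean(0)) @ b
        fit = reml_fit(y, Za, Zd, max_iter=400)
        pred = fit.predict(Za[:5], Zd[:5])
        assert np.corrcoef(pred, y[:5])[0, 1] > 0.999
        assert np.allclose(pred, y[:5], atol=0.15 * y.std())

    def test_kernel_route_equals_marker_route(self, rng):
        n, m = 40, 60
        Za = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        Zd = (Za == 1).astype(float)
        y = rng.normal(size=n)
        tr, te = np.arange(30), np.arange(30, 40)
        fit = reml_fit(y[tr], Za[tr], Zd[tr], max_iter=80)
        # cross-kinship blocks with training-panel centering
        Wa_tr, Wa_te = Za[tr] - 2 * fit.freqs, Za[te] - 2 * fit.freqs
        Wd_tr, Wd_te = Zd[tr] - fit.dom_means, Zd[te] - fit.dom_means
        Kca = Wa_te @ Wa_tr.T / m
        Kcd = Wd_te @ Wd_tr.T / m
        kernel_pred = gblup_predict(fit, Kca, Kcd)
        marker_pred = fit.predict(Za[te], Zd[te])
        assert np.allclose(kernel_pred, marker_pred, atol=1e-8)

    def test_dimension_mismatch_errors(self, rng):
        Za = rng.choice([0.0, 1.0, 2.0], size=(20, 30))
        y = rng.normal(size=20)
        fit = reml_fit(y, Za, max_iter=30)
        with pytest.raises(ModelError):
            gblup_predict(fit, np.ones((3, 7)))


class TestBayesB:
    def test_planted_qtl_rank_in_top_decile(self, rng):
        n, m = 300, 400
        W = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        qtl = [40, 140, 240, 340, 390]
        b = np.zeros(m)
        b[qtl] = [2.0, -2.0, 1.5, 2.5, -1.8]
        gval = W @ b
        y = gval + rng.normal(0, np.sqrt(gval.var() * 0.25), n)
        fit = bayesb_fit(y, W, McmConfig(n_iter=2500, burn_in=800, thin=5, seed=3))
        top_decile = set(np.argsort(-np.abs(fit.effects))[: m // 10])
        assert all(q in top_decile for q in qtl)

    def test_null_inclusion_matches_prior(self):
        rng = np.random.default_rng(8)
        n, m = 80, 100
        W = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        y = rng.normal(size=n)
        cfg = McmConfig(n_iter=2000, burn_in=500, thin=2, pi=0.95, seed=5)
        fit = bayesb_fit(y, W, cfg)
        # mean posterior inclusion approximately the prior 1 - pi
        assert abs(fit.inclusion.mean() - 0.05) < 0.04

    def test_dense_limit_agrees_with_gblup(self, rng):
        # equal small effects everywhere ~ infinitesimal model: low pi BayesB
        # tracks the ridge/GBLUP fit
        n, m = 150, 120
        Za = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        b = rng.normal(0, 0.15, size=m)
        y = (Za - Za.mean(0)) @ b + rng.normal(0, 0.5, n)
        bb = bayesb_fit(y, Za, McmConfig(n_iter=2500, burn_in=800, thin=2,
                                         pi=0.05, seed=9))
        gb = reml_fit(y, Za, max_iter=300)
        assert np.corrcoef(bb.predict(Za), gb.predict(Za))[0, 1] > 0.99

    def test_determinism_and_config_validation(self, rng):
        W = rng.choice([0.0, 1.0, 2.0], size=(40, 30))
        y = rng.normal(size=40)
        cfg = McmConfig(n_iter=300, burn_in=100, thin=2, seed=4)
        f1 = bayesb_fit(y, W, cfg)
        f2 = bayesb_fit(y, W, cfg)
        assert np.array_equal(f1.effects, f2.effects)
        with pytest.raises(ConfigError):
            McmConfig(n_iter=100, burn_in=200)
        with pytest.raises(ConfigError):
            McmConfig(pi=1.0)


class TestLasso:
    def test_large_lambda_all_zero_mean_prediction(self, rng):
        W = rng.choice([0.0, 1.0, 2.0], size=(50, 20))
        y = rng.normal(2.0, 1.0, 50)
        fit = lasso_fit(y, W, lambdas=np.array([1e6]))
        assert not fit.coef.any()
        assert np.allclose(fit.predict(W), y.mean())

    def test_zero_lambda_orthonormal_equals_ols(self, rng):
        n, p = 60, 5
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        W = Q * np.sqrt(n)  # orthonormal columns after 1/sqrt(n) scaling
        beta = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
        y = W @ beta + rng.normal(0, 0.01, n)
        fit = lasso_fit(y, W, lambdas=np.array([0.0]))
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), W]), y, rcond=None)[0]
        assert np.allclose(fit.coef, ols[1:], atol=1e-6)

    def test_single_predictor_soft_threshold_closed_form(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 1.3 * x + rng.normal(0, 0.3, n)
        lam = 0.4
        fit = lasso_fit(y, x[:, None], lambdas=np.array([lam]))
        xs = (x - x.mean()) / x.std()
        yc = y - y.mean()
        rho = float(xs @ yc) / n
        expected_std = np.sign(rho) * max(abs(rho) - lam, 0.0)
        assert fit.coef[0] == pytest.approx(expected_std / x.std(), abs=1e-6)

    def test_matches_sklearn_coordinate_descent(self, rng):
        from sklearn.linear_model import Lasso

        n, m = 120, 40
        W = rng.normal(size=(n, m))
        beta = np.zeros(m)
        beta[:5] = [2, -1.5, 1, 3, -2]
        y = W @ beta + rng.normal(0, 0.5, n)
        lam = 0.1
        ours = lasso_fit(y, W, lambdas=np.array([lam]), tol=1e-8, max_passes=2000)
        sk = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000, tol=1e-10)
        Ws = (W - W.mean(0)) / W.std(0)
        sk.fit(Ws, y)
        assert np.allclose(ours.coef * W.std(0), sk.coef_, atol=1e-4)

    def test_zero_variance_columns_dropped_with_warning(self, rng):
        W = rng.normal(size=(30, 3))
        W[:, 1] = 7.0
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = lasso_fit(y, W, lambdas=np.array([0.1]))
        assert fit.coef[1] == 0.0

    def test_inner_cv_lambda_selection_runs(self, rng):
        n, m = 100, 50
        W = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        b = np.zeros(m)
        b[:3] = [2, -2, 1.5]
        y = W @ b + rng.normal(0, 1, n)
        fit = lasso_fit(y, W, seed=0)
        assert fit.cv_mse is not None and fit.lam > 0
        assert np.corrcoef(fit.predict(W), y)[0, 1] > 0.8


class TestCrossValidate:
    def test_perfect_and_null_predictions(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)

        perfect = cross_validate(lambda tr, te: y[te], y, folds=5, repeats=3, seed=0)
        assert perfect.mean == pytest.approx(1.0)

        rngs = np.random.default_rng(4)
        null = cross_validate(
            lambda tr, te: rngs.normal(size=len(te)), y, folds=5, repeats=20, seed=0
        )
        # ~N(0, 1/sqrt(n)) per repeat: mean within 3 MC sd of zero
        assert abs(null.mean) < 3 * null.sd / np.sqrt(null.repeats) + 0.05

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=60)
        fp = lambda tr, te: y[te] + 0.5 * rng.standard_normal(len(te))
        r1 = cross_validate(lambda tr, te: y[te] * 0.9, y, folds=4, repeats=3, seed=7)
        r2 = cross_validate(lambda tr, te: y[te] * 0.9, y, folds=4, repeats=3, seed=7)
        assert r1.per_repeat == r2.per_repeat

    def test_constant_observed_flagged(self):
        y = np.full(20, 1.0)
        res = cross_validate(lambda tr, te: np.arange(len(te), dtype=float), y,
                             folds=4, repeats=2, seed=0)
        assert res.flagged_repeats == [0, 1]
        assert np.isnan(res.mean)

    def test_too_few_observations(self):
        with pytest.raises(ModelError):
            cross_validate(lambda tr, te: te, np.ones(3), folds=5)


class TestEnvBlup:
    @staticmethod
    def balanced_frame(gmeans, env_effects, reps, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for gname, gm in gmeans.items():
            for ename, ee in env_effects.items():
                for _ in range(reps):
                    rows.append({"genotype": gname, "env": ename,
                                 "value": gm + ee + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_noiseless_blups_equal_genotype_means(self):
        df = self.balanced_frame({"g1": 10.0, "g2": 12.0, "g3": 8.0},
                                 {"E1": 1.0, "E2": -1.0}, reps=2)
        res = env_blup(df)
        assert np.allclose(res.blups.to_numpy(), [10.0, 12.0, 8.0], atol=1e-3)
        assert (res.anova["p"] < 0.01).all()

    def test_shrinkage_matches_closed_form_single_env(self):
        # balanced one-environment data: BLUP deviation = raw deviation times
        # sg2 / (sg2 + se2/r) at the estimated components
        rng = np.random.default_rng(6)
        reps, n_g = 4, 40
        gmeans = {f"g{i:02d}": float(rng.normal(0, 2)) for i in range(n_g)}
        df = self.balanced_frame(gmeans, {"E1": 0.0}, reps=reps, noise=1.5, seed=7)
        res = env_blup(df)
        sg2, se2 = res.varcomp["genotype"], res.varcomp["residual"]
        shrink = sg2 / (sg2 + se2 / reps)
        raw = df.groupby("genotype")["value"].mean()
        grand = df["value"].mean()
        expected = grand + shrink * (raw - grand)
        assert np.allclose(res.blups.to_numpy(),
                           expected.reindex(res.blups.index).to_numpy(), atol=1e-6)

    def test_environment_permutation_keeps_ranking(self):
        df = self.balanced_frame({"g1": 10.0, "g2": 13.0, "g3": 9.0},
                                 {"E1": 2.0, "E2": -2.0}, reps=2, noise=0.2, seed=8)
        res1 = env_blup(df)
        swapped = df.copy()
        swapped["env"] = swapped["env"].map({"E1": "E2", "E2": "E1"})
        res2 = env_blup(swapped)
        assert (res1.blups.rank() == res2.blups.rank()).all()
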