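import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from pbsis import (
    BinaryDataset,
    PenaltySpec,
    fit_path,
    fit_penalized_logistic,
    irls_working_response,
    lambda_grid,
    select_tuning,
    soft_threshold,
    two_stage_pbsis,
)
from pbsis.penalized import PenalizedFit, RegularizationPath, _standardize

from conftest import make_logistic_dataset


def lasso_objective(Xs, y, b0, beta, lam):
    """(1/n) negative log-likelihood + lam * ||beta||_1 on standardized X."""
    eta = b0 + Xs @ beta
    return float(np.mean(np.logaddexp(0, eta) - y * eta)) + lam * np.abs(beta).sum()


def lasso_oracle(Xs, y, lam):
    """Brute-force convex solve via positive/negative split + L-BFGS-B."""
    n, d = Xs.shape

    def obj(par):
        b0, a, b = par[0], par[1:1 + d], par[1 + d:]
        eta = b0 + Xs @ (a - b)
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        val = np.mean(np.logaddexp(0, eta) - y * eta) + lam * (a.sum() + b.sum())
        g0 = np.mean(p - y)
        gx = Xs.T @ (p - y) / n
        return val, np.concatenate([[g0], gx + lam, -gx + lam])

    res = minimize(
        obj, np.zeros(1 + 2 * d), jac=True, method="L-BFGS-B",
        bounds=[(None, None)] + [(0, None)] * (2 * d),
        options=dict(maxiter=20000, ftol=1e-16, gtol=1e-12),
    )
    return res.fun


class TestSoftThreshold:
    @pytest.mark.parametrize("z, g, expected", [(3, 1, 2), (-3, 1, -2), (0.5, 1, 0)])
    def test_examples(self, z, g, expected):
        assert soft_threshold(z, g) == expected

    @given(z=st.floats(-1e6, 1e6), g=st.floats(0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_odd_and_shrinking(self, z, g):
        s = soft_threshold(z, g)
        assert soft_threshold(-z, g) == -s
        assert abs(s) <= abs(z)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestWorkingResponse:
    def test_at_eta_zero(self):
        z, w = irls_working_response(np.zeros(2), np.array([1.0, 0.0]))
        np.testing.assert_allclose(w, [0.25, 0.25])
        np.testing.assert_allclose(z, [2.0, -2.0])

    def test_clamping_keeps_z_finite(self):
        z, w = irls_working_response(np.array([40.0]), np.array([1.0]))
        assert np.isfinite(z[0]) and w[0] == pytest.approx(1e-5 * (1 - 1e-5))


class TestPenaltySpec:
    def test_default_shapes(self):
        assert PenaltySpec("scad", 0.1).shape == 3.7
        assert PenaltySpec("mcp", 0.1).shape == 3.0
        assert PenaltySpec("lasso", 0.1).shape is None

    @pytest.mark.parametrize("family, shape", [("scad", 2.0), ("mcp", 1.0)])
    def test_shape_bounds(self, family, shape):
        with pytest.raises(ValueError):
            PenaltySpec(family, 0.1, shape)

    def test_penalty_values_continuous_at_region_edges(self):
        for family in ("scad", "mcp"):
            spec = PenaltySpec(family, 0.5)
            ts = np.linspace(0, 5 * spec.shape * spec.lam, 5000)
            vals = np.array([spec.value(t) for t in ts])
            assert np.all(np.diff(vals) >= -1e-12)  # nondecreasing in |t|
            assert np.max(np.abs(np.diff(vals))) < 0.01  # no jumps


class TestLambdaGrid:
    def test_two_point_grid(self, small_dataset):
        lams = lambda_grid(small_dataset, n_lambda=2, lambda_min_ratio=0.01)
        assert len(lams) == 2
        assert lams[1] == pytest.approx(0.01 * lams[0])

    def test_hand_computed_lambda_max(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1, 0, 1, 0])
        lams = lambda_grid(BinaryDataset(X, y), n_lambda=2)
        assert lams[0] == pytest.approx(0.5)

    def test_null_fit_at_lambda_max(self, small_dataset):
        path = fit_path(small_dataset, "lasso", n_lambda=30)
        assert path.fits[0].df == 0
        ybar = small_dataset.y.mean()
        assert path.fits[0].intercept == pytest.approx(
            math.log(ybar / (1 - ybar)), abs=1e-4
        )


class TestFitPenalizedLogistic:
    def test_lambda_zero_matches_unpenalized_mle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        data = make_logistic_dataset(rng, 200, 3)
        fit = fit_penalized_logistic(data, PenaltySpec("lasso", 0.0))
        ref = sm.Logit(data.y, sm.add_constant(data.X)).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coef], ref.params, atol=1e-5
        )
        assert fit.df == 3 and fit.converged

    def test_lasso_objective_matches_convex_oracle(self, rng):
        # >= 20 random small instances against a generic convex solver
        for trial in range(20):
            n = int(rng.integers(30, 61))
            d = int(rng.integers(2, 9))
            data = make_logistic_dataset(rng, n, d)
            lam = float(rng.uniform(0.02, 0.2))
            fit = fit_penalized_logistic(data, PenaltySpec("lasso", lam))
            Xs, _, _ = _standardize(data.X)
            b0, beta = fit._std_state
            ours = lasso_objective(Xs, data.y.astype(float), b0, beta, lam)
            oracle = lasso_oracle(Xs, data.y.astype(float), lam)
            assert ours <= oracle + 1e-5

    def test_lasso_kkt_certificate(self, rng):
        for trial in range(10):
            data = make_logistic_dataset(rng, 60, 8)
            lam = 0.05
            fit = fit_penalized_logistic(data, PenaltySpec("lasso", lam))
            Xs, _, _ = _standardize(data.X)
            b0, beta = fit._std_state
            p = 1.0 / (1.0 + np.exp(-(b0 + Xs @ beta)))
            g = Xs.T @ (data.y - p) / data.n
            active = beta != 0
            if active.any():
                np.testing.assert_allclose(np.abs(g[active]), lam, atol=1e-4)
            if (~active).any():
                assert np.all(np.abs(g[~active]) <= lam + 1e-4)

    def test_large_lambda_gives_null_model(self, small_dataset):
        lam = float(lambda_grid(small_dataset, 2)[0]) * 1.5
        fit = fit_penalized_logistic(small_dataset, PenaltySpec("lasso", lam))
        assert fit.df == 0

    @pytest.mark.parametrize("family", ["scad", "mcp"])
    def test_nonconvex_penalties_reduce_to_lasso_at_large_shape(self, rng, family):
        data = make_logistic_dataset(rng, 80, 6)
        lam = 0.08
        ref = fit_penalized_logistic(data, PenaltySpec("lasso", lam))
        fit = fit_penalized_logistic(data, PenaltySpec(family, lam, shape=1e6))
        np.testing.assert_allclose(fit.coef, ref.coef, atol=1e-3)

    @pytest.mark.parametrize("family", ["scad", "mcp"])
    def test_nonconvex_fit_descends_from_lasso_start(self, rng, family):
        # the nonconvex solution's penalized objective is never worse than
        # evaluating the same objective at the lasso solution
        data = make_logistic_dataset(rng, 80, 6)
        lam = 0.08
        spec = PenaltySpec(family, lam)
        fit = fit_penalized_logistic(data, spec)
        lasso = fit_penalized_logistic(data, PenaltySpec("lasso", lam))
        Xs, _, _ = _standardize(data.X)
        y = data.y.astype(float)

        def obj(state):
            b0, beta = state
            eta = b0 + Xs @ beta
            nll = float(np.mean(np.logaddexp(0, eta) - y * eta))
            return nll + sum(spec.value(b) for b in beta)

        assert obj(fit._std_state) <= obj(lasso._std_state) + 1e-8


class TestPath:
    def test_lambdas_strictly_decreasing_and_warm_start_continuity(self, rng):
        data = make_logistic_dataset(rng, 100, 10)
        path = fit_path(data, "lasso", n_lambda=40)
        assert np.all(np.diff(path.lambdas) < 0)
        # coefficients move continuously along the grid
        coefs = np.array([f.coef for f in path.fits])
        assert np.max(np.abs(np.diff(coefs, axis=0))) < 1.0
        assert all(f.converged for f in path.fits)

    def test_rejects_increasing_grid(self, small_dataset):
        with pytest.raises(ValueError, match="decreasing"):
            fit_path(small_dataset, "lasso", lambdas=np.array([0.1, 0.2]))


class TestSelectTuning:
    def _toy_path(self, devs, dfs, lams):
        fits = [
            PenalizedFit(0.0, np.ones(df), PenaltySpec("lasso", lam), df, dev, True, 1)
            for dev, df, lam in zip(devs, dfs, lams)
        ]
        return RegularizationPath(np.asarray(lams, dtype=float), fits)

    def test_single_lambda_path_returned_for_every_criterion(self, small_dataset):
        path = fit_path(small_dataset, "lasso", n_lambda=30)
        single = RegularizationPath(path.lambdas[:1], path.fits[:1])
        for crit in ("cv", "aic", "bic", "ebic"):
            fit = select_tuning(single, crit, small_dataset, folds=5, seed=0)
            assert fit is single.fits[0]

    @pytest.mark.parametrize("crit", ["aic", "bic", "ebic"])
    def test_equal_deviance_prefers_sparser_model(self, small_dataset, crit):
        path = self._toy_path([50.0, 50.0], [2, 5], [0.2, 0.1])
        fit = select_tuning(path, crit, small_dataset)
        assert fit.df == 2

    def test_ebic_never_larger_than_aic(self, rng):
        from pbsis import ModelSpec, generate_dataset

        data, _ = generate_dataset(ModelSpec.table_model(1), (8, 0))
        sub = data.subset(list(range(21)))
        path = fit_path(sub, "lasso")
        aic = select_tuning(path, "aic", sub)
        ebic = select_tuning(path, "ebic", sub)
        assert ebic.df <= aic.df

    def test_cv_is_deterministic_under_seed(self, rng):
        data = make_logistic_dataset(rng, 90, 8)
        path = fit_path(data, "lasso", n_lambda=40)
        f1 = select_tuning(path, "cv", data, folds=5, seed=42)
        f2 = select_tuning(path, "cv", data, folds=5, seed=42)
        assert f1.penalty.lam == f2.penalty.lam

    def test_cv_requires_enough_members_per_class(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(3), np.zeros(17)].astype(int)
        data = BinaryDataset(X, y)
        path = fit_path(data, "lasso", n_lambda=10)
        with pytest.raises(ValueError, match="per class"):
            select_tuning(path, "cv", data, folds=10, seed=0)

    def test_unknown_criterion(self, small_dataset):
        path = fit_path(small_dataset, "lasso", n_lambda=10)
        with pytest.raises(ValueError, match="criterion"):
            select_tuning(path, "gcv", small_dataset)


class TestTwoStage:
    def test_final_support_within_screened_set(self, rng):
        data = make_logistic_dataset(rng, 100, 40)
        screen, fit, support = two_stage_pbsis(data, 10, "lasso", "bic")
        assert set(support) <= set(screen.selected.tolist())
        assert len(support) == fit.df

    def test_d_equal_p_reduces_to_one_stage(self, rng):
        data = make_logistic_dataset(rng, 120, 6)
        screen, fit, support = two_stage_pbsis(data, 6, "lasso", "bic")
        # one-stage: same path + tuning on all predictors in ranked order
        sub = data.subset(screen.selected)
        path = fit_path(sub, "lasso")
        direct = select_tuning(path, "bic", sub)
        assert fit.penalty.lam == direct.penalty.lam
        assert set(support) == set(screen.selected[direct.support].tolist())

    def test_excluded_true_predictor_cannot_reappear(self, rng):
        # stage-2 support is drawn from the screened columns only
        data = make_logistic_dataset(rng, 80, 30)
        screen, _, support = two_stage_pbsis(data, 5, "lasso", "bic")
        excluded = set(range(30)) - set(screen.selected.tolist())
        assert not (set(support) & excluded)
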