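"""Feature-weighted Cox elastic net: weights, path, theta, CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopernet.cox_core import CauseView, cox_gradient
from coopernet.fwcoxnet import (
    FeatureInfo,
    PenaltyConfig,
    cv_partial_loglik,
    fit_fwcoxnet,
    lambda_path,
    make_cv_folds,
    solve_beta,
    update_theta,
    weight_vector,
)

from conftest import random_survival


class TestWeightVector:
    def test_theta_zero_collapses_to_unit_weights(self, rng):
        z = rng.uniform(0, 5, size=20)
        assert np.allclose(weight_vector(z, 0.0).w, 1.0)

    def test_two_feature_arithmetic(self):
        wv = weight_vector(np.array([0.0, np.log(3)]), 1.0)
        assert wv.w == pytest.approx([2.0, 2.0 / 3.0])
        assert np.sum(1.0 / wv.w) == pytest.approx(2.0)

    def test_larger_scores_get_smaller_penalties(self):
        z = np.array([4.0, 2.0, 1.0, 0.5, 0.1])
        w = weight_vector(z, 1.0).w
        assert np.all(np.diff(w) > 0)  # scores descend, so weights ascend

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 50), min_size=2, max_size=30),
           st.floats(-50, 50))
    def test_harmonic_mean_identity(self, z, theta):
        wv = weight_vector(np.asarray(z), theta)
        assert np.all(wv.w > 0)
        assert wv.harmonic_identity_gap < 1e-8 * len(z)

    def test_overflow_guarded(self):
        w = weight_vector(np.array([0.0, 1.0]), 500.0).w
        assert np.all(np.isfinite(w[1:])) and w[1] < 1.0


class TestLambdaPath:
    def test_fit_at_lambda_max_is_null(self, rng):
        view, X = random_survival(rng, 80, 6)
        lams = lambda_path(view, X, 1.0)
        assert np.all(solve_beta(view, X, 1.0, lams[0]) == 0.0)
        assert np.any(solve_beta(view, X, 1.0, lams[-1]) != 0.0)

    def test_doubling_weights_halves_lambda_max(self, rng):
        view, X = random_survival(rng, 60, 4)
        l1 = lambda_path(view, X, 1.0, w=np.ones(4))[0]
        l2 = lambda_path(view, X, 1.0, w=2 * np.ones(4))[0]
        assert l2 == pytest.approx(l1 / 2)

    def test_lambda_max_matches_bisection_oracle(self, rng):
        view, X = random_survival(rng, 60, 4)
        lam_max = lambda_path(view, X, 1.0)[0]
        lo, hi = 1e-4, 10.0
        for _ in range(40):
            mid = np.sqrt(lo * hi)
            if np.all(solve_beta(view, X, 1.0, mid) == 0.0):
                hi = mid
            else:
                lo = mid
        assert lam_max == pytest.approx(hi, rel=1e-2)

    def test_alpha_zero_uses_surrogate(self, rng):
        view, X = random_survival(rng, 60, 4)
        lams = lambda_path(view, X, 0.0)
        assert np.all(np.isfinite(lams)) and lams[0] > 0


class TestSolveBeta:
    def test_unpenalized_matches_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        view, X = random_survival(rng, 150, 4)
        b = solve_beta(view, X, 1.0, 0.0)
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(4)])
        df["T"], df["E"] = view.time, view.delta
        cph = CoxPHFitter().fit(df, "T", "E")
        assert np.max(np.abs(b - cph.params_.values)) < 1e-4

    def test_unit_weights_match_coxnet_oracle(self, rng):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        view, X = random_survival(rng, 120, 25)
        lams = lambda_path(view, X, 1.0, n_lambda=15, lambda_min_ratio=0.05)
        y = np.array([(bool(d), t) for d, t in zip(view.delta, view.time)],
                     dtype=[("e", bool), ("t", float)])
        oracle = CoxnetSurvivalAnalysis(alphas=lams, l1_ratio=1.0, normalize=False,
                                        tol=1e-12).fit(X, y)
        b = np.zeros(25)
        for i, lam in enumerate(lams):
            b = solve_beta(view, X, 1.0, lam, beta_init=b)
            assert np.max(np.abs(b - oracle.coef_[:, i])) < 1e-4

    def test_kkt_conditions_hold_at_solution(self, rng):
        view, X = random_survival(rng, 100, 12)
        w = weight_vector(rng.uniform(0, 1, 12), 1.5).w
        lam = 0.5 * lambda_path(view, X, 1.0, w=w)[0]
        b = solve_beta(view, X, 1.0, lam, w=w)
        g = cox_gradient(b, view, X) / 100
        zero = b == 0.0
        assert np.all(np.abs(g[zero]) <= lam * w[zero] + 1e-4)
        # active coordinates sit on the subgradient boundary
        assert np.allclose(np.abs(g[~zero]), lam * w[~zero], atol=1e-4)


class TestUpdateTheta:
    def test_constant_scores_leave_objective_unchanged(self, rng):
        view, X = random_survival(rng, 50, 5)
        beta = rng.normal(size=5)
        th = update_theta(view, X, beta, np.ones(5), 1.0, 0.1, theta_init=0.3)
        assert th == 0.3

    def test_never_worse_than_theta_zero(self, rng):
        view, X = random_survival(rng, 50, 8)
        z = rng.uniform(0, 1, 8)
        beta = rng.normal(size=8) * (rng.uniform(size=8) < 0.6)
        th = update_theta(view, X, beta, z, 1.0, 0.2, theta_init=0.0)
        q = np.abs(beta)
        assert float(weight_vector(z, th).w @ q) <= float(weight_vector(z, 0.0).w @ q) + 1e-12

    def test_brackets_grid_oracle(self, rng):
        z = rng.uniform(0, 1, 30)
        beta = rng.normal(size=30) * (rng.uniform(size=30) < 0.4)
        view, X = random_survival(rng, 40, 30)
        thresh = 1e-7
        th = update_theta(view, X, beta, z, 1.0, 0.1, theta_init=0.0, thresh=thresh)
        q = np.abs(beta)

        def g(t):
            return float(weight_vector(z, t).w @ q)

        grid = np.linspace(-50, 50, 10001)
        best = min(g(t) for t in grid)
        assert g(th) <= best + thresh * max(1.0, best) + 1e-9


class TestFitFwcoxnet:
    def test_zero_scores_equal_plain_elastic_net(self, rng):
        view, X = random_survival(rng, 90, 10)
        cfg = PenaltyConfig(alpha=1.0, nfolds=4, n_lambda=25)
        f0 = fit_fwcoxnet(view, X, z=None, config=cfg, seed=5)
        fz = fit_fwcoxnet(view, X, z=np.zeros(10), config=cfg, seed=5)
        assert np.allclose(f0.beta, fz.beta, atol=1e-6)
        assert f0.lambda_selected == fz.lambda_selected

    def test_accepts_feature_info(self, rng):
        view, X = random_survival(rng, 90, 10)
        cfg = PenaltyConfig(alpha=1.0, nfolds=4, n_lambda=20)
        f = fit_fwcoxnet(view, X, z=FeatureInfo(np.abs(rng.normal(size=10))),
                         config=cfg, seed=2)
        assert f.beta.shape == (10,)

    def test_all_censored_returns_null_fit_with_warning(self, rng):
        X = rng.standard_normal((30, 4))
        view = CauseView(time=rng.uniform(1, 2, 30), delta=np.zeros(30))
        with pytest.warns(UserWarning, match="null fit"):
            f = fit_fwcoxnet(view, X, config=PenaltyConfig(nfolds=3))
        assert f.null_fit and np.all(f.beta == 0.0)

    def test_too_few_events_for_cv_raises(self, rng):
        X = rng.standard_normal((30, 4))
        delta = np.zeros(30)
        delta[:3] = 1.0
        view = CauseView(time=rng.uniform(1, 2, 30), delta=delta)
        with pytest.raises(ValueError, match="fewer than nfolds"):
            fit_fwcoxnet(view, X, config=PenaltyConfig(nfolds=10))

    def test_objective_trace_nonincreasing(self, rng):
        view, X = random_survival(rng, 100, 15)
        cfg = PenaltyConfig(alpha=1.0, nfolds=4, n_lambda=25)
        f = fit_fwcoxnet(view, X, z=np.abs(rng.normal(size=15)), config=cfg, seed=3)
        assert np.all(np.diff(f.objective_trace) <= 1e-8)

    def test_deterministic_replay(self, rng):
        view, X = random_survival(rng, 90, 10)
        cfg = PenaltyConfig(alpha=1.0, nfolds=4, n_lambda=20)
        a = fit_fwcoxnet(view, X, z=np.abs(rng.normal(size=10)), config=cfg, seed=9)
        b = fit_fwcoxnet(view, X, z=a.beta * 0 + np.abs(a.beta), config=cfg, seed=9)
        c = fit_fwcoxnet(view, X, z=np.abs(a.beta), config=cfg, seed=9)
        assert np.array_equal(b.beta, c.beta) and b.theta == c.theta


class TestCvPartialLoglik:
    def test_null_beta_hand_evaluation(self):
        # 5 observations, 2 folds, beta = 0 for both: each fold contributes
        # (sum log risk sizes on all data) - (sum log risk sizes on train)
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        delta = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        view = CauseView(time=time, delta=delta)
        X = np.zeros((5, 1))
        folds = [np.array([0, 1]), np.array([2, 3, 4])]
        B = np.zeros((1, 1))
        cv = cv_partial_loglik(view, X, [B, B], folds)
        full = np.log(5) + np.log(3) + np.log(2)
        train1 = np.log(3) + np.log(2)  # rows 2,3,4: events at t=3 (risk 3), t=4 (risk 2)
        train2 = np.log(2)              # rows 0,1: event at t=1 (risk 2)
        assert cv[0] == pytest.approx(-((full - train1) + (full - train2)))

    def test_folds_must_partition(self, rng):
        view, X = random_survival(rng, 10, 2)
        with pytest.raises(ValueError, match="partition"):
            cv_partial_loglik(view, X, [np.zeros((1, 2))], [np.array([0, 1])])


class TestMakeCvFolds:
    def test_stratified_spreads_events(self, rng):
        delta = np.zeros(100)
        delta[:10] = 1.0
        folds = make_cv_folds(delta, 5, True, 42)
        assert sorted(np.concatenate(folds).tolist()) == list(range(100))
        assert all(delta[f].sum() == 2 for f in folds)

    def test_deterministic_given_seed(self):
        delta = np.r_[np.ones(20), np.zeros(40)]
        a = make_cv_folds(delta, 4, False, 7)
        b = make_cv_folds(delta, 4, False, 7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
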