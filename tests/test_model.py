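import numpy as np
import pytest

from conftest import cd_lasso_oracle, kkt_residual, soft_threshold

from connpredict.exceptions import CovariateError, PartitionError
from connpredict.model import (
    LassoLarsLOOCV,
    SexResidualizer,
    StandardizedLasso,
    fit_lasso,
    lars_lambda_path,
    leave_k_out_cv,
    residualize_on_sex,
    select_lambda_loocv,
)


class TestResidualizeOnSex:
    def test_sex_indicator_feature_goes_to_zero(self):
        sex = np.array([0, 0, 0, 1, 1, 1])
        X = np.column_stack([sex.astype(float), np.ones(6)])
        res = residualize_on_sex(X, sex)
        assert np.allclose(res[:, 0], 0.0, atol=1e-12)

    def test_orthogonal_feature_only_centered(self):
        sex = np.array([0, 0, 1, 1])
        x = np.array([1.0, 3.0, 1.0, 3.0])  # equal group means
        res = residualize_on_sex(x[:, None], sex)
        assert np.allclose(res[:, 0], x - x.mean())

    def test_equals_group_mean_subtraction(self):
        # two-group regression identity: residual = value - own-group mean
        rng = np.random.default_rng(0)
        sex = np.array([0, 1, 0, 1, 1, 0])
        X = rng.normal(size=(6, 3))
        res = residualize_on_sex(X, sex)
        for g in (0, 1):
            expected = X[sex == g] - X[sex == g].mean(axis=0)
            assert np.allclose(res[sex == g], expected, atol=1e-12)

    def test_single_sex_cohort_rejected(self):
        with pytest.raises(CovariateError):
            residualize_on_sex(np.ones((4, 2)), np.zeros(4))

    def test_estimator_transform_uses_training_groups(self):
        sex = np.array([0, 0, 1, 1])
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        est = SexResidualizer().fit(X, sex)
        out = est.transform(np.array([[1.0], [11.0]]), np.array([0, 1]))
        assert np.allclose(out.ravel(), [0.0, 0.0])


class TestFitLasso:
    def test_lambda_zero_is_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=20)
        m = fit_lasso(X, y, 0.0)
        A = np.column_stack([np.ones(20), X])
        ref, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose([m.intercept, *m.betas], ref, atol=1e-8)

    def test_lambda_max_kills_all_betas(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / len(y)
        m = fit_lasso(X, y, lam_max * 1.0001)
        assert np.allclose(m.betas, 0.0)
        assert m.intercept == pytest.approx(y.mean())

    def test_matches_coordinate_descent_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        lam = 0.15
        m = fit_lasso(X, y, lam)
        b0, b = cd_lasso_oracle(X, y, lam)
        assert np.allclose(m.betas, b, atol=1e-6)
        assert m.intercept == pytest.approx(b0, abs=1e-6)
        assert kkt_residual(X, y, m.intercept, m.betas, lam) < 1e-6

    def test_oracle_objective_descends_and_meets_kkt(self):
        # monotone objective decrease along the oracle's own sweeps
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        lam = 0.1
        from conftest import lasso_objective

        n = len(y)
        xbar, ybar = X.mean(axis=0), y.mean()
        Xc, yc = X - xbar, y - ybar
        col_sq = (Xc**2).sum(axis=0) / n
        b = np.zeros(5)
        resid = yc.copy()
        prev = lasso_objective(X, y, ybar - xbar @ b, b, lam)
        for _ in range(50):
            for j in range(5):
                rho = Xc[:, j] @ resid / n + col_sq[j] * b[j]
                new = soft_threshold(rho, lam) / col_sq[j]
                resid -= Xc[:, j] * (new - b[j])
                b[j] = new
            obj = lasso_objective(X, y, ybar - xbar @ b, b, lam)
            assert obj <= prev + 1e-12
            prev = obj
        assert kkt_residual(X, y, ybar - xbar @ b, b, lam) < 1e-6


class TestLarsPath:
    def test_orthonormal_design_knots_are_sorted_correlations(self):
        rng = np.random.default_rng(5)
        n, m = 32, 5
        raw = rng.normal(size=(n, m))
        raw -= raw.mean(axis=0)  # orthonormalize within the centered space
        Q, _ = np.linalg.qr(raw)
        X = Q * np.sqrt(n)  # zero-mean columns with X'X = n I
        y = rng.normal(size=n)
        knots = lars_lambda_path(X, y)
        c = np.abs(X.T @ (y - y.mean())) / n
        expected = np.sort(c)[::-1]
        assert np.allclose(knots[: m], expected, atol=1e-10)
        assert knots[-1] == 0.0

    def test_single_predictor_two_knots(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        y = 2 * x + rng.normal(size=10)
        knots = lars_lambda_path(x[:, None], y)
        lam_max = abs(x @ (y - y.mean())) / 10
        assert np.allclose(knots, [lam_max, 0.0])

    def test_strictly_decreasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        knots = lars_lambda_path(X, y)
        assert np.all(np.diff(knots) < 0)

    def test_path_coefficients_piecewise_linear(self):
        # solutions at knot midpoints equal the average of knot solutions
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, -1.0, 0.0, 0.5] + rng.normal(size=30) * 0.3
        knots = lars_lambda_path(X, y)
        for a, b in zip(knots[:-2], knots[1:-1]):
            mid = (a + b) / 2
            beta_mid = fit_lasso(X, y, mid).betas
            avg = (fit_lasso(X, y, a).betas + fit_lasso(X, y, b).betas) / 2
            assert np.allclose(beta_mid, avg, atol=1e-5)


def loocv_oracle(X, y, candidates):
    """Exhaustive double loop (candidate x left-out subject) selection."""
    n = len(y)
    best_lam, best_score = None, -np.inf
    for lam in sorted(candidates, reverse=True):
        preds = np.empty(n)
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            b0, b = cd_lasso_oracle((X[tr] - mu) / sd, y[tr], lam)
            preds[i] = b0 + ((X[i] - mu) / sd) @ b
        if np.std(preds) == 0:
            continue
        score = np.corrcoef(preds, y)[0, 1]
        if score > best_score:
            best_lam, best_score = lam, score
    return best_lam


class TestSelectLambdaLoocv:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        y = X @ [2.0, 0.0, -1.0, 0.0] + rng.normal(size=12) * 0.5
        candidates = [1.0, 0.5, 0.25, 0.1, 0.05, 0.01]
        lam = select_lambda_loocv(X, y, candidates=candidates)
        assert lam == pytest.approx(loocv_oracle(X, y, candidates))

    def test_strong_feature_recovered(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 10))
        y = 3.0 * X[:, 4]
        lam = select_lambda_loocv(X, y)
        est = StandardizedLasso(lam=lam).fit(X, y)
        assert est.coef_[4] != 0
        assert np.corrcoef(est.predict(X), y)[0, 1] > 0.99

    def test_pure_noise_does_not_crash(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(16, 6))
        y = rng.normal(size=16)
        lam = select_lambda_loocv(X, y)
        assert lam >= 0

    def test_loocv_estimator_exposes_sklearn_api(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(24, 6))
        y = X[:, 0] - X[:, 3] + 0.1 * rng.normal(size=24)
        est = LassoLarsLOOCV().fit(X, y)
        assert est.lambda_ > 0
        assert est.predict(X).shape == (24,)
        assert est.get_params() == {"candidates": None}


class TestLeaveKOutCV:
    def test_exact_linear_signal_recovered(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(58, 40))
        y = X @ np.r_[2.0, -1.5, 1.0, np.zeros(37)]  # zero noise
        lam = select_lambda_loocv(X, y)
        res = leave_k_out_cv(X, y, lam, k=10, repeats=10, seed=1)
        assert res.R > 0.99

    def test_null_mean_r_at_or_below_zero(self):
        rng = np.random.default_rng(14)
        Rs = []
        for s in range(15):
            X = rng.normal(size=(30, 12))
            y = rng.normal(size=30)
            Rs.append(leave_k_out_cv(X, y, 0.3, k=10, repeats=3, seed=s).R)
        assert np.mean(Rs) <= 0.1

    def test_seed_reproducibility_to_last_bit(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        a = leave_k_out_cv(X, y, 0.2, k=6, repeats=4, seed=99)
        b = leave_k_out_cv(X, y, 0.2, k=6, repeats=4, seed=99)
        assert np.array_equal(a.per_repeat_R, b.per_repeat_R)
        assert np.array_equal(a.predicted, b.predicted)

    def test_fold_partition_covers_each_subject_once(self):
        from connpredict.model import _fold_indices

        rng = np.random.default_rng(16)
        folds = _fold_indices(58, 10, rng)
        assert [len(f) for f in folds] == [10, 10, 10, 10, 10, 8]
        assert sorted(np.concatenate(folds)) == list(range(58))

    def test_fold_size_must_be_below_n(self):
        with pytest.raises(PartitionError):
            leave_k_out_cv(np.ones((10, 2)), np.arange(10), 0.1, k=10)

    def test_mean_r_non_decreasing_in_effect_size(self, small_pool):
        # same seeds across three planted effect levels, 20 cohorts each
        from connpredict.experiments import evaluate_cell
        from connpredict.simulate import SimulationConfig, generate_cohort
        from connpredict.atlas import build_network

        net = build_network(small_pool, "netA")
        means = []
        for effect in (0.0, 0.25, 0.5):
            Rs = []
            for s in range(20):
                cfg = SimulationConfig(
                    effect_size=effect, informative_network="netA",
                    n_informative_edges=3, seed=1000 + s,
                )
                cohort = generate_cohort(cfg, pool=small_pool)
                Rs.append(evaluate_cell(cohort, net, "EC", seed=s).R)
            means.append(np.mean(Rs))
        assert means[0] <= means[1] <= means[2]
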