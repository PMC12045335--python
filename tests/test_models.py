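"""Unit and oracle tests for the maximum-likelihood fitters."""

import numpy as np
import pytest
from scipy import optimize, stats

from sympercept import models
from conftest import simulate_multinomial, simulate_ordinal


# ---------------------------------------------------------------------------
# multinomial
# ---------------------------------------------------------------------------

def test_intercept_only_multinomial_recovers_empirical_frequencies():
    y = np.repeat([1, 2, 3], 60)
    X = np.ones((180, 1))
    fit = models.fit_multinomial(X, y)
    P = models.predict_category_probs(fit, X)
    assert np.allclose(P, 1.0 / 3.0, atol=1e-8)


def test_two_level_multinomial_equals_binary_logit(rng):
    X = np.column_stack([np.ones(300), rng.standard_normal(300)])
    y = (rng.random(300) < 1.0 / (1.0 + np.exp(-(0.3 + 0.8 * X[:, 1])))).astype(int)
    mfit = models.fit_multinomial(X, y, ref_category=0)
    bfit = models.fit_logistic(X, y)
    assert np.allclose(mfit.coef[0], bfit.coef, atol=1e-6)
    assert np.isclose(mfit.loglik, bfit.loglik, atol=1e-8)


def test_multinomial_matches_generic_optimizer_oracle(rng):
    """Newton estimates agree with a generic numerical maximizer of the
    explicitly written multinomial log-likelihood to 1e-6 relative."""
    B_true = np.array([[-0.5, 0.8, -0.4], [0.2, -0.6, 0.9]])
    X, y = simulate_multinomial(rng, 200, B_true)
    fit = models.fit_multinomial(X, y)

    Y = np.column_stack([(y == c).astype(float) for c in (1, 2, 3)])

    def negll(b):
        B = b.reshape(2, 3)
        eta = np.column_stack([np.zeros(len(X)), X @ B.T])
        return -(np.sum(Y * eta) - np.sum(np.log(np.sum(np.exp(eta), axis=1))))

    def grad(b):
        B = b.reshape(2, 3)
        eta = np.column_stack([np.zeros(len(X)), X @ B.T])
        P = np.exp(eta - eta.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        return -((Y[:, 1:] - P[:, 1:]).T @ X).ravel()

    res = optimize.minimize(negll, np.zeros(6), jac=grad, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    oracle = res.x.reshape(2, 3)
    assert np.allclose(fit.coef, oracle, rtol=1e-6, atol=1e-8)
    assert np.isclose(fit.loglik, -res.fun, rtol=1e-10)


def test_multinomial_agrees_with_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    B_true = np.array([[-0.3, 0.5], [0.4, -0.7]])
    X, y = simulate_multinomial(rng, 400, B_true)
    fit = models.fit_multinomial(X, y)
    ref = sm.MNLogit(y, X).fit(disp=0, method="newton")
    assert np.allclose(fit.coef, ref.params.T, atol=1e-5)


def test_predicted_probability_rows_sum_to_one(rng):
    B_true = np.array([[-0.5, 0.8], [0.2, -0.6], [0.1, 0.3]])
    X, y = simulate_multinomial(rng, 500, B_true)
    fit = models.fit_multinomial(X, y)
    P = models.predict_category_probs(fit, X)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((P > 0) & (P < 1))


def test_predict_probs_closed_forms():
    fit = models.MultinomialFit(
        categories=np.array([1, 2, 3]), ref_category=1,
        coef=np.zeros((2, 2)), cov=np.eye(4), loglik=-1.0, n_obs=10,
        converged=True)
    P = models.predict_category_probs(fit, np.array([[1.0, 2.0]]))
    assert np.allclose(P, 1.0 / 3.0)
    # intercept-only (ln 2, 0) with ref first: softmax(0, ln2, 0)
    fit2 = models.MultinomialFit(
        categories=np.array([1, 2, 3]), ref_category=1,
        coef=np.array([[np.log(2.0)], [0.0]]), cov=np.eye(2), loglik=-1.0,
        n_obs=10, converged=True)
    P2 = models.predict_category_probs(fit2, np.array([[1.0]]))
    assert np.allclose(P2, [[0.25, 0.50, 0.25]])


def test_predict_probs_dimension_mismatch_rejected():
    fit = models.MultinomialFit(
        categories=np.array([1, 2]), ref_category=1,
        coef=np.zeros((1, 3)), cov=np.eye(3), loglik=-1.0, n_obs=10,
        converged=True)
    with pytest.raises(ValueError, match="columns"):
        models.predict_category_probs(fit, np.ones((5, 2)))


def test_multinomial_rejects_single_level():
    with pytest.raises(ValueError):
        models.fit_multinomial(np.ones((10, 1)), np.ones(10))


# ---------------------------------------------------------------------------
# ordinal proportional odds
# ---------------------------------------------------------------------------

def test_ordinal_intercept_only_thresholds_are_cumulative_logits():
    y = np.repeat([1, 2, 3], [50, 30, 20])
    X = np.ones((100, 1))  # constant column absorbed into thresholds
    fit = models.fit_ordinal_po(X, y)
    assert np.allclose(fit.thresholds, [0.0, np.log(4.0)], atol=1e-6)


def test_ordinal_two_levels_reduces_to_logistic(rng):
    X = rng.standard_normal((400, 1))
    y = (rng.random(400) < 1.0 / (1.0 + np.exp(-(0.2 + 0.9 * X[:, 0])))).astype(int)
    ofit = models.fit_ordinal_po(X, y)
    bfit = models.fit_logistic(np.column_stack([np.ones(400), X]), y)
    # logit P(Y<=0) = theta - x'b  <=>  logit P(Y=1) = -theta + x'b
    assert np.isclose(ofit.slopes[0], bfit.coef[1], atol=1e-6)
    assert np.isclose(ofit.thresholds[0], -bfit.coef[0], atol=1e-6)


def test_ordinal_matches_generic_optimizer_oracle(rng):
    theta_true = [-1.0, 0.2, 1.5]
    beta_true = [0.8, -0.5]
    X, y = simulate_ordinal(rng, 500, theta_true, beta_true)
    fit = models.fit_ordinal_po(X, y)

    def negll(par):
        th = par[:3]
        if np.any(np.diff(th) <= 0):
            return 1e10
        b = par[3:]
        eta = X @ b
        th_ext = np.concatenate([[-np.inf], th, [np.inf]])
        A = 1.0 / (1.0 + np.exp(-(th_ext[y] - eta)))
        B = 1.0 / (1.0 + np.exp(-(th_ext[y - 1] - eta)))
        return -np.sum(np.log(A - B))

    res = optimize.minimize(negll, np.array([-1.0, 0.0, 1.0, 0.0, 0.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    oracle = res.x
    mine = np.concatenate([fit.thresholds, fit.slopes])
    assert np.allclose(mine, oracle, rtol=1e-6, atol=1e-5)
    assert fit.loglik >= -res.fun - 1e-7


def test_ordinal_agrees_with_statsmodels(rng):
    OrderedModel = pytest.importorskip(
        "statsmodels.miscmodels.ordinal_model").OrderedModel
    X, y = simulate_ordinal(rng, 600, [-0.8, 0.5, 1.8], [0.7])
    fit = models.fit_ordinal_po(X, y)
    ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
    assert np.isclose(fit.slopes[0], ref.params[0], atol=1e-4)
    assert np.isclose(fit.loglik, ref.llf, atol=1e-5)


# ---------------------------------------------------------------------------
# parallel lines
# ---------------------------------------------------------------------------

def test_parallel_lines_zero_statistic_when_likelihoods_equal():
    cats = np.array([1, 2, 3])
    ofit = models.OrdinalFit(categories=cats, thresholds=np.array([0.0, 1.0]),
                             slopes=np.array([0.5]), loglik=-100.0,
                             converged=True, n_obs=50)
    mfit = models.MultinomialFit(categories=cats, ref_category=1,
                                 coef=np.zeros((2, 2)), cov=np.eye(4),
                                 loglik=-100.0, n_obs=50, converged=True)
    res = models.test_parallel_lines(ofit, mfit)
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_parallel_lines_df_formula():
    cats = np.arange(1, 6)
    ofit = models.OrdinalFit(categories=cats, thresholds=np.arange(4.0),
                             slopes=np.array([0.5, -0.2]), loglik=-100.0,
                             converged=True, n_obs=50)
    mfit = models.MultinomialFit(categories=cats, ref_category=1,
                                 coef=np.zeros((4, 3)), cov=np.eye(12),
                                 loglik=-99.0, n_obs=50, converged=True)
    assert models.test_parallel_lines(ofit, mfit).df == 6  # 2 slopes x (5-2)


def test_parallel_lines_null_calibration(rng):
    """Under data generated exactly from a proportional-odds model the test
    should rarely reject: statistic small and non-significant in >=90% of
    replicates (and never negative)."""
    keep = 0
    for _ in range(50):
        X, y = simulate_ordinal(rng, 400, [-0.5, 0.7, 1.8], [0.6, -0.3])
        Xd = np.column_stack([np.ones(len(X)), X])
        ofit = models.fit_ordinal_po(Xd, y)
        mfit = models.fit_multinomial(Xd, y)
        res = models.test_parallel_lines(ofit, mfit)
        assert res.statistic >= -1e-8
        if res.p > 0.05:
            keep += 1
    assert keep >= 45


# ---------------------------------------------------------------------------
# logistic
# ---------------------------------------------------------------------------

def test_logistic_reproduces_two_by_two_odds_ratio():
    # exposed: 20 events / 10 non-events; unexposed: 10 / 20
    x = np.repeat([1, 1, 0, 0], [20, 10, 10, 20])
    y = np.repeat([1, 0, 1, 0], [20, 10, 10, 20])
    X = np.column_stack([np.ones(60), x])
    fit = models.fit_logistic(X, y)
    assert np.isclose(fit.or_[1], 4.0, atol=1e-6)
    assert np.isclose(fit.coef[1], np.log(4.0), atol=1e-6)
    # symmetric table: OR exactly 1
    y2 = np.repeat([1, 0, 1, 0], [10, 10, 10, 10])
    x2 = np.repeat([1, 1, 0, 0], [10, 10, 10, 10])
    fit2 = models.fit_logistic(np.column_stack([np.ones(40), x2]), y2)
    assert np.isclose(fit2.or_[1], 1.0, atol=1e-8)
    assert np.isclose(fit2.coef[1], 0.0, atol=1e-8)


def test_logistic_se_matches_numerical_hessian_oracle(rng):
    X = np.column_stack([np.ones(300), rng.standard_normal((300, 2))])
    y = (rng.random(300) < 1.0 / (1.0 + np.exp(-(X @ [0.2, 0.7, -0.4])))).astype(int)
    fit = models.fit_logistic(X, y)

    def negll(b):
        eta = X @ b
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    H = np.zeros((3, 3))
    h = 1e-5
    for i in range(3):
        for j in range(3):
            bpp = fit.coef.copy(); bpp[i] += h; bpp[j] += h
            bpm = fit.coef.copy(); bpm[i] += h; bpm[j] -= h
            bmp = fit.coef.copy(); bmp[i] -= h; bmp[j] += h
            bmm = fit.coef.copy(); bmm[i] -= h; bmm[j] -= h
            H[i, j] = (negll(bpp) - negll(bpm) - negll(bmp) + negll(bmm)) / (4 * h * h)
    se_oracle = np.sqrt(np.diag(np.linalg.inv(H)))
    assert np.allclose(fit.se, se_oracle, rtol=1e-5)
    # CI ordering invariant
    assert np.all(fit.ci95[:, 0] < fit.or_)
    assert np.all(fit.or_ < fit.ci95[:, 1])


def test_logistic_detects_separation():
    x = np.concatenate([np.zeros(20), np.ones(20)])
    y = np.concatenate([np.zeros(20), np.ones(20)])
    X = np.column_stack([np.ones(40), x])
    with pytest.raises(models.SeparationError):
        models.fit_logistic(X, y)


def test_logistic_requires_both_classes():
    with pytest.raises(ValueError):
        models.fit_logistic(np.ones((10, 1)), np.ones(10))


def test_logistic_wald_ci_coverage(rng):
    """95% Wald CI for a logistic OR covers the truth within +-3 points of
    nominal over 1,000 replicates at n=500."""
    beta_true = 0.5
    covered = 0
    n_rep = 1000
    for _ in range(n_rep):
        x = rng.standard_normal(500)
        p = 1.0 / (1.0 + np.exp(-(-0.3 + beta_true * x)))
        y = (rng.random(500) < p).astype(int)
        fit = models.fit_logistic(np.column_stack([np.ones(500), x]), y)
        lo, hi = fit.ci95[1]
        if lo < np.exp(beta_true) < hi:
            covered += 1
    assert abs(covered / n_rep - 0.95) <= 0.03


# ---------------------------------------------------------------------------
# linear
# ---------------------------------------------------------------------------

def test_linear_exact_and_degenerate_r2(rng):
    x = rng.standard_normal(50)
    X = np.column_stack([np.ones(50), x])
    fit = models.fit_linear(X, 2.0 * x)
    assert np.isclose(fit.r2, 1.0, atol=1e-12)
    fit0 = models.fit_linear(X, np.full(50, 3.0))
    assert fit0.r2 == 0.0


def test_linear_matches_normal_equations_oracle(rng):
    X = np.column_stack([np.ones(80), rng.standard_normal((80, 3))])
    y = X @ [1.0, 0.5, -0.3, 0.2] + rng.standard_normal(80)
    fit = models.fit_linear(X, y)
    oracle = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.coef, oracle, rtol=1e-10)
    resid = y - X @ oracle
    r2_oracle = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
    assert np.isclose(fit.r2, r2_oracle, rtol=1e-12)


# ---------------------------------------------------------------------------
# pseudo-R2 and LR test
# ---------------------------------------------------------------------------

def test_pseudo_r2_closed_forms():
    z = models.pseudo_r2(-100.0, -100.0, 200)
    assert z.cox_snell == 0.0 and z.nagelkerke == 0.0 and z.mcfadden == 0.0
    perfect = models.pseudo_r2(-1e-12, -120.0, 200)
    assert np.isclose(perfect.nagelkerke, 1.0, atol=1e-9)
    # formula oracle
    r = models.pseudo_r2(-80.0, -100.0, 150)
    cs = 1 - np.exp(2 * (-100.0 + 80.0) / 150)
    assert np.isclose(r.cox_snell, cs, atol=1e-12)
    assert np.isclose(r.nagelkerke, cs / (1 - np.exp(2 * -100.0 / 150)), atol=1e-12)
    assert np.isclose(r.mcfadden, 1 - 80.0 / 100.0, atol=1e-12)
    assert r.nagelkerke >= r.cox_snell


def test_pseudo_r2_nondecreasing_along_nested_sequence(rng):
    """Adding predictors never decreases the log-likelihood, hence Cox-Snell
    and Nagelkerke are nondecreasing along a nested model sequence."""
    n = 300
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    p = 1.0 / (1.0 + np.exp(-(X @ [0.1, 0.6, -0.4, 0.0])))
    y = (rng.random(n) < p).astype(int)
    null = models.fit_logistic(X[:, :1], y)
    prev_ll = null.loglik
    prev = models.pseudo_r2(null.loglik, null.loglik, n)
    for k in range(2, 5):
        fit = models.fit_logistic(X[:, :k], y)
        assert fit.loglik >= prev_ll - 1e-8
        cur = models.pseudo_r2(fit.loglik, null.loglik, n)
        assert cur.cox_snell >= prev.cox_snell - 1e-10
        assert cur.nagelkerke >= prev.nagelkerke - 1e-10
        prev, prev_ll = cur, fit.loglik


def test_lr_test_basics():
    res = models.lr_test(-50.0, -50.0, 2)
    assert res.statistic == 0.0 and res.p == 1.0
    res2 = models.lr_test(-55.0, -50.0, 3)
    assert np.isclose(res2.statistic, 10.0)
    assert np.isclose(res2.p, stats.chi2.sf(10.0, 3), atol=1e-12)
    with pytest.raises(ValueError):
        models.lr_test(-50.0, -55.0, 1)
    with pytest.raises(ValueError):
        models.lr_test(-55.0, -50.0, 0)
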