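"""Maximum-likelihood fitting of the regression families behind the
symptom-perception accuracy measure.

Four model families are fitted from scratch by Newton-Raphson with
step-halving:

* baseline-category multinomial logit (the model whose per-person predicted
  probability of the observed outcome category is the accuracy score),
* cumulative-logit proportional-odds ordinal regression,
* binary logistic regression,
* ordinary least-squares linear regression.

The module also provides the likelihood-ratio machinery used downstream:
the test of parallel lines (proportional odds vs. multinomial), nested-model
LR tests, and the Cox-Snell / Nagelkerke / McFadden pseudo-R² family.

Sign conventions
----------------
Multinomial and logistic models use the usual ``logit P = x'b`` form.
The ordinal model uses ``logit P(Y <= k) = theta_k - x'beta`` so that a
positive slope moves probability mass toward higher outcome categories
(the convention of SPSS PLUM and MASS::polr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MultinomialFit",
    "OrdinalFit",
    "BinaryFit",
    "LinearFit",
    "TestResult",
    "PseudoR2",
    "ConvergenceError",
    "SeparationError",
    "fit_multinomial",
    "predict_category_probs",
    "fit_ordinal_po",
    "test_parallel_lines",
    "fit_logistic",
    "fit_linear",
    "pseudo_r2",
    "lr_test",
]

#: |loglik change| below which Newton iterations stop.
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100
#: ridge added to the information matrix before solving, for numerical safety
RIDGE = 1e-8
#: |coefficient| beyond which a logistic fit is declared separated
SEPARATION_BOUND = 15.0


class ConvergenceError(RuntimeError):
    """Raised when Newton iterations fail to converge.

    Carries the last iterate in ``last_params`` for diagnosis.
    """

    def __init__(self, message: str, last_params: np.ndarray | None = None):
        super().__init__(message)
        self.last_params = last_params


class SeparationError(RuntimeError):
    """Raised on complete/quasi separation in a logistic fit."""

    def __init__(self, message: str, predictor_index: int | None = None):
        super().__init__(message)
        self.predictor_index = predictor_index


@dataclass
class MultinomialFit:
    """Baseline-category multinomial logit fit.

    ``coef`` has one row per non-reference category (in the order of
    ``categories`` with the reference removed) and one column per design
    column.  ``cov`` is the inverse observed information over the
    vectorised (row-major) coefficients.
    """

    categories: np.ndarray
    ref_category: object
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_obs: int
    converged: bool

    @property
    def n_params(self) -> int:
        return int(self.coef.size)

    def to_dict(self) -> dict:
        return {
            "model": "multinomial_logit",
            "categories": np.asarray(self.categories).tolist(),
            "ref_category": self.ref_category,
            "coef": self.coef.tolist(),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }


@dataclass
class OrdinalFit:
    """Cumulative-logit proportional-odds fit, logit P(Y<=k) = theta_k - x'beta."""

    categories: np.ndarray
    thresholds: np.ndarray
    slopes: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    #: documented sign convention, for downstream reports
    convention: str = "logit P(Y<=k) = theta_k - x'beta"

    @property
    def n_params(self) -> int:
        return int(self.thresholds.size + self.slopes.size)

    def to_dict(self) -> dict:
        return {
            "model": "ordinal_proportional_odds",
            "categories": np.asarray(self.categories).tolist(),
            "thresholds": self.thresholds.tolist(),
            "slopes": self.slopes.tolist(),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "convention": self.convention,
        }


@dataclass
class BinaryFit:
    """Binary logistic fit with Wald standard errors and odds ratios."""

    coef: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci95: np.ndarray  # (p, 2): lower, upper on the OR scale
    loglik: float
    cov: np.ndarray
    n_obs: int
    converged: bool

    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        return {
            "model": "binary_logit",
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "or": self.or_.tolist(),
            "ci95": self.ci95.tolist(),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }


@dataclass
class LinearFit:
    """OLS fit with coefficient of determination."""

    coef: np.ndarray
    r2: float
    resid_var: float
    loglik: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "model": "linear",
            "coef": self.coef.tolist(),
            "r2": float(self.r2),
            "resid_var": float(self.resid_var),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
        }


@dataclass
class TestResult:
    """Chi-square test result (upper-tail p).

    ``flagged`` marks a degenerate comparison (see test_parallel_lines).
    """

    statistic: float
    df: int
    p: float
    flagged: bool = False

    def to_dict(self) -> dict:
        return {"statistic": float(self.statistic), "df": int(self.df),
                "p": float(self.p), "flagged": bool(self.flagged)}


@dataclass
class PseudoR2:
    """Likelihood-based explained-variance analogues for non-linear models."""

    cox_snell: float
    nagelkerke: float
    mcfadden: float

    def to_dict(self) -> dict:
        return {
            "cox_snell": float(self.cox_snell),
            "nagelkerke": float(self.nagelkerke),
            "mcfadden": float(self.mcfadden),
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D array")
    if len(y) != X.shape[0]:
        raise ValueError("design and outcome length mismatch")
    if X.shape[1] >= X.shape[0]:
        raise ValueError("more parameters than observations")
    return X, y


def _drop_missing(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Listwise deletion; returns the kept rows and the dropped count."""
    ok = np.isfinite(X).all(axis=1) & np.isfinite(np.asarray(y, dtype=float))
    return X[ok], y[ok], int((~ok).sum())


# ---------------------------------------------------------------------------
# multinomial logit
# ---------------------------------------------------------------------------

def _multinomial_probs(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Category probabilities, reference first.  B: (K-1, p)."""
    eta = X @ B.T  # (n, K-1)
    eta_full = np.column_stack([np.zeros(len(X)), eta])
    eta_full -= eta_full.max(axis=1, keepdims=True)
    e = np.exp(eta_full)
    return e / e.sum(axis=1, keepdims=True)


def _multinomial_loglik(Y_ind: np.ndarray, P: np.ndarray) -> float:
    return float(np.sum(Y_ind * np.log(np.clip(P, 1e-300, None))))


def fit_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    ref_category=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> MultinomialFit:
    """Fit a baseline-category multinomial logit by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) design matrix including an intercept column.
    y : outcome vector; every observed level is used as a category.
    ref_category : baseline level; defaults to the lowest observed level.

    The reference defaults to the lowest outcome level (for a symptom item,
    "not at all"), which is the natural baseline for a bothered/not-bothered
    reading of the scale.
    """
    X, y = _check_design(X, y)
    X, y, _ = _drop_missing(X, y)
    categories = np.unique(y)
    if len(categories) < 2:
        raise ValueError("outcome must have at least two observed levels")
    counts = np.array([(y == c).sum() for c in categories])
    if (counts == 0).any():
        raise ValueError("empty outcome category")
    if ref_category is None:
        ref_category = categories[0]
    if ref_category not in categories:
        raise ValueError(f"reference category {ref_category!r} not observed")
    others = [c for c in categories if c != ref_category]
    order = [ref_category] + others
    # indicator matrix in (ref, others) order
    Y_ind = np.column_stack([(y == c).astype(float) for c in order])
    n, p = X.shape
    K = len(order)

    B = np.zeros((K - 1, p))
    P = _multinomial_probs(X, B)
    ll = _multinomial_loglik(Y_ind, P)
    converged = False
    for _ in range(max_iter):
        resid = Y_ind[:, 1:] - P[:, 1:]  # (n, K-1)
        grad = (resid.T @ X).ravel()  # (K-1)*p
        Pm = P[:, 1:]
        # W_i = diag(p_i) - p_i p_i', stacked over i
        W = -np.einsum("ik,il->ikl", Pm, Pm)
        idx = np.arange(K - 1)
        W[:, idx, idx] += Pm
        info = np.einsum("ikl,ip,iq->kplq", W, X, X).reshape((K - 1) * p, (K - 1) * p)
        info[np.diag_indices_from(info)] += RIDGE
        step = np.linalg.solve(info, grad).reshape(K - 1, p)
        # step-halving on the log-likelihood
        scale = 1.0
        for _half in range(40):
            B_new = B + scale * step
            P_new = _multinomial_probs(X, B_new)
            ll_new = _multinomial_loglik(Y_ind, P_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("multinomial step-halving failed", B)
        delta = ll_new - ll
        B, P, ll = B_new, P_new, ll_new
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"multinomial fit did not converge in {max_iter} iterations", B
        )
    # observed information at the optimum
    Pm = P[:, 1:]
    W = -np.einsum("ik,il->ikl", Pm, Pm)
    idx = np.arange(K - 1)
    W[:, idx, idx] += Pm
    info = np.einsum("ikl,ip,iq->kplq", W, X, X).reshape((K - 1) * p, (K - 1) * p)
    info[np.diag_indices_from(info)] += RIDGE
    cov = np.linalg.inv(info)
    return MultinomialFit(
        categories=np.asarray(order),
        ref_category=ref_category,
        coef=B,
        cov=cov,
        loglik=ll,
        n_obs=n,
        converged=True,
    )


def predict_category_probs(fit: MultinomialFit, X: np.ndarray) -> np.ndarray:
    """Predicted category probabilities (columns in ``fit.categories`` order).

    Softmax inversion of the fitted linear predictors; each row sums to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != fit.coef.shape[1]:
        raise ValueError(
            f"design has {X.shape[1]} columns, fit expects {fit.coef.shape[1]}"
        )
    return _multinomial_probs(X, fit.coef)


# ---------------------------------------------------------------------------
# ordinal proportional odds
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _ordinal_ll_grad_hess(theta, beta, X, k_idx, K, want_hess=True):
    """Log-likelihood, gradient and Hessian of the PO model.

    Parameters are (theta_1..theta_{K-1}, beta); k_idx holds the 0-based
    outcome category per observation.
    """
    n, p = X.shape
    eta = X @ beta
    theta_ext = np.concatenate([[-np.inf], theta, [np.inf]])
    za = theta_ext[k_idx + 1] - eta  # upper cut
    zb = theta_ext[k_idx] - eta  # lower cut
    A = np.where(np.isinf(za), 1.0, _sigmoid(np.where(np.isinf(za), 0.0, za)))
    Bv = np.where(np.isinf(zb), 0.0, _sigmoid(np.where(np.isinf(zb), 0.0, zb)))
    D = A - Bv
    if np.any(D <= 0):
        return -np.inf, None, None
    ll = float(np.log(D).sum())
    a = np.where(np.isinf(za), 0.0, A * (1.0 - A))
    b = np.where(np.isinf(zb), 0.0, Bv * (1.0 - Bv))
    # gradient
    g_theta = np.zeros(K - 1)
    g_eta = -(a - b) / D
    has_upper = k_idx < K - 1
    has_lower = k_idx > 0
    np.add.at(g_theta, k_idx[has_upper], (a / D)[has_upper])
    np.add.at(g_theta, k_idx[has_lower] - 1, (-b / D)[has_lower])
    g_beta = X.T @ g_eta
    grad = np.concatenate([g_theta, g_beta])
    if not want_hess:
        return ll, grad, None
    # Hessian via d2 ll/du dv = D_uv/D - D_u D_v / D^2
    a2 = a * (1.0 - 2.0 * A)
    b2 = b * (1.0 - 2.0 * Bv)
    H = np.zeros((K - 1 + p, K - 1 + p))
    h_uu = a2 / D - (a / D) ** 2
    h_llw = -b2 / D - (b / D) ** 2
    h_ul = a * b / D**2
    h_ue = -a2 / D + a * (a - b) / D**2
    h_le = b2 / D - b * (a - b) / D**2
    h_ee = (a2 - b2) / D - ((a - b) / D) ** 2
    # theta-theta block
    np.add.at(H, (k_idx[has_upper], k_idx[has_upper]), h_uu[has_upper])
    np.add.at(H, (k_idx[has_lower] - 1, k_idx[has_lower] - 1), h_llw[has_lower])
    both = has_upper & has_lower
    np.add.at(H, (k_idx[both], k_idx[both] - 1), h_ul[both])
    np.add.at(H, (k_idx[both] - 1, k_idx[both]), h_ul[both])
    # theta-beta blocks
    for j in range(K - 1):
        up = has_upper & (k_idx == j)
        lo = has_lower & (k_idx - 1 == j)
        v = np.zeros(n)
        v[up] += h_ue[up]
        v[lo] += h_le[lo]
        row = X.T @ v
        H[j, K - 1 :] = row
        H[K - 1 :, j] = row
    # beta-beta block
    H[K - 1 :, K - 1 :] = X.T @ (X * h_ee[:, None])
    return ll, grad, H


def fit_ordinal_po(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> OrdinalFit:
    """Fit a cumulative-logit proportional-odds model by Newton-Raphson.

    An intercept (constant) column in the design is dropped automatically:
    its role is absorbed by the thresholds.  Iterates that break threshold
    monotonicity are rejected by step-halving, which re-parameterizes the
    search path without changing the optimum (the PO log-likelihood is
    concave in (theta, beta)).
    """
    X, y = _check_design(X, y)
    X, y, _ = _drop_missing(X, y)
    # drop constant columns (intercept absorbed into thresholds)
    keep = np.ptp(X, axis=0) > 0
    Xs = X[:, keep]
    categories = np.unique(y)
    K = len(categories)
    if K < 2:
        raise ValueError("outcome must have at least two observed levels")
    k_idx = np.searchsorted(categories, y)
    n, p = Xs.shape
    # start at marginal cumulative logits, beta = 0
    cum = np.cumsum(np.bincount(k_idx, minlength=K))[:-1] / n
    theta = np.log(cum / (1.0 - cum))
    beta = np.zeros(p)
    ll, grad, H = _ordinal_ll_grad_hess(theta, beta, Xs, k_idx, K)
    converged = False
    for _ in range(max_iter):
        info = -H
        info[np.diag_indices_from(info)] += RIDGE
        step = np.linalg.solve(info, grad)
        scale = 1.0
        for _half in range(40):
            theta_new = theta + scale * step[: K - 1]
            beta_new = beta + scale * step[K - 1 :]
            if np.all(np.diff(theta_new) > 0):
                ll_new, grad_new, H_new = _ordinal_ll_grad_hess(
                    theta_new, beta_new, Xs, k_idx, K
                )
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
            scale *= 0.5
        else:
            raise ConvergenceError(
                "ordinal step-halving failed", np.concatenate([theta, beta])
            )
        delta = ll_new - ll
        theta, beta, ll, grad, H = theta_new, beta_new, ll_new, grad_new, H_new
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"ordinal fit did not converge in {max_iter} iterations",
            np.concatenate([theta, beta]),
        )
    return OrdinalFit(
        categories=categories,
        thresholds=theta,
        slopes=np.asarray(beta),
        loglik=ll,
        converged=True,
        n_obs=n,
    )


def test_parallel_lines(ordinal: OrdinalFit, multinomial: MultinomialFit) -> TestResult:
    """Likelihood-ratio test of proportional odds against the multinomial.

    The multinomial relaxes the shared-slope constraint; the statistic is
    ``2 (ll_multinomial - ll_ordinal)`` on ``p_slope * (K - 2)`` degrees of
    freedom, with p_slope the number of (non-threshold) slopes.

    The baseline-category multinomial does not strictly nest the cumulative
    model, so at finite n its maximized likelihood can fall *below* the
    ordinal one even when both fits converged.  A negative difference is no
    evidence against proportionality: the statistic is then reported as 0
    (p = 1) with ``flagged=True``.
    """
    K = len(ordinal.categories)
    if len(multinomial.categories) != K:
        raise ValueError("fits have different outcome categories")
    stat = 2.0 * (multinomial.loglik - ordinal.loglik)
    flagged = stat < -1e-6
    stat = max(stat, 0.0)
    df = int(len(ordinal.slopes) * (K - 2))
    df = max(df, 1)
    return TestResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)),
                      flagged=flagged)


# ---------------------------------------------------------------------------
# binary logistic
# ---------------------------------------------------------------------------

def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> BinaryFit:
    """Fit a binary logistic model by Newton-Raphson with Wald inference."""
    X, y = _check_design(X, y)
    y = np.asarray(y, dtype=float)
    X, y, _ = _drop_missing(X, y)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all() or len(uniq) != 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    mu = _sigmoid(eta)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    converged = False
    for _ in range(max_iter):
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        info[np.diag_indices_from(info)] += RIDGE
        step = np.linalg.solve(info, grad)
        scale = 1.0
        for _half in range(40):
            beta_new = beta + scale * step
            mu_new = _sigmoid(X @ beta_new)
            mu_new = np.clip(mu_new, 1e-12, 1 - 1e-12)
            ll_new = float(np.sum(y * np.log(mu_new) + (1 - y) * np.log1p(-mu_new)))
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("logistic step-halving failed", beta)
        delta = ll_new - ll
        beta, mu, ll = beta_new, mu_new, ll_new
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations", beta
        )
    if np.any(np.abs(beta) > SEPARATION_BOUND):
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"complete or quasi separation detected on predictor column {j} "
            f"(|coef| = {abs(beta[j]):.1f})",
            predictor_index=j,
        )
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    info[np.diag_indices_from(info)] += RIDGE
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    or_ = np.exp(beta)
    z = stats.norm.ppf(0.975)
    ci95 = np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)])
    return BinaryFit(
        coef=beta,
        se=se,
        or_=or_,
        ci95=ci95,
        loglik=ll,
        cov=cov,
        n_obs=n,
        converged=True,
    )


# ---------------------------------------------------------------------------
# linear
# ---------------------------------------------------------------------------

def fit_linear(X: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares with R² = 1 - SSR/SST.

    A constant outcome yields R² = 0 by the degenerate-input rule.
    """
    X, y = _check_design(X, y)
    y = np.asarray(y, dtype=float)
    X, y, _ = _drop_missing(X, y)
    n, p = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        r2 = 0.0
    else:
        r2 = 1.0 - ssr / sst
    resid_var = ssr / max(n - p, 1)
    # gaussian log-likelihood at the MLE variance (for LR bookkeeping)
    sigma2 = max(ssr / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return LinearFit(coef=coef, r2=float(r2), resid_var=float(resid_var), loglik=float(ll), n_obs=n)


# ---------------------------------------------------------------------------
# pseudo-R² and LR tests
# ---------------------------------------------------------------------------

def pseudo_r2(fit_loglik: float, null_loglik: float, n: int) -> PseudoR2:
    """Cox-Snell, Nagelkerke and McFadden pseudo-R² from two log-likelihoods.

    Nagelkerke rescales Cox-Snell by its attainable maximum and is the
    conventional normalized headline figure; all three are emitted.
    """
    if fit_loglik < null_loglik - 1e-8:
        raise ValueError("fitted log-likelihood below null log-likelihood")
    if null_loglik >= 0.0:
        raise ValueError("degenerate null log-likelihood (must be < 0)")
    fit_loglik = max(fit_loglik, null_loglik)
    cs = 1.0 - np.exp(2.0 * (null_loglik - fit_loglik) / n)
    cs_max = 1.0 - np.exp(2.0 * null_loglik / n)
    nk = cs / cs_max
    mf = 1.0 - fit_loglik / null_loglik
    return PseudoR2(cox_snell=float(cs), nagelkerke=float(nk), mcfadden=float(mf))


def lr_test(nested_loglik: float, full_loglik: float, df_diff: int) -> TestResult:
    """Likelihood-ratio chi-square test for nested models."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    stat = 2.0 * (full_loglik - nested_loglik)
    if stat < -1e-6:
        raise ValueError("full model log-likelihood below nested model")
    stat = max(stat, 0.0)
    return TestResult(statistic=stat, df=int(df_diff), p=float(stats.chi2.sf(stat, df_diff)))
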