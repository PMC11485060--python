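"""Maximum-likelihood logistic fits for the combined-exposure-level model.

The model places the four combined levels of two binary factors into a
logistic regression with the unexposed cell as reference,

    logit p = theta0 + theta1*I(a_only) + theta2*I(b_only) + theta3*I(both) + z @ gamma,

and supports three fits:

* the unconstrained MLE (model M1, saturated when no confounders),
* a closed-form shortcut for the confounder-free saturated case, and
* the MLE under the additive-null constraint
  ``exp(theta3) - exp(theta1) - exp(theta2) + 1 = 0`` (model M2), obtained by
  the exact reparameterization ``theta3 = log(exp(theta1) + exp(theta2) - 1)``.

Log-likelihoods are Bernoulli (per subject), so the global deviance
``GDEV = -2 l(theta_hat)`` is comparable across all three fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from statsmodels.tools import numdiff

from .data import (CorrectedCountTable, CountTable, DegenerateDataError,
                   ExposureDataset, ZeroCellError)

GRAD_TOL = 1e-8
MAX_ITER = 200
CONSTRAINT_TOL = 1e-8


def _converged(res, scale: float = 1.0) -> bool:
    """BFGS can stop with a 'precision loss' status after the gradient is
    already far below any statistically meaningful level; judge convergence
    by the achieved gradient norm rather than the status flag alone."""
    gnorm = float(np.max(np.abs(np.atleast_1d(res.jac))))
    return bool(res.success) or gnorm < 1e-5 * max(1.0, scale)


class InfeasibleConstraintError(RuntimeError):
    """The additive-null manifold has no interior optimum for the data.

    The constrained parameterization requires exp(theta1) + exp(theta2) > 1;
    when the optimizer is pushed onto that boundary the constrained model is
    not estimable (both single-exposure odds ratios point strongly below 1).
    """


class ConvergenceError(RuntimeError):
    """The optimizer failed to meet the gradient tolerance."""


@dataclass
class FittedModel:
    """A fitted combined-level logistic model.

    Attributes
    ----------
    theta0 : intercept (log-odds of the outcome at the reference level).
    theta : array (theta1, theta2, theta3) for a_only, b_only, both.
    gamma : confounder coefficients (length p, possibly empty).
    covariance : (4+p) x (4+p) covariance of (theta0, theta1..3, gamma).
    loglik : maximized Bernoulli log-likelihood.
    df : number of free parameters (4+p unconstrained, 3+p constrained).
    constrained : True when fitted on the additive-null manifold.
    """

    theta0: float
    theta: np.ndarray
    gamma: np.ndarray
    covariance: np.ndarray
    loglik: float
    df: int
    constrained: bool
    converged: bool
    n: int
    message: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate(([self.theta0], self.theta, self.gamma))

    @property
    def theta_cov(self) -> np.ndarray:
        """3x3 covariance of (theta1, theta2, theta3)."""
        return self.covariance[1:4, 1:4]

    @property
    def gdev(self) -> float:
        """Global deviance, -2 * maximized log-likelihood."""
        return -2.0 * self.loglik

    @property
    def interaction_contrast(self) -> float:
        t1, t2, t3 = self.theta
        return float(np.exp(t3) - np.exp(t1) - np.exp(t2) + 1.0)


# ---------------------------------------------------------------------------
# likelihood kernels (count-table representation, Bernoulli log-likelihood)

def _counts_loglik(eta: np.ndarray, cases: np.ndarray,
                   controls: np.ndarray) -> float:
    # sum_j a_j * eta_j - (a_j + b_j) * log(1 + exp(eta_j))
    return float(np.dot(cases, eta)
                 - np.dot(cases + controls, np.logaddexp(0.0, eta)))


def _eta_from_theta(theta4: np.ndarray) -> np.ndarray:
    t0, t1, t2, t3 = theta4
    return np.array([t0, t0 + t1, t0 + t2, t0 + t3])


def _counts_negll_grad(theta4, cases, controls):
    eta = _eta_from_theta(theta4)
    p = 1.0 / (1.0 + np.exp(-eta))
    total = cases + controls
    resid = cases - total * p            # d l / d eta_j
    grad = -np.array([resid.sum(), resid[1], resid[2], resid[3]])
    return -_counts_loglik(eta, cases, controls), grad


def _counts_information(theta4, cases, controls):
    """Observed (= expected, canonical link) information for the 4 cells."""
    eta = _eta_from_theta(theta4)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = (cases + controls) * p * (1.0 - p)
    H = np.zeros((4, 4))
    H[0, 0] = w.sum()
    for j in (1, 2, 3):
        H[0, j] = H[j, 0] = w[j]
        H[j, j] = w[j]
    return H


def _individual_negll_grad(params, X, y):
    eta = X @ params
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())
    grad = -X.T @ (y - p)
    return -ll, grad


def _as_counts(data):
    if isinstance(data, (CountTable, CorrectedCountTable)):
        return data
    if isinstance(data, ExposureDataset) and data.confounders is None:
        return data.to_counts()
    return None


# ---------------------------------------------------------------------------
# unconstrained fit

def saturated_from_counts(table) -> FittedModel:
    """Closed-form saturated MLE for a confounder-free count table.

    The saturated MLE equals the observed cell log-odds, so each
    coefficient is a log cross-product ratio against the reference cell and
    the covariance is a sum of reciprocal cell counts:

    * ``theta_j = log(cases_j/controls_j) - log(cases_0/controls_0)``
    * ``Var(theta_j) = 1/cases_j + 1/controls_j + 1/cases_0 + 1/controls_0``
    * ``Cov(theta_i, theta_j) = 1/cases_0 + 1/controls_0`` for i != j.

    Raises :class:`ZeroCellError` if any of the 8 cells is empty; callers
    decide whether to apply :meth:`CountTable.corrected`.
    """
    zero = table.zero_cells()
    if zero:
        raise ZeroCellError(zero)
    a, b = table.as_arrays()
    logodds = np.log(a) - np.log(b)
    theta0 = logodds[0]
    theta = logodds[1:] - theta0

    v = 1.0 / a + 1.0 / b                     # variance of each cell log-odds
    cov = np.zeros((4, 4))
    cov[0, 0] = v[0]
    cov[0, 1:] = cov[1:, 0] = -v[0]
    cov[1:, 1:] = v[0] + np.diag(v[1:])

    eta = _eta_from_theta(np.concatenate(([theta0], theta)))
    ll = _counts_loglik(eta, a, b)
    return FittedModel(theta0=float(theta0), theta=theta, gamma=np.zeros(0),
                       covariance=cov, loglik=ll, df=4, constrained=False,
                       converged=True, n=int(round(a.sum() + b.sum())))


def fit_unconstrained(data) -> FittedModel:
    """Unconstrained MLE of the combined-level logistic model (model M1).

    Confounder-free data is reduced to the 2x4 table and maximized by
    quasi-Newton iteration on the 4 cell parameters; with confounders the
    full individual-level likelihood is maximized. The covariance is the
    inverse observed information.
    """
    table = _as_counts(data)
    if table is not None:
        return _fit_unconstrained_counts(table)
    return _fit_unconstrained_individual(data)


def _check_degenerate(cases, controls):
    if cases.sum() == 0 or controls.sum() == 0:
        raise DegenerateDataError("all outcomes identical; the intercept is "
                                  "not estimable")


def _fit_unconstrained_counts(table) -> FittedModel:
    cases, controls = table.as_arrays()
    _check_degenerate(cases, controls)
    zero = table.zero_cells()
    if zero:
        raise ZeroCellError(zero)

    x0 = np.zeros(4)
    res = optimize.minimize(_counts_negll_grad, x0, args=(cases, controls),
                            jac=True, method="BFGS",
                            options={"gtol": GRAD_TOL, "maxiter": MAX_ITER})
    H = _counts_information(res.x, cases, controls)
    cov = np.linalg.inv(H)
    return FittedModel(theta0=float(res.x[0]), theta=res.x[1:].copy(),
                       gamma=np.zeros(0), covariance=cov,
                       loglik=-float(res.fun), df=4, constrained=False,
                       converged=_converged(res), n=table.n,
                       message=res.message)


def _fit_unconstrained_individual(data: ExposureDataset) -> FittedModel:
    y = data.outcome.astype(float)
    if y.min() == y.max():
        raise DegenerateDataError("all outcomes identical")
    X = data.design_matrix()
    k = X.shape[1]
    res = optimize.minimize(_individual_negll_grad, np.zeros(k), args=(X, y),
                            jac=True, method="BFGS",
                            options={"gtol": GRAD_TOL, "maxiter": MAX_ITER})
    p = 1.0 / (1.0 + np.exp(-(X @ res.x)))
    H = X.T @ (X * (p * (1 - p))[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular information matrix: {exc}") from exc
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        raise ConvergenceError(f"unconstrained fit did not converge: "
                               f"{res.message}")
    return FittedModel(theta0=float(res.x[0]), theta=res.x[1:4].copy(),
                       gamma=res.x[4:].copy(), covariance=cov,
                       loglik=-float(res.fun), df=k, constrained=False,
                       converged=True, n=data.n, message=res.message)


# ---------------------------------------------------------------------------
# constrained fit (additive null: exp(t3) = exp(t1) + exp(t2) - 1)

_BARRIER = 1e10


def _theta3_of(t1, t2):
    u = np.exp(t1) + np.exp(t2) - 1.0
    return (np.log(u), u) if u > 0 else (None, u)


def _constrained_negll_grad_counts(phi, cases, controls):
    """Reduced objective in (t0, t1, t2); valid in the interior only.

    Used for the covariance (numerical Hessian) after the optimum has been
    located in the boundary-free (t0, r, t3) coordinates.
    """
    t0, t1, t2 = phi
    t3, u = _theta3_of(t1, t2)
    if t3 is None or u < 1e-12:
        return _BARRIER * (1.0 + (1e-12 - u)), np.array([0.0, -_BARRIER,
                                                         -_BARRIER])
    eta = np.array([t0, t0 + t1, t0 + t2, t0 + t3])
    p = 1.0 / (1.0 + np.exp(-eta))
    total = cases + controls
    resid = cases - total * p
    nll = -_counts_loglik(eta, cases, controls)
    # chain rule: d theta3/d theta1 = e^t1/u, d theta3/d theta2 = e^t2/u
    g0 = -resid.sum()
    g1 = -(resid[1] + resid[3] * np.exp(t1) / u)
    g2 = -(resid[2] + resid[3] * np.exp(t2) / u)
    return nll, np.array([g0, g1, g2])


def _constrained_negll_individual(phi, X, y):
    t3, u = _theta3_of(phi[1], phi[2])
    if t3 is None or u < 1e-12:
        return _BARRIER * (1.0 + (1e-12 - u))
    full = np.concatenate((phi[:3], [t3], phi[3:]))
    nll, _ = _individual_negll_grad(full, X, y)
    return nll


# The additive-null manifold {e^t3 = e^t1 + e^t2 - 1} is covered exactly by
# the unconstrained coordinates psi = (t0, r, t3) with r = t1 - t2:
#     e^t1 + e^t2 = 1 + e^t3,  e^t1 / e^t2 = e^r.
# Every psi in R^3 maps to a feasible theta, so the optimizer never meets a
# boundary; an infeasible dataset reveals itself as t3 -> -infinity.

def _theta_from_psi(psi):
    t0, r, t3 = psi[0], psi[1], psi[2]
    log_s = np.logaddexp(0.0, t3)             # log(1 + e^t3)
    log_denom = np.logaddexp(0.0, r)          # log(1 + e^r)
    t1 = log_s + r - log_denom
    t2 = log_s - log_denom
    return np.array([t0, t1, t2, t3])


def _constrained_negll_grad_psi(psi, cases, controls):
    theta4 = _theta_from_psi(psi)
    nll, g = _counts_negll_grad(theta4, cases, controls)   # d/d(t0..t3)
    sig3 = 1.0 / (1.0 + np.exp(-psi[2]))      # d log(1+e^t3) / d t3
    sig_r = 1.0 / (1.0 + np.exp(-psi[1]))     # e^r / (1 + e^r)
    g_r = g[1] * (1.0 - sig_r) - g[2] * sig_r
    g_t3 = (g[1] + g[2]) * sig3 + g[3]
    return nll, np.array([g[0], g_r, g_t3])


def _constrained_negll_psi_individual(psi_gamma, X, y):
    theta4 = _theta_from_psi(psi_gamma[:3])
    full = np.concatenate((theta4, psi_gamma[3:]))
    nll, _ = _individual_negll_grad(full, X, y)
    return nll


def _reduced_jacobian(t1, t2, p_conf):
    """d(theta0, theta1..3, gamma)/d(theta0, theta1, theta2, gamma)."""
    u = np.exp(t1) + np.exp(t2) - 1.0
    k_red = 3 + p_conf
    J = np.zeros((4 + p_conf, k_red))
    J[0, 0] = J[1, 1] = J[2, 2] = 1.0
    J[3, 1] = np.exp(t1) / u
    J[3, 2] = np.exp(t2) / u
    for j in range(p_conf):
        J[4 + j, 3 + j] = 1.0
    return J


def fit_constrained(data) -> FittedModel:
    """MLE under the additive-null constraint (model M2).

    The equality constraint is removed exactly by optimizing over
    (theta0, theta1, theta2) with ``theta3 = log(e^t1 + e^t2 - 1)``; the
    delta method maps the reduced covariance back to the full parameter
    vector, so the reported covariance of theta3 reflects the constraint.
    """
    table = _as_counts(data)
    if table is not None:
        cases, controls = table.as_arrays()
        _check_degenerate(cases, controls)
        start = _constrained_start_psi(table, None)
        res = optimize.minimize(_constrained_negll_grad_psi, start,
                                args=(cases, controls), jac=True,
                                method="BFGS",
                                options={"gtol": GRAD_TOL,
                                         "maxiter": MAX_ITER})
        theta4 = _theta_from_psi(res.x)
        if res.x[2] < -15.0:            # e^t3 -> 0: boundary of the manifold
            raise InfeasibleConstraintError(
                "optimizer pushed exp(theta1)+exp(theta2) -> 1 (theta3 -> "
                "-inf); the additive-null model is not estimable for these "
                "data")
        phi = theta4[:3]
        hess = numdiff.approx_hess(
            phi, lambda q: _constrained_negll_grad_counts(q, cases,
                                                          controls)[0])
        n = table.n
        p_conf = 0
        nll = res.fun
        success = _converged(res)
        msg = res.message
    else:
        y = data.outcome.astype(float)
        if y.min() == y.max():
            raise DegenerateDataError("all outcomes identical")
        X = data.design_matrix()
        p_conf = X.shape[1] - 4
        start = np.concatenate((_constrained_start_psi(None, data),
                                np.zeros(p_conf)))
        res = optimize.minimize(_constrained_negll_psi_individual, start,
                                args=(X, y), method="BFGS",
                                options={"gtol": GRAD_TOL,
                                         "maxiter": MAX_ITER})
        theta4 = _theta_from_psi(res.x[:3])
        if res.x[2] < -15.0:
            raise InfeasibleConstraintError(
                "optimizer pushed exp(theta1)+exp(theta2) -> 1; the "
                "additive-null model is not estimable for these data")
        phi = np.concatenate((theta4[:3], res.x[3:]))
        hess = numdiff.approx_hess(
            phi, lambda q: _constrained_negll_individual(q, X, y))
        n = data.n
        nll = res.fun
        success = _converged(res)
        msg = res.message

    cov_red = np.linalg.inv(hess)
    J = _reduced_jacobian(theta4[1], theta4[2], p_conf)
    cov = J @ cov_red @ J.T
    cov = 0.5 * (cov + cov.T)
    theta = theta4[1:].copy()
    model = FittedModel(theta0=float(theta4[0]), theta=theta,
                        gamma=np.asarray(phi[3:], dtype=float).copy(),
                        covariance=cov, loglik=-float(nll), df=3 + p_conf,
                        constrained=True, converged=success, n=n,
                        message=msg)
    if not success:
        model.diagnostics["warning"] = f"constrained fit: {msg}"
    return model


def _constrained_start_psi(table, data):
    """Starting point in (t0, r, t3) near the unconstrained optimum."""
    try:
        if table is not None:
            m = saturated_from_counts(table)
        else:
            m = _fit_unconstrained_individual(data)
        t1, t2 = m.theta[0], m.theta[1]
        u = np.exp(t1) + np.exp(t2) - 1.0
        t3 = np.log(u) if u > 1e-3 else np.log(1e-3)
        return np.array([m.theta0, t1 - t2, t3])
    except (ZeroCellError, DegenerateDataError):
        return np.array([0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# deviance

def deviance(model: FittedModel, data) -> float:
    """Bernoulli deviance ``-2 l(data; theta_hat)`` of ``data`` at the
    model's estimates.

    On the training data this equals ``-2 * model.loglik``; with held-out
    data it is the generalization error used for tuning-parameter selection.
    """
    table = _as_counts(data)
    if table is not None:
        if model.gamma.size:
            raise ValueError("model has confounder coefficients but data has "
                             "no confounders")
        cases, controls = table.as_arrays()
        eta = _eta_from_theta(np.concatenate(([model.theta0], model.theta)))
        return -2.0 * _counts_loglik(eta, cases, controls)
    if model.gamma.size != data.n_confounders:
        raise ValueError("confounder dimension mismatch between model and "
                         "data")
    X = data.design_matrix()
    y = data.outcome.astype(float)
    nll, _ = _individual_negll_grad(model.params, X, y)
    return 2.0 * nll
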