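"""Dirichlet regression for three-part compositional responses.

The mean/precision parametrization is used throughout: a composition
``Y = (Y1, Y2, Y3)`` is Dirichlet with concentration ``alpha_c = phi * mu_c``
where the means follow a multinomial-logit link against covariates,

    mu_1 = exp(X b1) / D,  mu_2 = exp(X b2) / D,  mu_3 = 1 / D,
    D = exp(X b1) + exp(X b2) + 1,

so the third component (here *Enterobacter*) acts as the reference category:
``mu_1 / mu_3 = exp(X b1)`` and ``mu_2 / mu_3 = exp(X b2)``.  The precision
``phi > 0`` shrinks all variances, ``Var(Y_c) = mu_c (1 - mu_c) / (phi + 1)``,
and forces negative cross-covariances ``-mu_c mu_d / (phi + 1)``.

Maximum likelihood runs over ``(b1, b2, log phi)`` with internally
standardized covariate columns for conditioning (estimates are reported in
user units); Wald z statistics and p-values come from the inverse observed
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

class BoundaryError(ValueError):
    """Raised when a composition sits on the simplex boundary."""


def _check_compositions(y: np.ndarray, strict: bool = True) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] != 3:
        raise ValueError("compositions must have three components")
    if np.any(np.abs(y.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("compositions must sum to 1")
    # the log-density is computable for any representable interior value, so
    # only exact zeros/ones count as boundary
    if strict and np.any((y <= 0.0) | (y >= 1.0)):
        raise BoundaryError(
            "composition on the simplex boundary; apply compress_proportions first"
        )
    return y


def predict_means(X_row, beta1, beta2) -> np.ndarray:
    """Mean triple(s) from the multinomial-logit link (reference = 3rd part).

    Accepts a single covariate row (with intercept entry) or a matrix;
    computed via max-subtraction so it never overflows.  Rows sum to 1
    exactly.
    """
    X = np.atleast_2d(np.asarray(X_row, dtype=float))
    eta = np.column_stack([X @ np.asarray(beta1, float), X @ np.asarray(beta2, float), np.zeros(len(X))])
    eta -= eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    mu = w / w.sum(axis=1, keepdims=True)
    return mu[0] if np.asarray(X_row).ndim == 1 else mu


def moments(mu, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Variances and pairwise covariances ((1,2), (1,3), (2,3)) of Y | mu, phi."""
    mu = np.asarray(mu, dtype=float)
    var = mu * (1 - mu) / (phi + 1.0)
    cov = np.array([
        -mu[0] * mu[1] / (phi + 1.0),
        -mu[0] * mu[2] / (phi + 1.0),
        -mu[1] * mu[2] / (phi + 1.0),
    ])
    return var, cov


def covariance_matrix(mu, phi: float) -> np.ndarray:
    """Full 3x3 covariance matrix (rows sum to zero)."""
    var, cov = moments(mu, phi)
    m = np.diag(var)
    m[0, 1] = m[1, 0] = cov[0]
    m[0, 2] = m[2, 0] = cov[1]
    m[1, 2] = m[2, 1] = cov[2]
    return m


def dirichlet_loglik(compositions, X, beta1, beta2, log_phi: float) -> float:
    """Log-likelihood of the mean/precision Dirichlet regression model."""
    y = _check_compositions(compositions)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = predict_means(X, beta1, beta2)
    phi = float(np.exp(log_phi))
    alpha = phi * mu
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(alpha).sum(axis=1)
            + ((alpha - 1.0) * np.log(y)).sum(axis=1)
        )
    )


@dataclass
class DirichletFit:
    """Fitted Dirichlet regression: two coefficient blocks plus precision.

    ``beta1``/``beta2`` are in user covariate units (intercept first);
    ``covariance`` spans the packed parameter vector (beta1, beta2,
    log_phi).  ``summary()`` renders the conventional regression table:
    estimate, standard error, Wald z and two-sided p per term, plus a
    precision row (phi with a delta-method standard error).
    """

    beta1: np.ndarray
    beta2: np.ndarray
    log_phi: float
    covariance: np.ndarray
    loglik: float
    converged: bool
    term_names: list[str]
    component_names: tuple[str, str, str] = ("Escherichia", "Klebsiella", "Enterobacter")

    @property
    def phi(self) -> float:
        return float(np.exp(self.log_phi))

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta1, self.beta2, [self.log_phi]])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def phi_se(self) -> float:
        # delta method through phi = exp(log_phi)
        return float(self.phi * self.se[-1])

    @property
    def z(self) -> np.ndarray:
        se = self.se
        z = np.full_like(se, np.nan)
        np.divide(self.params, se, out=z, where=se > 0)
        return z

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def predict(self, X) -> np.ndarray:
        return predict_means(X, self.beta1, self.beta2)

    def summary(self) -> pd.DataFrame:
        p = len(self.beta1)
        rows = []
        est = self.params
        se = self.se
        z = self.z
        pv = self.pvalues
        for block, offset in ((self.component_names[0], 0), (self.component_names[1], p)):
            for i, term in enumerate(self.term_names):
                j = offset + i
                rows.append((block, term, est[j], se[j], z[j], pv[j]))
        phi_z = self.phi / self.phi_se if self.phi_se > 0 else np.nan
        rows.append(
            ("Precision", "phi", self.phi, self.phi_se, phi_z, 2.0 * stats.norm.sf(abs(phi_z)))
        )
        return pd.DataFrame(rows, columns=["block", "term", "estimate", "std_error", "z", "p_value"])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale non-intercept columns; returns (Xs, means, scales)."""
    X = np.array(X, dtype=float, copy=True)
    means = np.zeros(X.shape[1])
    scales = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue  # intercept or constant column left alone
        means[j] = col.mean()
        scales[j] = col.std(ddof=0)
        X[:, j] = (col - means[j]) / scales[j]
    return X, means, scales


def _destandardize_jacobian(means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Linear map A with beta_user = A @ beta_std for one coefficient block.

    With x_std = (x - m)/s the linear predictors match when
    b_user_j = b_std_j / s_j (j >= 1) and
    b_user_0 = b_std_0 - sum_j b_std_j m_j / s_j.
    """
    p = len(means)
    A = np.zeros((p, p))
    A[0, 0] = 1.0
    for j in range(1, p):
        A[j, j] = 1.0 / scales[j]
        A[0, j] = -means[j] / scales[j]
    return A


def fit_dirichlet(
    compositions,
    X,
    term_names: Optional[Sequence[str]] = None,
    component_names: tuple[str, str, str] = ("Escherichia", "Klebsiella", "Enterobacter"),
    gtol: float = 1e-8,
    auto_compress: bool = True,
) -> DirichletFit:
    """Maximum-likelihood Dirichlet regression of compositions on X.

    ``X`` must include the intercept column.  Boundary observations are
    compressed toward the barycenter automatically (with a logged notice)
    when ``auto_compress`` is set.  Raises on rank-deficient X.
    """
    y = np.atleast_2d(np.asarray(compositions, dtype=float))
    if np.any((y <= 0.0) | (y >= 1.0)):
        if not auto_compress:
            raise BoundaryError("boundary compositions present")
        logger.info("boundary compositions present; applying compress_proportions")
        y = compress_proportions(y)
    y = _check_compositions(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n != len(y):
        raise ValueError("compositions and X must have equal length")
    if n <= 2 * p + 1:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, r = np.linalg.qr(X)
        bad = [j for j in range(p) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient (suspect columns {bad})")
    if term_names is None:
        term_names = ["intercept"] + [f"x{j}" for j in range(1, p)]

    Xs, means, scales = _standardize(X)

    # init: OLS of the log-ratio transforms, phi by moment matching
    lr1 = np.log(y[:, 0] / y[:, 2])
    lr2 = np.log(y[:, 1] / y[:, 2])
    b1_0, *_ = np.linalg.lstsq(Xs, lr1, rcond=None)
    b2_0, *_ = np.linalg.lstsq(Xs, lr2, rcond=None)
    mu0 = predict_means(Xs, b1_0, b2_0)
    resid_var = np.mean((y - mu0) ** 2, axis=0)
    mom = np.mean(mu0 * (1 - mu0), axis=0) / np.clip(resid_var, 1e-12, None) - 1.0
    phi0 = float(np.clip(np.mean(mom), 0.1, 1e6))
    theta0 = np.concatenate([b1_0, b2_0, [np.log(phi0)]])

    def nll(theta):
        b1, b2, lp = theta[:p], theta[p : 2 * p], theta[-1]
        try:
            return -dirichlet_loglik(y, Xs, b1, b2, lp)
        except FloatingPointError:
            return np.inf

    def grad(theta):
        b1, b2, lp = theta[:p], theta[p : 2 * p], theta[-1]
        phi = np.exp(lp)
        mu = predict_means(Xs, b1, b2)
        alpha = phi * mu
        # d loglik / d alpha_c = -digamma(alpha_c) + log y_c
        dl_dalpha = -special.digamma(alpha) + np.log(y)
        # mu_c = softmax link; d mu_c / d eta_k = mu_c (delta_ck - mu_k), k in {1,2}
        g = np.empty_like(theta)
        for k in range(2):
            dmu = mu * (-mu[:, [k]])
            dmu[:, k] += mu[:, k]
            deta = phi * np.sum(dl_dalpha * dmu, axis=1)
            g[k * p : (k + 1) * p] = Xs.T @ deta
        dl_dphi = special.digamma(phi) + np.sum(dl_dalpha * mu, axis=1)
        g[-1] = phi * np.sum(dl_dphi)
        return -g

    res = optimize.minimize(nll, theta0, jac=grad, method="BFGS",
                            options={"gtol": gtol, "maxiter": 1000})
    theta = res.x
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-4)
    if not converged:
        logger.warning("Dirichlet fit did not fully converge: %s", res.message)

    H = _hessian_fd(nll, theta)
    try:
        cov_std = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_std = np.full((len(theta), len(theta)), np.nan)
        converged = False

    # back-transform to user units: block-diagonal linear map
    A = np.zeros((2 * p + 1, 2 * p + 1))
    Ablock = _destandardize_jacobian(means, scales)
    A[:p, :p] = Ablock
    A[p : 2 * p, p : 2 * p] = Ablock
    A[-1, -1] = 1.0
    theta_user = A @ theta
    cov_user = A @ cov_std @ A.T

    return DirichletFit(
        beta1=theta_user[:p],
        beta2=theta_user[p : 2 * p],
        log_phi=float(theta_user[-1]),
        covariance=cov_user,
        loglik=float(-res.fun),
        converged=converged,
        term_names=list(term_names),
        component_names=component_names,
    )


def _hessian_fd(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def simulate_dirichlet(X, beta1, beta2, phi: float, seed: int) -> np.ndarray:
    """i.i.d. Dirichlet draws with concentration ``phi * mu(X_i)`` per row."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = predict_means(X, beta1, beta2)
    alpha = phi * mu
    rng = np.random.default_rng(seed)
    # log-space gamma draw via G_a = G_{a+1} * U^{1/a} (exact for any a > 0);
    # keeps small-concentration draws strictly positive where a plain gamma
    # sample would underflow to an exact zero
    g1 = rng.gamma(shape=alpha + 1.0)
    u = rng.random(alpha.shape)
    log_g = np.log(g1) + np.log(u) / alpha
    log_g -= special.logsumexp(log_g, axis=1, keepdims=True)
    y = np.exp(np.maximum(log_g, -700.0))
    return y / y.sum(axis=1, keepdims=True)


def compress_proportions(compositions, n: Optional[int] = None) -> np.ndarray:
    """Shrink proportions toward the barycenter: y' = (y (n-1) + 1/3) / n.

    ``n`` defaults to the number of observations.  Output is strictly
    interior and still sums to one row-wise.
    """
    y = np.atleast_2d(np.asarray(compositions, dtype=float))
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if n is None:
        n = len(y)
    n = max(int(n), 2)
    return (y * (n - 1) + 1.0 / 3.0) / n


_TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def ternary_coordinates(composition) -> np.ndarray:
    """Equilateral-triangle embedding of simplex points.

    Vertices: component 1 -> (0,0), component 2 -> (1,0), component 3 ->
    (1/2, sqrt(3)/2); the barycenter (1/3,1/3,1/3) maps to the centroid.
    """
    y = np.atleast_2d(np.asarray(composition, dtype=float))
    if np.any(np.abs(y.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("compositions must sum to 1")
    pts = y @ _TRIANGLE
    return pts[0] if np.asarray(composition).ndim == 1 else pts
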