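"""Count-regression models for per-OTU differential abundance testing.

Four models share a log-linear count part with a library-size offset,
``mu_i = N_i * exp(x_i' beta)``:

* ``P``    — Poisson.
* ``NB``   — negative binomial (NB2): a Poisson-gamma mixture where
  ``exp(e_i) ~ Gamma(1/phi, 1/phi)`` multiplies the rate, giving
  ``Var(Y) = mu + phi * mu^2``.
* ``ZIP``  — zero-inflated Poisson: a point mass at zero with probability
  ``pi_i = logistic(z_i' gamma)`` mixed with the Poisson.
* ``ZINB`` — zero-inflated negative binomial, combining both, with
  ``E[Y_i | x_i, z_i] = (1 - pi_i) * mu_i``.

Fitting is direct likelihood maximization on an unconstrained
parametrization (``phi`` on the log scale, zero inflation through the logit
of ``gamma``), with standard errors from the inverse of the numerically
evaluated observed information at the optimum.  Two-sided Wald p-values on
the count-part group coefficient feed the downstream selection; the model
with the smallest AIC wins per-(OTU, pair) arbitration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

MODELS = ("P", "NB", "ZIP", "ZINB")
#: Arbitration order for AIC ties with equal parameter counts.
MODEL_ORDER = {m: i for i, m in enumerate(MODELS)}

_PHI_FLOOR = 1e-8  # below this the NB/ZINB fit is degenerate-to-Poisson
_MAX_ITER = 500
_GTOL = 1e-8


class NumericOverflowError(FloatingPointError):
    """Raised when a likelihood evaluation produces a non-finite value."""


@dataclass
class CountData:
    """Inputs for one (OTU, pair) fit.

    ``design_count`` holds the count-part covariates x_i (intercept + group
    dummy for a city-year pair); ``design_zero`` the zero-part covariates
    z_i (defaults to x_i when None and a zero-inflated model is fitted);
    ``offset`` is log(N_i) for library sizes N_i.
    """

    y: np.ndarray
    design_count: np.ndarray
    offset: np.ndarray
    design_zero: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.design_count = np.atleast_2d(np.asarray(self.design_count, dtype=float))
        self.offset = np.asarray(self.offset, dtype=float)
        n = self.y.shape[0]
        if n < 2:
            raise ValueError("need at least 2 observations")
        if self.design_count.shape[0] != n or self.offset.shape[0] != n:
            raise ValueError("y, design_count and offset must have equal length")
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("y must be nonnegative integers")
        if self.design_zero is not None:
            self.design_zero = np.atleast_2d(np.asarray(self.design_zero, dtype=float))
            if self.design_zero.shape[0] != n:
                raise ValueError("design_zero length mismatch")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def zero_design(self) -> np.ndarray:
        return self.design_count if self.design_zero is None else self.design_zero


@dataclass
class CountModelFit:
    """A fitted count model: parameters, uncertainty and fit quality.

    ``se``/``pvalues`` align with the free-parameter vector
    ``(beta, [gamma], [log phi])``; ``pvalues`` are two-sided Wald tests of
    zero.  ``aic = 2k - 2*loglik`` with ``k`` free parameters.
    """

    model: str
    beta: np.ndarray
    gamma: np.ndarray
    phi: Optional[float]
    se: np.ndarray
    loglik: float
    aic: float
    pvalues: np.ndarray
    converged: bool
    n_params: int
    degenerate: Optional[str] = None
    se_available: bool = True

    @property
    def group_pvalue(self) -> float:
        """Wald p for the count-part group dummy (beta's second entry)."""
        return float(self.pvalues[1])


def _split_params(model: str, params: np.ndarray, p: int, q: int):
    """(beta, gamma, log_phi) from the packed free-parameter vector."""
    params = np.asarray(params, dtype=float)
    beta = params[:p]
    gamma = np.empty(0)
    log_phi = None
    pos = p
    if model in ("ZIP", "ZINB"):
        gamma = params[pos : pos + q]
        pos += q
    if model in ("NB", "ZINB"):
        log_phi = params[pos]
    return beta, gamma, log_phi


def n_free_params(model: str, p: int, q: int) -> int:
    k = p
    if model in ("ZIP", "ZINB"):
        k += q
    if model in ("NB", "ZINB"):
        k += 1
    return k


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    log_mu_r = np.log(mu + r)
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * (np.log(r) - log_mu_r)
        + y * (np.log(mu) - log_mu_r)
    )


def _poisson_logpmf(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # eta = log(mu); written with eta to avoid log(exp(.)) round trips
    return y * eta - np.exp(eta) - special.gammaln(y + 1.0)


def _nb_logpmf_zero(mu: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    return r * (np.log(r) - np.log(mu + r))


def loglik(model: str, params: Sequence[float], data: CountData) -> float:
    """Exact log-likelihood of ``model`` at ``params`` on ``data``.

    ``params`` packs ``(beta, [gamma], [log phi])``.  Raises
    :class:`NumericOverflowError` naming the first offending observation if
    the result is not finite.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    p = data.design_count.shape[1]
    q = data.zero_design().shape[1]
    beta, gamma, log_phi = _split_params(model, np.asarray(params, float), p, q)
    eta = data.offset + data.design_count @ beta
    y = data.y
    with np.errstate(over="ignore", invalid="ignore"):
        if model == "P":
            terms = _poisson_logpmf(y, eta)
        elif model == "NB":
            phi = float(np.exp(log_phi))
            if phi < _PHI_FLOOR:
                terms = _poisson_logpmf(y, eta)
            else:
                terms = _nb_logpmf(y, np.exp(eta), phi)
        else:
            eta_z = data.zero_design() @ gamma
            # log pi = eta_z - log(1+e^eta_z); log(1-pi) = -log(1+e^eta_z)
            log_denom = np.logaddexp(0.0, eta_z)
            mu = np.exp(eta)
            if model == "ZIP":
                base_zero = -mu
                base_pos = _poisson_logpmf(y, eta)
            else:  # ZINB
                phi = float(np.exp(log_phi))
                if phi < _PHI_FLOOR:
                    base_zero = -mu
                    base_pos = _poisson_logpmf(y, eta)
                else:
                    base_zero = _nb_logpmf_zero(mu, phi)
                    base_pos = _nb_logpmf(y, mu, phi)
            is_zero = y == 0
            terms = np.where(
                is_zero,
                np.logaddexp(eta_z, base_zero) - log_denom,
                base_pos - log_denom,
            )
    total = float(np.sum(terms))
    if not np.isfinite(total):
        bad = int(np.argwhere(~np.isfinite(terms))[0][0])
        raise NumericOverflowError(
            f"non-finite {model} log-likelihood at observation {bad}"
        )
    return total


def _poisson_grad(params, data: CountData) -> np.ndarray:
    eta = data.offset + data.design_count @ params
    return data.design_count.T @ (data.y - np.exp(eta))


def _nb_grad(params, data: CountData) -> np.ndarray:
    p = data.design_count.shape[1]
    beta, log_phi = params[:p], params[p]
    phi = float(np.exp(log_phi))
    mu = np.exp(data.offset + data.design_count @ beta)
    r = 1.0 / phi
    y = data.y
    g_beta = data.design_count.T @ ((y - mu) * r / (r + mu))
    # d loglik / d r, then chain through r = exp(-log_phi): dr/dlogphi = -r
    dl_dr = np.sum(
        special.digamma(y + r) - special.digamma(r)
        + np.log(r) + 1.0 - np.log(r + mu) - (y + r) / (r + mu)
    )
    return np.concatenate([g_beta, [-r * dl_dr]])


def _poisson_closed_form_start(data: CountData) -> np.ndarray:
    """Poisson MLE via Newton iterations (fast, reliable start point)."""
    p = data.design_count.shape[1]
    beta = np.zeros(p)
    rate = data.y.sum() / np.exp(data.offset).sum()
    beta[0] = np.log(max(rate, 1e-12))
    for _ in range(50):
        eta = data.offset + data.design_count @ beta
        mu = np.exp(np.clip(eta, -700, 700))
        grad = data.design_count.T @ (data.y - mu)
        hess = (data.design_count * mu[:, None]).T @ data.design_count
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def _moment_phi(y: np.ndarray, mu: np.ndarray) -> float:
    # method-of-moments dispersion: Var = mu + phi mu^2
    resid = (y - mu) ** 2 - mu
    denom = np.sum(mu**2)
    if denom <= 0:
        return 1e-3
    return float(max(np.sum(resid) / denom, 1e-3))


def _logistic_zero_start(data: CountData) -> np.ndarray:
    """gamma start: logistic regression of the zero indicator on design_zero."""
    Z = data.zero_design()
    z = (data.y == 0).astype(float)
    q = Z.shape[1]
    gamma = np.zeros(q)
    pbar = np.clip(z.mean(), 1e-3, 1 - 1e-3)
    gamma[0] = np.log(pbar / (1 - pbar))
    for _ in range(25):
        pi = special.expit(Z @ gamma)
        w = np.clip(pi * (1 - pi), 1e-8, None)
        grad = Z.T @ (z - pi)
        hess = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(hess + 1e-8 * np.eye(q), grad)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5, 5)
        gamma = gamma + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(gamma, -10, 10)


def _initial_params(model: str, data: CountData) -> np.ndarray:
    beta0 = _poisson_closed_form_start(data)
    parts = [beta0]
    if model in ("ZIP", "ZINB"):
        parts.append(_logistic_zero_start(data))
    if model in ("NB", "ZINB"):
        mu = np.exp(data.offset + data.design_count @ beta0)
        parts.append([np.log(_moment_phi(data.y, mu))])
    return np.concatenate([np.atleast_1d(p) for p in parts])


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of ``fun`` at ``x``."""
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def wald_pvalue(estimate: float, se: float) -> float:
    """Two-sided Wald p-value ``2 * (1 - Phi(|estimate/se|))``."""
    if se <= 0 or not np.isfinite(se):
        raise ValueError(f"undefined p-value: se={se}")
    return float(2.0 * stats.norm.sf(abs(estimate / se)))


def fit(model: str, data: CountData, init: Optional[np.ndarray] = None) -> CountModelFit:
    """Maximum-likelihood fit of ``model`` on ``data``.

    Quasi-Newton (BFGS) on the unconstrained parametrization; analytic
    gradients for P/NB, finite differences for the zero-inflated models.
    On non-convergence a perturbed restart is attempted.  Standard errors
    come from the inverse observed information; a singular information
    matrix yields ``se_available=False`` and ``converged=False``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model in ("P", "NB") and data.y.sum() == 0:
        raise ValueError(f"{model} undefined for identically-zero counts")
    p = data.design_count.shape[1]
    q = data.zero_design().shape[1]
    x0 = np.asarray(init, float) if init is not None else _initial_params(model, data)

    def nll(params):
        try:
            return -loglik(model, params, data)
        except NumericOverflowError:
            return np.inf

    if model == "P":
        jac = lambda params: -_poisson_grad(params, data)
    elif model == "NB":
        jac = lambda params: -_nb_grad(params, data)
    else:
        jac = "3-point"

    best = None
    starts = [x0]
    rng = np.random.default_rng(0)
    for attempt, start in enumerate(starts):
        res = optimize.minimize(
            nll, start, jac=jac, method="BFGS",
            options={"gtol": _GTOL, "maxiter": _MAX_ITER},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        if attempt == 0:
            starts.append(x0 + rng.normal(scale=0.5, size=x0.size))

    params = best.x
    ll = -best.fun
    converged = bool(np.isfinite(ll)) and (
        best.success or np.linalg.norm(getattr(best, "jac", np.array([np.inf]))) < 1e-3
    )
    beta, gamma, log_phi = _split_params(model, params, p, q)
    phi = float(np.exp(log_phi)) if log_phi is not None else None
    degenerate = None
    k = n_free_params(model, p, q)

    at_boundary = phi is not None and phi < 1e-4
    if at_boundary:
        # snap to the exact Poisson limit and re-polish the other parameters;
        # the phi direction is flat there, so its se is undefined
        fixed_log_phi = np.log(_PHI_FLOOR) - 10.0
        def nll_red(qs):
            return nll(np.concatenate([qs, [fixed_log_phi]]))
        jac_red = (lambda qs: -_poisson_grad(qs, data)) if model == "NB" else "3-point"
        res2 = optimize.minimize(
            nll_red, params[:-1], jac=jac_red, method="BFGS",
            options={"gtol": _GTOL, "maxiter": _MAX_ITER},
        )
        if -res2.fun >= ll - 1e-10:
            params = np.concatenate([res2.x, [fixed_log_phi]])
            ll = -res2.fun
            converged = converged or res2.success
        beta, gamma, log_phi = _split_params(model, params, p, q)
        phi = 0.0
        degenerate = "degenerate-to-Poisson"
    if model in ("ZIP", "ZINB") and np.all(data.y == 0):
        degenerate = "all-zero: pi -> 1 boundary"
        converged = False

    se = np.full(k, np.nan)
    pvals = np.full(k, np.nan)
    se_available = False
    if np.isfinite(ll):
        if at_boundary:
            free = np.arange(k - 1)
            H = _numeric_hessian(lambda qs: nll(np.concatenate([qs, [params[-1]]])), params[:-1])
        else:
            free = np.arange(k)
            H = _numeric_hessian(nll, params)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                se[free] = np.sqrt(diag)
                pvals[free] = [wald_pvalue(est, s) for est, s in zip(params[free], se[free])]
                se_available = True
        except np.linalg.LinAlgError:
            pass
    if not se_available:
        logger.debug("%s fit: singular information matrix; se unavailable", model)
        converged = False

    return CountModelFit(
        model=model,
        beta=beta,
        gamma=gamma,
        phi=phi,
        se=se,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        pvalues=pvals,
        converged=converged,
        n_params=k,
        degenerate=degenerate,
        se_available=se_available,
    )


def compare_by_aic(fits: Sequence[CountModelFit]) -> CountModelFit:
    """Return the converged fit with the smallest AIC.

    Ties break by fewer free parameters, then by the fixed model order
    P < NB < ZIP < ZINB.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fit to arbitrate")
    return min(usable, key=lambda f: (f.aic, f.n_params, MODEL_ORDER[f.model]))
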