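"""Mixed models with crossed random intercepts.

Two estimators live here:

* :func:`fit_lmm` — Gaussian linear mixed model. Variance ratios
  ``theta_f = sigma2_f / sigma2_e`` are optimized on the log scale with the
  fixed effects and the residual variance profiled out analytically
  (Woodbury/matrix-determinant-lemma algebra, so cost scales with the total
  number of random-intercept levels q, not with n).
* :func:`fit_binomial_glmm` — logit-link binomial mixed model. The marginal
  likelihood is approximated by a Laplace approximation around the joint
  penalized mode of (beta, u) (the lme4 strategy); for a single random factor
  an adaptive Gauss-Hermite rule (``nagq`` > 1) is available and is used by
  the test suite's quadrature cross-checks.

Random effects are intercepts only; the scaled parameterization u = sigma * b
with b ~ N(0, I) keeps the objective smooth at sigma -> 0, so boundary fits
degrade gracefully into plain OLS / logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MixedFit", "fit_lmm", "fit_binomial_glmm", "ConvergenceWarning"]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class MixedFit:
    """Result of a mixed-model fit (either family)."""

    beta: np.ndarray
    se: np.ndarray
    vcov_beta: np.ndarray
    vc: dict[str, float]                 # random-intercept variances per factor
    sigma2: float | None                 # residual variance (gaussian only)
    u: dict[str, np.ndarray]             # BLUPs / conditional modes per factor
    levels: dict[str, np.ndarray]        # level labels, aligned with u
    loglik: float
    n_obs: int
    n_params: int                        # fixed + variance parameters
    criterion: str                       # "ML", "REML", or "Laplace"/"AGQ<k>"
    converged: bool
    singular: bool = False
    message: str = ""
    family: str = "gaussian"
    nagq: int = field(default=1, repr=False)

    def u_lookup(self, factor: str) -> dict:
        return dict(zip(self.levels[factor], self.u[factor]))


def _encode_factors(factors: dict[str, np.ndarray], n: int):
    """Label arrays -> (codes, level labels); preserves first-seen order."""
    codes, levels = {}, {}
    for name, labels in factors.items():
        labels = np.asarray(labels)
        if labels.shape != (n,):
            raise ValueError(f"random factor {name!r} has wrong length")
        uniq, inv = np.unique(labels, return_inverse=True)
        codes[name] = inv
        levels[name] = uniq
    return codes, levels


def _dense_z(codes: dict[str, np.ndarray], n: int):
    """Stacked indicator matrix Z (n x q) and per-factor column slices."""
    slices, cols = {}, 0
    for name, c in codes.items():
        k = int(c.max()) + 1 if len(c) else 0
        slices[name] = slice(cols, cols + k)
        cols += k
    Z = np.zeros((n, cols))
    for name, c in codes.items():
        Z[np.arange(n), slices[name].start + c] = 1.0
    return Z, slices


# ---------------------------------------------------------------------------
# Gaussian LMM
# ---------------------------------------------------------------------------

def _lmm_profile(log_theta, y, X, Z, slices, free, reml):
    """Profiled -2*loglik pieces for variance ratios theta (free factors only).

    Returns (neg_loglik, beta, sigma2, cov_unscaled, resid, K_chol, scale)
    where cov_unscaled = (X' M^-1 X)^-1 and M = I + Z Theta Z'.
    """
    n, p = X.shape
    scale = np.zeros(Z.shape[1])
    for (name, sl), lt in zip(free.items(), log_theta):
        scale[sl] = np.exp(0.5 * lt)   # sqrt(theta_f)
    U = Z * scale                       # n x q
    q = U.shape[1]
    K = U.T @ U + np.eye(q)
    Kc = cho_factor(K, lower=True)
    logdet_M = 2.0 * np.log(np.diag(Kc[0])).sum()

    UtX = U.T @ X
    Uty = U.T @ y
    XtMiX = X.T @ X - UtX.T @ cho_solve(Kc, UtX)
    XtMiy = X.T @ y - UtX.T @ cho_solve(Kc, Uty)
    ytMiy = y @ y - Uty @ cho_solve(Kc, Uty)

    cov_unscaled = np.linalg.inv(XtMiX)
    beta = cov_unscaled @ XtMiy
    rss = float(ytMiy - beta @ XtMiy)
    rss = max(rss, 1e-300)
    if reml:
        sigma2 = rss / (n - p)
        sign, logdet_X = np.linalg.slogdet(XtMiX)
        nll = 0.5 * ((n - p) * (_LOG2PI + np.log(sigma2)) + logdet_M
                     + logdet_X + (n - p))
    else:
        sigma2 = rss / n
        nll = 0.5 * (n * (_LOG2PI + np.log(sigma2)) + logdet_M + n)
    return nll, beta, sigma2, cov_unscaled, Kc, U, scale


def fit_lmm(
    y,
    X,
    factors: dict[str, np.ndarray],
    criterion: str = "REML",
    var_fixed: dict[str, float] | None = None,
    feature_names: list[str] | None = None,
    maxiter: int = 500,
) -> MixedFit:
    """Fit a Gaussian LMM with crossed random intercepts.

    Parameters
    ----------
    y, X
        Response (n,) and design matrix (n, p) including the intercept column.
    factors
        Mapping factor name -> length-n array of level labels.
    criterion
        ``"ML"`` or ``"REML"``.
    var_fixed
        Factors whose random-intercept variance is pinned (only 0.0 is
        supported); pinned factors are reported with variance 0 and u = 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y/X length mismatch")
    if criterion not in {"ML", "REML"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    reml = criterion == "REML"
    var_fixed = dict(var_fixed or {})
    for name, v in var_fixed.items():
        if v != 0.0:
            raise NotImplementedError("variances can only be pinned to 0")

    free_names = [f for f in factors if f not in var_fixed]
    codes, levels = _encode_factors(factors, n)
    free_codes = {f: codes[f] for f in free_names}
    Z, slices = _dense_z(free_codes, n)
    free = {f: slices[f] for f in free_names}

    start_obj = None
    if free_names:
        x0 = np.zeros(len(free_names))     # theta = 1 start

        def objective(lt):
            lt = np.clip(lt, -30.0, 30.0)
            try:
                return _lmm_profile(lt, y, X, Z, free, free, reml)[0]
            except np.linalg.LinAlgError:
                return np.inf

        start_obj = objective(x0)
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": maxiter,
                     "maxfev": maxiter * 4},
        )
        log_theta = np.clip(res.x, -30.0, 30.0)
        converged = bool(res.success) or res.fun <= start_obj + 1e-9
        message = res.message
    else:
        log_theta = np.array([])
        converged, message = True, "no free variance parameters"

    nll, beta, sigma2, cov_unscaled, Kc, U, scale = _lmm_profile(
        log_theta, y, X, Z, free, free, reml)
    loglik = -nll

    theta = np.exp(log_theta)
    vc = {name: float(theta[i] * sigma2) for i, name in enumerate(free_names)}
    singular = any(t < 1e-8 for t in theta)
    if singular:
        warnings.warn("variance component estimated at the zero boundary",
                      ConvergenceWarning, stacklevel=2)
    for name in var_fixed:
        vc[name] = 0.0

    # BLUPs: u = Theta Z' M^-1 (y - X beta), in the scaled parameterization
    resid = y - X @ beta
    Ut_r = U.T @ resid
    b = Ut_r - U.T @ (U @ cho_solve(Kc, Ut_r))   # = U' M^-1 r
    u_all = scale * b                             # sqrt(theta) * b, then *sqrt(theta)... see below
    # u = theta * (Z' M^-1 r); U = Z*scale so U'M^-1 r = scale * Z'M^-1 r
    # hence Z'M^-1 r = b / scale (where scale>0) and u = theta * that = scale * b.
    u = {}
    for name in factors:
        if name in free:
            u[name] = u_all[free[name]]
        else:
            u[name] = np.zeros(len(levels[name]))

    vcov_beta = sigma2 * cov_unscaled
    se = np.sqrt(np.clip(np.diag(vcov_beta), 0, None))
    n_params = p + len(free_names) + 1   # + residual variance
    return MixedFit(
        beta=beta, se=se, vcov_beta=vcov_beta, vc=vc, sigma2=float(sigma2),
        u=u, levels=levels, loglik=float(loglik), n_obs=n, n_params=n_params,
        criterion=criterion, converged=converged, singular=singular,
        message=str(message), family="gaussian",
    )


# ---------------------------------------------------------------------------
# Binomial GLMM
# ---------------------------------------------------------------------------

def _penalized_mode(y, X, Z, sigma_cols, beta0, b0, max_newton=100):
    """Joint penalized Newton for (beta, b); returns mode and curvature."""
    n, p = X.shape
    q = Z.shape[1]
    U = Z * sigma_cols
    phi = np.concatenate([beta0, b0])

    def pll(phi):
        eta = X @ phi[:p] + U @ phi[p:]
        return float(y @ eta - np.logaddexp(0.0, eta).sum()
                     - 0.5 * phi[p:] @ phi[p:])

    cur = pll(phi)
    for _ in range(max_newton):
        eta = X @ phi[:p] + U @ phi[p:]
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        g = np.concatenate([X.T @ (y - mu), U.T @ (y - mu) - phi[p:]])
        C = np.empty((p + q, p + q))
        Xw = X * w[:, None]
        C[:p, :p] = Xw.T @ X
        C[:p, p:] = Xw.T @ U
        C[p:, :p] = C[:p, p:].T
        C[p:, p:] = (U * w[:, None]).T @ U + np.eye(q)
        try:
            step = np.linalg.solve(C, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(C, g, rcond=None)[0]
        # step-halving line search on the penalized log-likelihood
        t = 1.0
        for _ in range(30):
            cand = phi + t * step
            new = pll(cand)
            if new >= cur - 1e-12:
                break
            t *= 0.5
        phi, improved = cand, new - cur
        cur = new
        if abs(improved) < 1e-10 * (1.0 + abs(cur)) and np.abs(g).max() < 1e-6:
            break
    eta = X @ phi[:p] + U @ phi[p:]
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    return phi[:p], phi[p:], cur, w, U


def _laplace_nll(log_sigma, y, X, Z, free, q, warm):
    sigma_cols = np.zeros(q)
    for (name, sl), ls in zip(free.items(), log_sigma):
        sigma_cols[sl] = np.exp(ls)
    beta, b, pll, w, U = _penalized_mode(y, X, Z, sigma_cols,
                                         warm["beta"], warm["b"])
    warm["beta"], warm["b"] = beta, b
    q_eff = U.shape[1]
    H = (U * w[:, None]).T @ U + np.eye(q_eff)
    sign, logdet = np.linalg.slogdet(H)
    nll = -(pll - 0.5 * logdet)
    return nll, beta, b, w, U


def _agq_nll(params, y, X, codes, p, nodes, weights):
    """Adaptive Gauss-Hermite -loglik for a single random factor.

    params = (beta, log_sigma); per-level 1-D integrals centered/scaled at
    each level's conditional mode.
    """
    beta, sigma = params[:p], np.exp(params[p])
    eta0 = X @ beta
    k = int(codes.max()) + 1
    total = 0.0
    for j in range(k):
        idx = codes == j
        yj, ej = y[idx], eta0[idx]

        def negpll(v):
            e = ej + sigma * v
            return -(yj @ e - np.logaddexp(0.0, e).sum() - 0.5 * v * v)

        r = optimize.minimize_scalar(negpll, bounds=(-30, 30), method="bounded",
                                     options={"xatol": 1e-10})
        vhat = r.x
        mu = special.expit(ej + sigma * vhat)
        h = sigma**2 * np.sum(mu * (1 - mu)) + 1.0     # curvature at mode
        s = 1.0 / np.sqrt(h)
        v = vhat + s * nodes
        e = ej[None, :] + sigma * v[:, None]
        # g(v) = loglik(v) - v^2/2; per-level integral is
        # s * sum_i w_i exp(z_i^2/2) exp(g(vhat + s z_i)) / sqrt(2*pi)
        # with probabilists' Hermite nodes z_i / weights w_i.
        g = (yj[None, :] * e - np.logaddexp(0.0, e)).sum(axis=1) - 0.5 * v**2
        log_terms = g + 0.5 * nodes**2 + np.log(weights) + np.log(s)
        total += special.logsumexp(log_terms) - 0.5 * _LOG2PI
    return -total


def fit_binomial_glmm(
    y,
    X,
    factors: dict[str, np.ndarray],
    var_fixed: dict[str, float] | None = None,
    nagq: int = 1,
    feature_names: list[str] | None = None,
    maxiter: int = 300,
) -> MixedFit:
    """Fit a logit-link binomial GLMM with crossed random intercepts.

    ``nagq=1`` uses the Laplace approximation (default, any number of crossed
    factors); ``nagq>1`` uses adaptive Gauss-Hermite quadrature and requires
    exactly one free random factor.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y/X length mismatch")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial outcome must be coded 0/1")
    var_fixed = dict(var_fixed or {})
    for name, v in var_fixed.items():
        if v != 0.0:
            raise NotImplementedError("variances can only be pinned to 0")

    codes, levels = _encode_factors(factors, n)
    free_names = [f for f in factors if f not in var_fixed]
    free_codes = {f: codes[f] for f in free_names}
    Z, slices = _dense_z(free_codes, n)
    q = Z.shape[1]
    free = {f: slices[f] for f in free_names}

    # start fixed effects at the plain-logistic solution
    warm = {"beta": np.zeros(p), "b": np.zeros(q)}
    beta_glm, _, _, _, _ = _penalized_mode(y, X, np.zeros((n, 0)),
                                           np.zeros(0), np.zeros(p),
                                           np.zeros(0))
    warm["beta"] = beta_glm

    if nagq > 1:
        if len(free_names) != 1:
            raise ValueError("nagq > 1 requires exactly one free random factor")
        nodes, weights = special.roots_hermitenorm(nagq)
        c = codes[free_names[0]]
        x0 = np.concatenate([beta_glm, [0.0]])
        res = optimize.minimize(
            _agq_nll, x0, args=(y, X, c, p, nodes, weights),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000,
                     "maxfev": 8000},
        )
        beta = res.x[:p]
        sigma = float(np.exp(res.x[p]))
        loglik = -float(res.fun)
        # conditional modes + SEs via one Laplace pass at the AGQ optimum
        sigma_cols = np.full(q, sigma)
        _, b, _, w, U = _penalized_mode(y, X, Z, sigma_cols, beta, np.zeros(q))
        vcov_beta, se = _beta_cov(y, X, U, w, p, q)
        vc = {free_names[0]: sigma**2}
        for name in var_fixed:
            vc[name] = 0.0
        u = {name: (sigma_cols[free[name]] * b[free[name]]
                    if name in free else np.zeros(len(levels[name])))
             for name in factors}
        return MixedFit(beta=beta, se=se, vcov_beta=vcov_beta, vc=vc,
                        sigma2=None, u=u, levels=levels, loglik=loglik,
                        n_obs=n, n_params=p + 1, criterion="ML",
                        converged=bool(res.success), singular=sigma < 1e-4,
                        message=str(res.message), family="binomial",
                        nagq=nagq)

    if free_names:
        x0 = np.zeros(len(free_names))

        def objective(ls):
            ls = np.clip(ls, -8.0, 3.0)
            return _laplace_nll(ls, y, X, Z, free, q, warm)[0]

        start_obj = objective(x0)
        # Powell is derivative-free (finite-difference gradients are too
        # noisy through the inner Newton solve) and converges in roughly
        # half the evaluations Nelder-Mead needs here.
        res = optimize.minimize(
            objective, x0, method="Powell",
            bounds=[(-8.0, 3.0)] * len(free_names),
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": maxiter,
                     "maxfev": maxiter * 8},
        )
        log_sigma = np.clip(res.x, -8.0, 3.0)
        converged = bool(res.success) or res.fun <= start_obj + 1e-9
        message = res.message
    else:
        log_sigma = np.array([])
        converged, message = True, "no free variance parameters"

    nll, beta, b, w, U = _laplace_nll(log_sigma, y, X, Z, free, q, warm)
    loglik = -float(nll)
    sigma = np.exp(log_sigma)
    vc = {name: float(sigma[i] ** 2) for i, name in enumerate(free_names)}
    singular = any(s < 1e-3 for s in sigma)
    for name in var_fixed:
        vc[name] = 0.0

    if np.abs(beta).max() > 30:
        warnings.warn("very large coefficient — possible complete separation",
                      ConvergenceWarning, stacklevel=2)
    if not converged:
        warnings.warn(f"binomial GLMM did not converge: {message}",
                      ConvergenceWarning, stacklevel=2)

    u = {}
    for name in factors:
        if name in free:
            sl = free[name]
            u[name] = float(sigma[free_names.index(name)]) * b[sl]
        else:
            u[name] = np.zeros(len(levels[name]))

    vcov_beta, se = _beta_cov(y, X, U, w, p, q)
    n_params = p + len(free_names)
    return MixedFit(beta=beta, se=se, vcov_beta=vcov_beta, vc=vc, sigma2=None,
                    u=u, levels=levels, loglik=loglik, n_obs=n,
                    n_params=n_params, criterion="ML", converged=converged,
                    singular=singular, message=str(message),
                    family="binomial", nagq=1)


def _beta_cov(y, X, U, w, p, q):
    """Fixed-effect covariance from the joint penalized Hessian (beta block)."""
    C = np.empty((p + q, p + q))
    Xw = X * w[:, None]
    C[:p, :p] = Xw.T @ X
    C[:p, p:] = Xw.T @ U
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = (U * w[:, None]).T @ U + np.eye(q)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Cinv = np.linalg.pinv(C)
    vcov = Cinv[:p, :p]
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    return vcov, se
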