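"""Sample-based reliability coefficients: alpha, the GLB, and omega variants.

All coefficients operate on the observed covariance (or correlation)
structure of an N x I response matrix:

* ``cronbach_alpha`` — Guttman's lambda-3, [I/(I-1)] (1 - sum Var(Y_i)/Var(Y));
* ``glb`` — the greatest lower bound to reliability, 1 - tr(Sigma_E)/Var(Y),
  obtained by maximizing the total error variance subject to the true-score
  covariance matrix Sigma_Y - diag(e) staying positive semidefinite and
  e >= 0.  The trace maximization is a semidefinite program; it is solved
  here by a primal log-det barrier interior-point method (Newton steps on the
  I error variances, which is exact for this convex problem);
* ``factor_minres`` / ``omega_total`` — one-factor exploratory solution by
  minimum residuals (ordinary least squares on off-diagonal elements) and
  McDonald's omega-total (sum lambda)^2 / [(sum lambda)^2 + sum psi^2];
* ``cfa_ml_onefactor`` — a one-factor confirmatory fit by normal-theory
  maximum likelihood with the latent variance fixed at 1.

Variances and covariances use the unbiased n-1 denominator throughout.
Heywood cases are handled by bounding uniquenesses below at 1e-3 and flagging
the solution rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model_core import validate_responses

__all__ = [
    "FactorSolution",
    "covariance_matrix",
    "cronbach_alpha",
    "glb",
    "glb_from_responses",
    "factor_minres",
    "cfa_ml_onefactor",
    "omega_total",
    "omega_from_responses",
]

_MIN_UNIQUENESS = 1e-3


@dataclass(frozen=True)
class FactorSolution:
    """One-factor solution: loadings, uniquenesses and fit metadata."""

    loadings: np.ndarray
    uniquenesses: np.ndarray
    converged: bool = True
    n_iter: int = 0
    heywood: bool = False


def covariance_matrix(responses: np.ndarray) -> np.ndarray:
    """Unbiased (n-1) sample covariance matrix of the item columns."""
    x = validate_responses(responses)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 persons")
    s = np.cov(x.astype(float), rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    if np.any(np.diag(s) == 0):
        warnings.warn("constant item column: zero variance", stacklevel=2)
    return s


def cronbach_alpha(responses: np.ndarray) -> float:
    """Cronbach's alpha (Guttman's lambda-3) of the sum score."""
    x = validate_responses(responses).astype(float)
    n, i = x.shape
    if i < 2:
        raise ValueError("alpha requires at least 2 items")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("sum score has zero variance")
    return float(i / (i - 1) * (1.0 - item_var.sum() / total_var))


# ---------------------------------------------------------------------------
# Greatest lower bound
# ---------------------------------------------------------------------------


def _glb_barrier_newton(sigma: np.ndarray, tol: float = 1e-8, max_outer: int = 60):
    """Interior-point solve of  max sum(e)  s.t.  sigma - diag(e) PSD, e >= 0.

    Follows the central path of the barrier

        f_mu(e) = -sum(e) - mu [ log det(sigma - diag(e)) + sum log e ]

    which is convex in e (the gradient of -log det(A) w.r.t. e_i is
    (A^-1)_ii and its Hessian is the elementwise square of A^-1, a PSD
    matrix).  Damped Newton steps stay strictly feasible; mu is reduced
    geometrically until the duality-gap proxy 2 I mu < tol.
    """
    i_dim = sigma.shape[0]
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin <= 0:
        raise ValueError("sigma must be strictly positive definite for the GLB solve")
    e = np.full(i_dim, 0.9 * eigmin / 1.0)  # sigma - diag(e) stays PD
    mu = max(float(np.trace(sigma)) / i_dim, 1.0)
    n_newton = 0
    for _ in range(max_outer):
        for _ in range(50):
            A = sigma - np.diag(e)
            Ainv = np.linalg.inv(A)
            grad = -1.0 + mu * np.diag(Ainv) - mu / e
            hess = mu * Ainv**2 + np.diag(mu / e**2)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = grad / np.diag(hess)
            # backtracking line search keeping strict feasibility
            t = 1.0
            for _ in range(60):
                e_new = e - t * step
                if np.all(e_new > 0):
                    try:
                        np.linalg.cholesky(sigma - np.diag(e_new))
                        break
                    except np.linalg.LinAlgError:
                        pass
                t *= 0.5
            else:
                raise RuntimeError("GLB line search failed to stay feasible")
            decrement = float(grad @ step)
            e = e_new
            n_newton += 1
            if decrement < 1e-10:
                break
        if 2.0 * i_dim * mu < tol:
            break
        mu *= 0.15
    else:
        raise RuntimeError("GLB interior-point method did not converge")
    return e, n_newton


def glb(sigma: np.ndarray, tol: float = 1e-8) -> float:
    """Greatest lower bound to reliability from a covariance matrix.

    Maximizes the trace of a nonnegative diagonal error matrix subject to
    the remaining true-score covariance matrix being positive semidefinite,
    then returns 1 - tr(Sigma_E) / Var(Y) with Var(Y) = 1' Sigma_Y 1.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1] or sigma.shape[0] < 2:
        raise ValueError("sigma must be a square matrix with I >= 2")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("sigma must be symmetric")
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin < -1e-10:
        raise ValueError("sigma must be positive semidefinite")
    var_y = float(sigma.sum())
    if var_y <= 0:
        raise ValueError("total variance must be positive")
    if eigmin <= 1e-12:
        # Singular true rank-deficient input: no diagonal can be removed in
        # directions already at the PSD boundary; perturb within tolerance.
        sigma = sigma + 1e-10 * np.eye(sigma.shape[0])
    e, _ = _glb_barrier_newton(sigma, tol=tol)
    val = 1.0 - e.sum() / var_y
    return float(min(max(val, 0.0), 1.0))


def glb_from_responses(responses: np.ndarray) -> float:
    """GLB of the sum score computed from raw binary responses."""
    return glb(covariance_matrix(responses))


# ---------------------------------------------------------------------------
# One-factor solutions and omega
# ---------------------------------------------------------------------------


def _fix_sign(lam: np.ndarray) -> np.ndarray:
    return lam if lam.sum() >= 0 else -lam


def _smc_start(r: np.ndarray) -> np.ndarray:
    """Squared-multiple-correlation start values with the sign pattern of the
    leading eigenvector; zero for diagonal matrices (degenerate input)."""
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    except np.linalg.LinAlgError:
        smc = np.full(r.shape[0], 0.5)
    _, v = np.linalg.eigh(r)
    lead = v[:, -1]
    signs = np.where(lead >= 0, 1.0, -1.0) * (1.0 if lead.sum() >= 0 else -1.0)
    return signs * np.sqrt(np.clip(smc, 0.0, 1.0))


def factor_minres(corr: np.ndarray, max_iter: int = 500) -> FactorSolution:
    """One-factor minres (OLS) fit to a correlation matrix.

    Minimizes the sum of squared off-diagonal residuals of ``corr - lam lam'``.
    Uniquenesses are 1 - lam^2, bounded below at 1e-3 (Heywood flagging).
    """
    r = np.asarray(corr, dtype=float)
    i_dim = r.shape[0]
    if r.ndim != 2 or r.shape[0] != r.shape[1] or i_dim < 3:
        raise ValueError("corr must be square with I >= 3")
    if not np.allclose(r, r.T, atol=1e-8) or not np.allclose(np.diag(r), 1.0, atol=1e-8):
        raise ValueError("corr must be a symmetric correlation matrix")
    off = ~np.eye(i_dim, dtype=bool)

    def objective(lam):
        resid = (r - np.outer(lam, lam))[off]
        return float(resid @ resid)

    def gradient(lam):
        m = r - np.outer(lam, lam)
        np.fill_diagonal(m, 0.0)
        return -4.0 * (m @ lam)

    lam0 = _smc_start(r)
    bound = np.sqrt(1.0 - _MIN_UNIQUENESS)
    lam0 = np.clip(lam0, -bound, bound)
    res = optimize.minimize(
        objective, lam0, jac=gradient, method="L-BFGS-B",
        bounds=[(-bound, bound)] * i_dim, options={"maxiter": max_iter},
    )
    lam = _fix_sign(res.x)
    heywood = bool(np.any(np.abs(lam) >= bound - 1e-9))
    if heywood:
        warnings.warn("minres Heywood case: uniqueness bounded at 1e-3", stacklevel=2)
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise RuntimeError(f"minres failed to converge: {res.message}")
    return FactorSolution(
        loadings=lam, uniquenesses=1.0 - lam**2,
        converged=bool(res.success), n_iter=int(res.nit), heywood=heywood,
    )


def cfa_ml_onefactor(sigma: np.ndarray, n: int, max_iter: int = 1000) -> FactorSolution:
    """One-factor CFA by normal-theory ML, latent variance fixed at 1.

    Minimizes F = log|Sigma(th)| + tr(S Sigma(th)^-1) - log|S| - I over
    Sigma(th) = lam lam' + diag(psi^2).  ``n`` (persons) is required for the
    precondition n > I; the discrepancy itself does not depend on it.
    """
    s = np.asarray(sigma, dtype=float)
    i_dim = s.shape[0]
    if s.ndim != 2 or s.shape[0] != s.shape[1] or i_dim < 3:
        raise ValueError("sigma must be square with I >= 3")
    if n <= i_dim:
        raise ValueError("need n > I for a normal-theory ML fit")
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sigma must be positive definite")

    def unpack(x):
        return x[:i_dim], x[i_dim:]

    def discrepancy_and_grad(x):
        lam, psi2 = unpack(x)
        model = np.outer(lam, lam) + np.diag(psi2)
        try:
            c = np.linalg.cholesky(model)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        inv = np.linalg.inv(model)
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        f = logdet + float(np.trace(s @ inv)) - logdet_s - i_dim
        g_sigma = inv - inv @ s @ inv
        g_lam = 2.0 * g_sigma @ lam
        g_psi = np.diag(g_sigma)
        return f, np.concatenate([g_lam, g_psi])

    diag_s = np.diag(s)
    lam0 = np.sqrt(np.clip(diag_s * 0.5, _MIN_UNIQUENESS, None))
    psi0 = np.clip(diag_s - lam0**2, _MIN_UNIQUENESS, None)
    x0 = np.concatenate([lam0, psi0])
    bounds = [(None, None)] * i_dim + [(_MIN_UNIQUENESS, None)] * i_dim
    res = optimize.minimize(
        discrepancy_and_grad, x0, jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    lam, psi2 = unpack(res.x)
    lam = _fix_sign(lam)
    heywood = bool(np.any(psi2 <= _MIN_UNIQUENESS + 1e-9))
    if heywood:
        warnings.warn("CFA Heywood case: uniqueness bounded at 1e-3", stacklevel=2)
    if not np.isfinite(res.fun) or res.fun >= 1e9:
        raise RuntimeError("CFA ML fit failed: non-PD model covariance")
    return FactorSolution(
        loadings=lam, uniquenesses=psi2,
        converged=bool(res.success), n_iter=int(res.nit), heywood=heywood,
    )


def omega_total(solution: FactorSolution) -> float:
    """McDonald's omega-total from a one-factor solution."""
    lam_sum = float(solution.loadings.sum())
    psi_sum = float(solution.uniquenesses.sum())
    denom = lam_sum**2 + psi_sum
    if denom <= 0:
        raise ValueError("degenerate solution: zero total variance")
    return lam_sum**2 / denom


def omega_from_responses(responses: np.ndarray, method: str = "minres") -> float:
    """Omega-total from raw responses.

    ``method="minres"`` fits the Pearson correlation matrix by minres (the
    exploratory route); ``method="cfa"`` fits the covariance matrix by
    normal-theory ML.  Omega is scale-free, so the two agree for an exact
    one-factor structure.
    """
    x = validate_responses(responses).astype(float)
    if method == "minres":
        r = np.corrcoef(x, rowvar=False)
        return omega_total(factor_minres(r))
    if method == "cfa":
        return omega_total(cfa_ml_onefactor(covariance_matrix(x), x.shape[0]))
    raise ValueError(f"unknown method {method!r}")
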