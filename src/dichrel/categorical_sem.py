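"""Categorical (nonlinear-SEM) reliability for dichotomous items.

The underlying-variable model: each binary item is a dichotomization of a
latent normal response variable y*_i = lam_i theta + eps_i (unit variance),
scored 1 when y*_i exceeds a threshold tau_i.  Estimation is limited
information and sequential: thresholds from the item margins, tetrachoric
correlations from the 2 x 2 tables (two-step ML with thresholds fixed), then
one-factor loadings on the probit metric fitted to the tetrachoric matrix by
unweighted (or diagonally weighted) least squares.

The Green-Yang reliability of the sum score is the ratio of the model-implied
true-score covariance of the sum to its model-implied total variance, where
each covariance entry takes the form

    Phi2(tau_i, tau_j; c) - Phi(tau_i) Phi(tau_j)

with c = lam_i lam_j in the numerator and c = rho*_ij (unit diagonal) in the
denominator.  Phi2 is the standard bivariate normal CDF, computed with the
Drezner-Wesolowsky / Genz Gauss-Legendre algorithm (absolute accuracy around
1e-14; the |rho| > 0.925 regime uses the complementary expansion).

This factor model is the probit-link twin of the 2PL: a probit item
characteristic curve Phi(a (theta - b)) corresponds to lam = a / sqrt(1 + a^2)
and tau = a b / sqrt(1 + a^2), so the population Green-Yang value coincides
with the quadrature reliability of the probit test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .model_core import validate_responses

__all__ = [
    "CategoricalFactorSolution",
    "threshold",
    "bivariate_normal_cdf",
    "tetrachoric",
    "tetrachoric_matrix",
    "probit_loadings",
    "green_yang_reliability",
    "green_yang_from_responses",
    "loading_from_discrimination",
    "threshold_from_parameters",
]

_RHO_BOUND = 0.999


@dataclass(frozen=True)
class CategoricalFactorSolution:
    """Thresholds, probit-metric loadings and the tetrachoric matrix."""

    thresholds: np.ndarray
    loadings: np.ndarray
    polychoric: np.ndarray


def threshold(item_responses: np.ndarray) -> float:
    """Threshold tau = Phi^-1(proportion of zeros) for one binary item."""
    x = np.asarray(item_responses)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("item responses must be binary")
    p0 = float(np.mean(x == 0))
    if p0 in (0.0, 1.0):
        raise ValueError("degenerate item: all responses identical")
    return float(stats.norm.ppf(p0))


# ---------------------------------------------------------------------------
# Bivariate normal CDF (Drezner-Wesolowsky / Genz)
# ---------------------------------------------------------------------------

# Gauss-Legendre nodes/weights on (-1, 1), 20 points
_GL_X, _GL_W = np.polynomial.legendre.leggauss(20)


def _bvnu(dh: float, dk: float, r: float) -> float:
    """Upper-orthant probability P(X > dh, Y > dk) for standard BVN, corr r."""
    if np.isposinf(dh) or np.isposinf(dk):
        return 0.0
    if np.isneginf(dh):
        return float(stats.norm.sf(dk))
    if np.isneginf(dk):
        return float(stats.norm.sf(dh))
    if r == 0.0:
        return float(stats.norm.sf(dh) * stats.norm.sf(dk))
    h, k = dh, dk
    hk = h * k
    if abs(r) < 0.925:
        hs = (h * h + k * k) / 2.0
        asr = np.arcsin(r)
        sn = np.sin(asr * (_GL_X + 1.0) / 2.0)
        bvn = float(np.sum(_GL_W * np.exp((sn * hk - hs) / (1.0 - sn**2))))
        bvn = bvn * asr / (4.0 * np.pi)
        return bvn + float(stats.norm.sf(h) * stats.norm.sf(k))
    # |r| close to 1: complementary expansion (Genz 2004)
    if r < 0.0:
        k = -k
        hk = -hk
    if abs(r) < 1.0:
        ass = (1.0 - r) * (1.0 + r)
        a = np.sqrt(ass)
        bs = (h - k) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr_e = -(bs / ass + hk) / 2.0
        bvn = 0.0
        if asr_e > -100.0:
            bvn = (
                a
                * np.exp(asr_e)
                * (1.0 - c * (bs - ass) * (1.0 - d * bs / 5.0) / 3.0 + c * d * ass * ass / 5.0)
            )
        if -hk < 100.0:
            b = np.sqrt(bs)
            sp = np.sqrt(2.0 * np.pi) * float(stats.norm.cdf(-b / a))
            bvn -= np.exp(-hk / 2.0) * sp * b * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0)
        a /= 2.0
        xs = (a * (1.0 + _GL_X)) ** 2
        ws = a * _GL_W
        rs = np.sqrt(1.0 - xs)
        asr_v = -(bs / xs + hk) / 2.0
        mask = asr_v > -100.0
        if mask.any():
            sp_v = 1.0 + c * xs[mask] * (1.0 + d * xs[mask])
            ep_v = np.exp(-hk * (1.0 - rs[mask]) / (2.0 * (1.0 + rs[mask]))) / rs[mask]
            bvn += float(np.sum(ws[mask] * np.exp(asr_v[mask]) * (ep_v - sp_v)))
        bvn = -bvn / (2.0 * np.pi)
    else:
        bvn = 0.0
    if r > 0.0:
        return bvn + float(stats.norm.sf(max(h, k)))
    bvn = -bvn
    if k > h:
        bvn += float(stats.norm.cdf(k) - stats.norm.cdf(h))
    return bvn


def bivariate_normal_cdf(tau_i: float, tau_j: float, rho: float) -> float:
    """P(Z1 <= tau_i, Z2 <= tau_j) for a standard bivariate normal."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if rho == 1.0:
        return float(stats.norm.cdf(min(tau_i, tau_j)))
    if rho == -1.0:
        return float(max(stats.norm.cdf(tau_i) + stats.norm.cdf(tau_j) - 1.0, 0.0))
    # P(X<=h, Y<=k) = P(X>-h, Y>-k) under symmetry
    return float(np.clip(_bvnu(-tau_i, -tau_j, rho), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Tetrachoric correlation
# ---------------------------------------------------------------------------


def _cell_probs(tau1: float, tau2: float, rho: float) -> np.ndarray:
    """2x2 cell probabilities [(0,0),(0,1),(1,0),(1,1)] under the BVN model."""
    p1 = stats.norm.cdf(tau1)
    p2 = stats.norm.cdf(tau2)
    p00 = bivariate_normal_cdf(tau1, tau2, rho)
    p01 = p1 - p00
    p10 = p2 - p00
    p11 = 1.0 - p1 - p2 + p00
    return np.clip(np.array([p00, p01, p10, p11]), 1e-300, 1.0)


def tetrachoric(
    table: np.ndarray, zero_cell: str = "correct"
) -> float:
    """Two-step ML tetrachoric correlation from a 2x2 contingency table.

    ``table[i][j]`` counts observations with item1 = i, item2 = j.  Thresholds
    are fixed at the margin quantiles; the correlation maximizes the
    four-cell multinomial likelihood, bounded in [-0.999, 0.999].  A zero
    cell triggers a continuity correction of +0.5 to every cell
    (``zero_cell="correct"``, warned) or an error (``zero_cell="error"``).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a nonnegative 2x2 count matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: tetrachoric undefined")
    if np.any(t == 0):
        if zero_cell == "error":
            raise ValueError("zero cell in 2x2 table")
        warnings.warn("zero cell: +0.5 continuity correction applied", stacklevel=2)
        t = t + 0.5
    n = t.sum()
    tau1 = float(stats.norm.ppf(t[0].sum() / n))
    tau2 = float(stats.norm.ppf(t[:, 0].sum() / n))
    counts = np.array([t[0, 0], t[0, 1], t[1, 0], t[1, 1]])

    def nll(rho):
        return -float(counts @ np.log(_cell_probs(tau1, tau2, rho)))

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def _pair_avar(tau1: float, tau2: float, rho: float, n: float) -> float:
    """Asymptotic variance of the tetrachoric estimate, inverse observed
    Fisher information of the four-cell likelihood at the estimate."""
    # expected information: n * sum_c (d p_c / d rho)^2 / p_c
    h = 1e-4
    p_plus = _cell_probs(tau1, tau2, min(rho + h, _RHO_BOUND))
    p_minus = _cell_probs(tau1, tau2, max(rho - h, -_RHO_BOUND))
    p0 = _cell_probs(tau1, tau2, rho)
    dp = (p_plus - p_minus) / (2 * h)
    info = n * float(np.sum(dp**2 / p0))
    return 1.0 / max(info, 1e-12)


def tetrachoric_matrix(responses: np.ndarray, zero_cell: str = "correct"):
    """Tetrachoric correlation matrix and asymptotic variances of its entries.

    Returns ``(rho_matrix, avar_matrix)``; the diagonal of the correlation
    matrix is 1 and the corresponding avar entries are 0.
    """
    x = validate_responses(responses)
    n, i_dim = x.shape
    xf = x.astype(float)
    n11 = xf.T @ xf
    ones = x.sum(axis=0).astype(float)
    rho = np.eye(i_dim)
    avar = np.zeros((i_dim, i_dim))
    tau = stats.norm.ppf(1.0 - ones / n)
    for i in range(i_dim):
        for j in range(i + 1, i_dim):
            c11 = n11[i, j]
            t = np.array(
                [
                    [n - ones[i] - ones[j] + c11, ones[j] - c11],
                    [ones[i] - c11, c11],
                ]
            )
            r = tetrachoric(t, zero_cell=zero_cell)
            rho[i, j] = rho[j, i] = r
            avar[i, j] = avar[j, i] = _pair_avar(float(tau[i]), float(tau[j]), r, n)
    return rho, avar


# ---------------------------------------------------------------------------
# Probit-metric loadings and the Green-Yang coefficient
# ---------------------------------------------------------------------------


def probit_loadings(
    polychoric: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
) -> np.ndarray:
    """One-factor loadings fitted to a tetrachoric/polychoric matrix.

    Unweighted least squares on off-diagonal elements by default; passing
    ``weights`` (e.g. inverse asymptotic variances of the tetrachorics)
    gives the diagonally weighted (DWLS) variant.  Loadings are sign-fixed
    so their sum is nonnegative and bounded inside (-1, 1).
    """
    r = np.asarray(polychoric, dtype=float)
    i_dim = r.shape[0]
    if r.ndim != 2 or r.shape[0] != r.shape[1] or i_dim < 3:
        raise ValueError("polychoric matrix must be square with I >= 3")
    off = ~np.eye(i_dim, dtype=bool)
    if weights is None:
        w = np.ones((i_dim, i_dim))
    else:
        w = np.asarray(weights, dtype=float)
    w = np.where(off, w, 0.0)

    def objective(lam):
        m = (r - np.outer(lam, lam)) * w
        return float(np.sum(m * (r - np.outer(lam, lam))))

    def gradient(lam):
        m = (r - np.outer(lam, lam)) * w
        return -4.0 * (m @ lam)

    from .sample_coefficients import _smc_start

    bound = np.sqrt(1.0 - 1e-3)
    lam0 = np.clip(_smc_start(r), -bound, bound)
    res = optimize.minimize(
        objective, lam0, jac=gradient, method="L-BFGS-B",
        bounds=[(-bound, bound)] * i_dim, options={"maxiter": max_iter},
    )
    if not res.success and res.status != 1:
        raise RuntimeError(f"probit loading fit failed: {res.message}")
    lam = res.x if res.x.sum() >= 0 else -res.x
    if np.allclose(lam, 0.0, atol=1e-6):
        warnings.warn("degenerate loadings: all near zero", stacklevel=2)
    return lam


def _implied_cov_sum(tau: np.ndarray, corr_fn) -> float:
    """Sum over (i, j) of Phi2(tau_i, tau_j; c_ij) - Phi(tau_i) Phi(tau_j)."""
    i_dim = tau.size
    phi = stats.norm.cdf(tau)
    total = 0.0
    for i in range(i_dim):
        for j in range(i, i_dim):
            c = corr_fn(i, j)
            term = bivariate_normal_cdf(tau[i], tau[j], c) - phi[i] * phi[j]
            total += term if i == j else 2.0 * term
    return total


def green_yang_reliability(solution: CategoricalFactorSolution) -> float:
    """Green-Yang categorical reliability of the sum score.

    Ratio of the model-implied true-score covariance of the sum (pairwise
    latent correlations lam_i lam_j, including the diagonal) to the
    model-implied total variance (tetrachoric correlations off the diagonal,
    1 on it).
    """
    tau = np.asarray(solution.thresholds, dtype=float)
    lam = np.asarray(solution.loadings, dtype=float)
    rho = np.asarray(solution.polychoric, dtype=float)
    if np.any(np.abs(lam) >= 1.0):
        raise ValueError("inadmissible solution: |loading| >= 1")
    num = _implied_cov_sum(tau, lambda i, j: float(lam[i] * lam[j]))
    den = _implied_cov_sum(tau, lambda i, j: 1.0 if i == j else float(rho[i, j]))
    if den <= 0:
        raise ValueError("nonpositive model-implied total variance")
    return float(np.clip(num / den, 0.0, 1.0))


def green_yang_from_responses(
    responses: np.ndarray,
    estimator: str = "uls",
    zero_cell: str = "correct",
) -> float:
    """Full Green-Yang pipeline: thresholds -> tetrachorics -> loadings -> GY.

    ``estimator="uls"`` (default) fits loadings by unweighted least squares;
    ``"dwls"`` weights each tetrachoric by its inverse asymptotic variance.
    """
    x = validate_responses(responses)
    tau = np.array([threshold(x[:, i]) for i in range(x.shape[1])])
    rho, avar = tetrachoric_matrix(x, zero_cell=zero_cell)
    if estimator == "uls":
        lam = probit_loadings(rho)
    elif estimator == "dwls":
        with np.errstate(divide="ignore"):
            w = np.where(avar > 0, 1.0 / avar, 0.0)
        lam = probit_loadings(rho, weights=w)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return green_yang_reliability(
        CategoricalFactorSolution(thresholds=tau, loadings=lam, polychoric=rho)
    )


def loading_from_discrimination(a: np.ndarray | float) -> np.ndarray | float:
    """Probit-metric loading lam = a / sqrt(1 + a^2) of a discrimination."""
    a = np.asarray(a, dtype=float)
    out = a / np.sqrt(1.0 + a**2)
    return out if out.ndim else float(out)


def threshold_from_parameters(a, b):
    """Threshold tau = a b / sqrt(1 + a^2) implied by probit 2PL parameters."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = a * b / np.sqrt(1.0 + a**2)
    return out if out.ndim else float(out)
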