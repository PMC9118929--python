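"""Classical reliability of the sum score from known 2PL item parameters.

Reliability of the number-correct score is the classical ratio

    rho = Var(T) / (Var(T) + Var(E))

with the variance components defined by integrals over the latent-trait
distribution: the error variance of item *i* is E_theta[P_i (1 - P_i)] and the
true-score variance is Var_theta[ sum_i P_i(theta) ].  Two computational
routes are provided:

* the *quadrature* route ("DQ"): rectangular quadrature of the integrals on a
  grid of equally spaced nodes with renormalized normal weights (101 nodes on
  [-6, 6] by default) — the package's definition of true reliability given
  item parameters;
* the *analytic* route ("DA"): Dimitrov's closed-form approximation built on
  a four-constant polynomial approximation to the error function, which is
  faster but mildly optimistic about reliability.

The analytic true-score variance treats item true scores as perfectly
correlated under unidimensionality: Var(T) = (sum_i sqrt(pi_i (1 - pi_i) -
Var(E_i)))^2, with negative bracketed terms (possible for extreme items under
the approximation) clipped to zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import ItemBank, QuadratureGrid, icc, make_grid

__all__ = [
    "VarianceDecomposition",
    "erf_approx",
    "marginal_prob_analytic",
    "marginal_prob_quadrature",
    "item_error_variance_analytic",
    "item_error_variance_quadrature",
    "true_score_variance_analytic",
    "true_score_variance_quadrature",
    "reliability_from_variances",
    "reliability_analytic",
    "reliability_quadrature",
]

# Abramowitz & Stegun style four-constant erf approximation.
_M1, _M2, _M3, _M4 = 0.278393, 0.230389, 0.000972, 0.078108


@dataclass(frozen=True)
class VarianceDecomposition:
    """True-score variance, error variance and the reliability ratio."""

    var_true: float
    var_error: float
    reliability: float

    def __post_init__(self) -> None:
        if self.var_true < 0 or self.var_error < 0:
            raise ValueError("variance components must be nonnegative")


def erf_approx(z: np.ndarray | float) -> np.ndarray | float:
    """Polynomial approximation of the error function, odd-extended to z < 0.

    erf(z) ~= 1 - (1 + m1 z + m2 z^2 + m3 z^3 + m4 z^4)^-4 for z >= 0; the
    maximum absolute error is below 5e-4 over the positive axis.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    x = np.abs(z)
    poly = 1.0 + x * (_M1 + x * (_M2 + x * (_M3 + x * _M4)))
    val = 1.0 - poly**-4
    out = np.sign(z) * val
    return out if out.ndim else float(out)


def _ab(bank_or_a, b=None):
    if isinstance(bank_or_a, ItemBank):
        return bank_or_a.a, bank_or_a.b
    return np.asarray(bank_or_a, dtype=float), np.asarray(b, dtype=float)


def marginal_prob_analytic(a, b=None) -> np.ndarray | float:
    """Marginal probability pi of a correct response, erf approximation.

    pi ~= [1 - erf(Z)] / 2 with Z = a b / sqrt(2 (1 + a^2)).
    """
    a, b = _ab(a, b)
    z = a * b / np.sqrt(2.0 * (1.0 + a**2))
    out = (1.0 - erf_approx(z)) / 2.0
    return out


def marginal_prob_quadrature(
    bank: ItemBank, grid: QuadratureGrid | None = None, link: str = "logistic"
) -> np.ndarray:
    """Marginal probability pi_i by rectangular quadrature over the trait."""
    grid = grid or make_grid()
    p = icc(grid.nodes[None, :], bank.a[:, None], bank.b[:, None], bank.D, link=link)
    return p @ grid.weights


def item_error_variance_analytic(a, b=None) -> np.ndarray | float:
    """Analytic approximation of the item error variance E[P(1-P)].

    Var(E_i) ~= m exp[-0.5 (b/d)^2] with m and d quadratic/rational
    polynomials in the discrimination a.
    """
    a, b = _ab(a, b)
    m = 0.2646 - 0.118 * a + 0.0187 * a**2
    d = 0.7427 + 0.7081 / a + 0.0074 / a**2
    if np.any(m <= 0):
        raise ValueError(
            "analytic error-variance polynomial m <= 0: discrimination outside "
            "the approximation's intended range"
        )
    return m * np.exp(-0.5 * (b / d) ** 2)


def item_error_variance_quadrature(
    bank: ItemBank, grid: QuadratureGrid | None = None, link: str = "logistic"
) -> np.ndarray:
    """Item error variances sum_q P(X_q)[1 - P(X_q)] W_q."""
    grid = grid or make_grid()
    p = icc(grid.nodes[None, :], bank.a[:, None], bank.b[:, None], bank.D, link=link)
    return (p * (1.0 - p)) @ grid.weights


def true_score_variance_analytic(bank: ItemBank) -> float:
    """Analytic true-score variance of the sum score.

    Item true-score variances pi_i(1-pi_i) - Var(E_i) are combined assuming
    perfectly correlated item true scores (unidimensionality):
    Var(T) = (sum_i sqrt(.))^2.  Negative bracketed values are clipped at 0.
    """
    pi = marginal_prob_analytic(bank.a, bank.b)
    var_e = item_error_variance_analytic(bank.a, bank.b)
    item_var_t = pi * (1.0 - pi) - var_e
    if np.any(item_var_t < 0):
        warnings.warn(
            "negative analytic item true-score variance clipped to 0 "
            f"({int((item_var_t < 0).sum())} item(s))",
            stacklevel=2,
        )
        item_var_t = np.clip(item_var_t, 0.0, None)
    return float(np.sqrt(item_var_t).sum() ** 2)


def true_score_variance_quadrature(
    bank: ItemBank, grid: QuadratureGrid | None = None, link: str = "logistic"
) -> float:
    """Quadrature true-score variance Var_theta[ sum_i P_i(theta) ]."""
    grid = grid or make_grid()
    p = icc(grid.nodes[None, :], bank.a[:, None], bank.b[:, None], bank.D, link=link)
    tcc = p.sum(axis=0)  # test characteristic curve at each node
    mean = tcc @ grid.weights
    return float(max((tcc**2) @ grid.weights - mean**2, 0.0))


def reliability_from_variances(var_true: float, var_error: float) -> float:
    """Classical reliability ratio Var(T) / (Var(T) + Var(E))."""
    if var_true < 0 or var_error < 0:
        raise ValueError("variance components must be nonnegative")
    total = var_true + var_error
    if total <= 0:
        raise ValueError("total variance is zero; reliability undefined")
    return var_true / total


def reliability_analytic(bank: ItemBank) -> VarianceDecomposition:
    """Analytic (DA) variance decomposition and reliability for a bank."""
    var_t = true_score_variance_analytic(bank)
    var_e = float(np.sum(item_error_variance_analytic(bank.a, bank.b)))
    return VarianceDecomposition(var_t, var_e, reliability_from_variances(var_t, var_e))


def reliability_quadrature(
    bank: ItemBank, grid: QuadratureGrid | None = None, link: str = "logistic"
) -> VarianceDecomposition:
    """Quadrature (DQ) variance decomposition and reliability for a bank.

    This is the package's reference definition of "true" reliability given
    item parameters.
    """
    grid = grid or make_grid()
    var_t = true_score_variance_quadrature(bank, grid, link=link)
    var_e = float(np.sum(item_error_variance_quadrature(bank, grid, link=link)))
    return VarianceDecomposition(var_t, var_e, reliability_from_variances(var_t, var_e))
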