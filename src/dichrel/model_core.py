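"""Two-parameter logistic (2PL) item response model and simulation primitives.

The 2PL gives the probability of a correct (``1``) response to item *i* as

    P_i(theta) = logistic(D * a_i * (theta - b_i))

with discrimination ``a_i > 0``, difficulty ``b_i`` on the latent-trait scale,
and a scaling constant ``D`` (1.702 by default) that aligns the logistic curve
with the normal-ogive metric.  Everything downstream — population reliability,
marginal-ML estimation, the Monte Carlo studies — consumes the types defined
here: an :class:`ItemBank` of (a, b, D), a :class:`QuadratureGrid` for
latent-trait integrals, and plain ``numpy`` arrays for traits and responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "DEFAULT_D",
    "ItemBank",
    "QuadratureGrid",
    "icc",
    "make_grid",
    "sample_item_parameters",
    "sample_theta",
    "simulate_responses",
    "sum_score",
    "validate_responses",
]

#: Scaling constant aligning the logistic and normal-ogive item metrics.
DEFAULT_D = 1.702


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of 2PL item parameters sharing one scaling constant.

    Parameters
    ----------
    a : array of discriminations, all strictly positive ("normal metric",
        used jointly with ``D``).
    b : array of difficulties, latent-trait units, finite.
    D : scaling constant, shared across items (default 1.702).
    """

    a: np.ndarray
    b: np.ndarray
    D: float = DEFAULT_D

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if a.shape != b.shape or a.ndim != 1 or a.size < 1:
            raise ValueError("a and b must be 1-D arrays of equal, positive length")
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(b)):
            raise ValueError("item parameters must be finite")
        if np.any(a <= 0):
            raise ValueError("all discriminations a must be > 0")
        if not self.D > 0:
            raise ValueError("scaling constant D must be > 0")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n_items(self) -> int:
        return self.a.size

    def __len__(self) -> int:
        return self.n_items


@dataclass(frozen=True)
class QuadratureGrid:
    """Rectangular quadrature nodes with normalized normal-density weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2 or nodes.shape != weights.shape:
            raise ValueError("grid needs >= 2 nodes with matching weights")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


def make_grid(n_nodes: int = 101, lo: float = -6.0, hi: float = 6.0) -> QuadratureGrid:
    """Equally spaced latent-trait grid with renormalized N(0,1) weights.

    The default (101 nodes on [-6, 6]) is the grid used throughout for the
    quadrature-based reliability integrals.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 quadrature nodes")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    nodes = np.linspace(lo, hi, n_nodes)
    dens = stats.norm.pdf(nodes)
    return QuadratureGrid(nodes=nodes, weights=dens / dens.sum())


def icc(
    theta: np.ndarray | float,
    a: np.ndarray | float,
    b: np.ndarray | float,
    D: float = DEFAULT_D,
    link: str = "logistic",
) -> np.ndarray:
    """Item characteristic curve: P(correct | theta) under the 2PL.

    ``link="probit"`` evaluates the normal-ogive variant Phi(a (theta - b))
    (``D`` is ignored), used for cross-checks against categorical factor
    models that assume a probit link.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    z = np.asarray(a, dtype=float) * (theta - np.asarray(b, dtype=float))
    if link == "logistic":
        return special.expit(D * z)
    if link == "probit":
        return stats.norm.cdf(z)
    raise ValueError(f"unknown link {link!r}")


def sample_item_parameters(
    n_items: int,
    rng: np.random.Generator | int | None = None,
    *,
    log_a_mean: float = -0.75,
    log_a_sd: float = 0.25,
    b_mean: float = 0.0,
    b_sd: float = 0.75,
    D: float = DEFAULT_D,
) -> ItemBank:
    """Draw an item bank, a ~ logN(-.75, .25^2), b ~ N(0, .75^2) by default.

    These distributions define the simulated test: moderately discriminating
    items (median a about 0.47) with difficulties concentrated near the
    population mean of the trait.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = _as_rng(rng)
    a = rng.lognormal(mean=log_a_mean, sigma=log_a_sd, size=n_items)
    b = rng.normal(loc=b_mean, scale=b_sd, size=n_items)
    return ItemBank(a=a, b=b, D=D)


def sample_theta(
    n: int,
    correlation: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Standard-normal latent traits; bivariate with the given correlation.

    Returns shape ``(n,)`` when ``correlation`` is None, else ``(n, 2)`` with
    unit variances and the requested population correlation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _as_rng(rng)
    if correlation is None:
        return rng.standard_normal(n)
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    z = rng.standard_normal((n, 2))
    # Cholesky factor of [[1, r], [r, 1]]
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = correlation * z[:, 0] + np.sqrt(1.0 - correlation**2) * z[:, 1]
    return out


def simulate_responses(
    theta: np.ndarray,
    bank: ItemBank,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate an N x I binary response matrix from the 2PL.

    Entry (n, i) is 1 with probability ``icc(theta_n, a_i, b_i, D)``,
    independently across persons and items (inverse-uniform draws).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1:
        raise ValueError("theta must be one column; simulate each construct separately")
    rng = _as_rng(rng)
    prob = icc(theta[:, None], bank.a[None, :], bank.b[None, :], bank.D)
    return (rng.random(prob.shape) < prob).astype(np.int8)


def validate_responses(responses: np.ndarray) -> np.ndarray:
    """Check an N x I response matrix is binary and complete; return int array."""
    x = np.asarray(responses)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
        raise ValueError("responses must be a 2-D N x I matrix")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("responses must contain only 0/1 entries with no missing values")
    return x.astype(np.int8, copy=False)


def sum_score(responses: np.ndarray) -> np.ndarray:
    """Unweighted number-correct score per person, Y = sum_i Y_i."""
    x = validate_responses(responses)
    return x.sum(axis=1).astype(np.int64)
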