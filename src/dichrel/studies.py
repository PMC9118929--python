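"""Monte Carlo harnesses comparing reliability coefficients.

Two experiments are provided.

``run_study1`` — the disattenuation benchmark.  Two latent constructs with a
known correlation are each measured by a bank of 2PL items; the Pearson
correlation of the two sum scores is attenuated by measurement error.
Disattenuating it (r / sqrt(rho_xx rho_yy)) with reliabilities computed from
the *true* item parameters — analytically (DA) or by quadrature (DQ) —
measures how accurately each route computes reliability: the better the
reliability values, the closer the average corrected correlation sits to the
true latent correlation.  The design crosses true correlations
{.3, .5, .7, .9} with 10-70 items per construct in steps of 5, N = 500
persons per dataset.

``run_study2`` — the estimator comparison.  Datasets are simulated from the
2PL with freshly drawn item parameters; every coefficient in the roster is
computed per dataset and compared against that dataset's quadrature
reliability at the generating parameters (the reference "true" value).
Root mean square error and bias summarize each design cell.  The roster
covers DA at true parameters, DQ/DA at marginal-ML estimates, alpha, the
GLB, omega (minres on Pearson correlations), omega from a one-factor ML CFA,
and the Green-Yang categorical coefficient.

Default replication counts (1000/cell for the disattenuation benchmark,
200/cell for the estimator comparison) are deliberate scaled-down choices
that keep Monte Carlo standard errors small relative to the effects under
study; both are configurable.  Every cell draws its randomness from an
independent child of the root seed, so results do not depend on execution
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categorical_sem import green_yang_from_responses
from .irt_estimation import EstimationConfig, estimate_2pl
from .model_core import (
    DEFAULT_D,
    ItemBank,
    icc,
    make_grid,
    sample_item_parameters,
    sample_theta,
    simulate_responses,
)
from .population_reliability import (
    item_error_variance_analytic,
    marginal_prob_analytic,
    reliability_analytic,
    reliability_quadrature,
)
from .sample_coefficients import cronbach_alpha, glb_from_responses, omega_from_responses

__all__ = [
    "Study1Config",
    "Study2Config",
    "ALL_COEFFICIENTS",
    "disattenuate",
    "rmse",
    "bias",
    "run_study1",
    "run_study2",
]


def disattenuate(r_xy: float, rho_xx: float, rho_yy: float) -> float:
    """Correct a correlation for unreliability: r / sqrt(rho_xx rho_yy).

    Not clipped; corrected values above 1 are reported as-is.
    """
    if rho_xx <= 0 or rho_yy <= 0:
        raise ValueError("reliabilities must be positive")
    return float(r_xy / np.sqrt(rho_xx * rho_yy))


def rmse(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Root mean square error of estimates against per-dataset truths."""
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.size == 0 or e.shape != t.shape:
        raise ValueError("estimates and truths must be nonempty and aligned")
    return float(np.sqrt(np.mean((e - t) ** 2)))


def bias(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Mean signed error of estimates against per-dataset truths."""
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.size == 0 or e.shape != t.shape:
        raise ValueError("estimates and truths must be nonempty and aligned")
    return float(np.mean(e - t))


# ---------------------------------------------------------------------------
# Study 1: disattenuation benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Study1Config:
    """Design of the disattenuation benchmark."""

    correlations: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    items_per_construct: tuple[int, ...] = tuple(range(10, 75, 5))
    n_persons: int = 500
    n_reps: int = 1000
    seed: int = 0
    batch: int = 250  # replications simulated at once (memory/speed trade-off)


def _batch_reliabilities(a, b, grid):
    """DA and DQ reliabilities for a (B, I) batch of item banks."""
    pi = marginal_prob_analytic(a, b)
    ve = item_error_variance_analytic(a, b)
    s = np.sqrt(np.clip(pi * (1.0 - pi) - ve, 0.0, None))
    rel_a = s.sum(axis=1) ** 2 / (s.sum(axis=1) ** 2 + ve.sum(axis=1))
    p = icc(grid.nodes[None, None, :], a[:, :, None], b[:, :, None])
    tcc = p.sum(axis=1)  # (B, Q)
    var_t = (tcc**2) @ grid.weights - (tcc @ grid.weights) ** 2
    var_e = ((p * (1.0 - p)) @ grid.weights).sum(axis=1)
    return rel_a, var_t / (var_t + var_e)


def _study1_cell(
    true_r: float, n_items: int, cfg: Study1Config, rng: np.random.Generator
) -> dict:
    grid = make_grid()
    n = cfg.n_persons
    raw = np.empty(cfg.n_reps)
    da = np.empty(cfg.n_reps)
    dq = np.empty(cfg.n_reps)
    done = 0
    while done < cfg.n_reps:
        bsz = min(cfg.batch, cfg.n_reps - done)
        z = rng.standard_normal((bsz, n, 2))
        theta = np.empty_like(z)
        theta[:, :, 0] = z[:, :, 0]
        theta[:, :, 1] = true_r * z[:, :, 0] + np.sqrt(1 - true_r**2) * z[:, :, 1]
        scores = np.empty((bsz, n, 2))
        rels_a = np.empty((bsz, 2))
        rels_q = np.empty((bsz, 2))
        for col in (0, 1):
            a = rng.lognormal(-0.75, 0.25, size=(bsz, n_items))
            b = rng.normal(0.0, 0.75, size=(bsz, n_items))
            prob = icc(theta[:, :, col, None], a[:, None, :], b[:, None, :], DEFAULT_D)
            scores[:, :, col] = (rng.random(prob.shape) < prob).sum(axis=2)
            rels_a[:, col], rels_q[:, col] = _batch_reliabilities(a, b, grid)
        x = scores[:, :, 0]
        y = scores[:, :, 1]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r_xy = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        sl = slice(done, done + bsz)
        raw[sl] = r_xy
        da[sl] = r_xy / np.sqrt(rels_a[:, 0] * rels_a[:, 1])
        dq[sl] = r_xy / np.sqrt(rels_q[:, 0] * rels_q[:, 1])
        done += bsz
    rows = []
    for method, est in (("raw", raw), ("DA", da), ("DQ", dq)):
        rows.append(
            {
                "true_correlation": true_r,
                "items_per_construct": n_items,
                "n_persons": n,
                "method": method,
                "mean_estimate": float(est.mean()),
                "mc_se": float(est.std(ddof=1) / np.sqrt(cfg.n_reps)),
                "n_reps": cfg.n_reps,
            }
        )
    return rows


def run_study1(config: Study1Config | None = None) -> pd.DataFrame:
    """Run the disattenuation benchmark; one row per (cell, method).

    Columns: true_correlation, items_per_construct, n_persons, method
    (raw / DA / DQ), mean_estimate, mc_se, n_reps.
    """
    cfg = config or Study1Config()
    cells = [(r, i) for r in cfg.correlations for i in cfg.items_per_construct]
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cells))
    rows: list[dict] = []
    for (true_r, n_items), ss in zip(cells, streams):
        rows.extend(_study1_cell(true_r, n_items, cfg, np.random.default_rng(ss)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Study 2: coefficient comparison
# ---------------------------------------------------------------------------

ALL_COEFFICIENTS = ("DATrue", "DQ", "DA", "alpha", "GLB", "omega", "CFA", "GY")


@dataclass(frozen=True)
class Study2Config:
    """Design of the coefficient-comparison experiment."""

    test_lengths: tuple[int, ...] = (15, 40, 65)
    sample_sizes: tuple[int, ...] = (100, 300, 500, 1000, 3000)
    n_reps: int = 200
    coefficients: tuple[str, ...] = ALL_COEFFICIENTS
    seed: int = 0
    estimation: EstimationConfig = field(default_factory=EstimationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(ALL_COEFFICIENTS)
        if unknown:
            raise ValueError(f"unknown coefficients: {sorted(unknown)}")


def _study2_dataset(
    n_items: int, n: int, cfg: Study2Config, rng: np.random.Generator, grid
) -> tuple[float, dict[str, float]]:
    bank = sample_item_parameters(n_items, rng)
    theta = sample_theta(n, rng=rng)
    resp = simulate_responses(theta, bank, rng)
    rho_true = reliability_quadrature(bank, grid).reliability
    wanted = cfg.coefficients
    out: dict[str, float] = {}
    fit_bank: ItemBank | None = None
    if "DQ" in wanted or "DA" in wanted:
        try:
            fit_bank = estimate_2pl(resp, cfg.estimation).bank
        except (RuntimeError, ValueError):
            fit_bank = None
    for name in wanted:
        try:
            if name == "DATrue":
                out[name] = reliability_analytic(bank).reliability
            elif name == "DQ":
                if fit_bank is None:
                    raise RuntimeError("2PL fit failed")
                out[name] = reliability_quadrature(fit_bank, grid).reliability
            elif name == "DA":
                if fit_bank is None:
                    raise RuntimeError("2PL fit failed")
                out[name] = reliability_analytic(fit_bank).reliability
            elif name == "alpha":
                out[name] = cronbach_alpha(resp)
            elif name == "GLB":
                out[name] = glb_from_responses(resp)
            elif name == "omega":
                out[name] = omega_from_responses(resp, method="minres")
            elif name == "CFA":
                out[name] = omega_from_responses(resp, method="cfa")
            elif name == "GY":
                out[name] = green_yang_from_responses(resp)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            out[name] = np.nan
    return rho_true, out


def run_study2(config: Study2Config | None = None) -> pd.DataFrame:
    """Run the coefficient comparison; tidy RMSE/bias table.

    One row per (test length, sample size, coefficient) with raw-scale and
    x100-scale RMSE and bias, Monte Carlo standard errors, and the number of
    failed (dropped) replications for that coefficient.
    """
    cfg = config or Study2Config()
    cells = [(i, n) for i in cfg.test_lengths for n in cfg.sample_sizes]
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cells))
    grid = make_grid()
    rows: list[dict] = []
    for (n_items, n), ss in zip(cells, streams):
        rng = np.random.default_rng(ss)
        truths = np.empty(cfg.n_reps)
        ests = {name: np.empty(cfg.n_reps) for name in cfg.coefficients}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(cfg.n_reps):
                rho_true, vals = _study2_dataset(n_items, n, cfg, rng, grid)
                truths[s] = rho_true
                for name in cfg.coefficients:
                    ests[name][s] = vals.get(name, np.nan)
        for name in cfg.coefficients:
            ok = np.isfinite(ests[name])
            n_failed = int((~ok).sum())
            e, t = ests[name][ok], truths[ok]
            if e.size == 0:
                continue
            err = e - t
            cell_rmse = rmse(e, t)
            cell_bias = bias(e, t)
            se_bias = float(err.std(ddof=1) / np.sqrt(err.size))
            # delta-method SE of the RMSE from the spread of squared errors
            se_rmse = float(
                (err**2).std(ddof=1) / np.sqrt(err.size) / (2.0 * cell_rmse)
                if cell_rmse > 0
                else 0.0
            )
            rows.append(
                {
                    "n_items": n_items,
                    "n_persons": n,
                    "coefficient": name,
                    "rmse": cell_rmse,
                    "bias": cell_bias,
                    "rmse_x100": 100.0 * cell_rmse,
                    "bias_x100": 100.0 * cell_bias,
                    "mc_se_rmse": se_rmse,
                    "mc_se_bias": se_bias,
                    "n_reps": int(err.size),
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame(rows)
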