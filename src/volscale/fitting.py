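"""Estimation of nonlinear scaling degrees from expression-vs-volume data.

Both estimators profile out a linear amplitude: for a trial nonlinear
degree the best-fitting amplitude has a closed form, so the search is a
bounded one-dimensional minimization seeded by a coarse grid.  Data are
normalized to the smallest-volume bin; the co-fitted amplitude absorbs
the arbitrariness of that reference, which makes the estimators
applicable to relative-scale (RPKM-like) measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dynamics import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingEstimate",
    "ExpressionTable",
    "fit_beta",
    "fit_alpha",
    "production_rate_proxy",
    "scaling_summary",
    "fit_trajectory_betas",
    "fit_trajectory_alphas",
]

#: fraction of the admissible interval treated as "at the bound"
_BOUND_TOL = 1e-6


@dataclass
class ScalingEstimate:
    """Fitted nonlinear degree for one gene.

    ``converged`` is False when the optimum pins at a bound or the
    likelihood is flat (degree indistinguishable from the linear
    limit); such estimates are excluded from summaries.
    """

    gene_id: str
    beta_hat: float | None = None
    alpha_hat: float | None = None
    C_hat: float | None = None
    residual_sse: float = np.nan
    converged: bool = False
    n_points: int = 0


@dataclass
class ExpressionTable:
    """Gene-by-volume-bin expression matrix with optional mRNA lifetimes."""

    gene_id: np.ndarray
    volumes: np.ndarray
    X: np.ndarray
    tau_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.tau_m is not None:
            self.tau_m = np.asarray(self.tau_m, dtype=float)
            if self.tau_m.shape != self.gene_id.shape:
                raise ValueError("tau_m must align with gene_id")
        if self.volumes.size < 3:
            raise ValueError("need at least 3 volume bins")
        if np.any(np.diff(self.volumes) <= 0):
            raise ValueError("volumes must be strictly increasing")
        if self.X.shape != (self.gene_id.size, self.volumes.size):
            raise ValueError("expression matrix must be genes x volume bins")
        if np.any(self.X < 0):
            raise ValueError("expression must be nonnegative")


def _check_xy(volumes, values, min_points):
    v = np.asarray(volumes, dtype=float)
    e = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.shape != e.shape:
        raise ValueError("volumes and expression must be 1-D arrays of equal length")
    if v.size < min_points:
        raise ValueError(f"need at least {min_points} points")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    if np.any(np.diff(v) <= 0):
        raise ValueError("volumes must be strictly increasing")
    if np.any(e < 0):
        raise ValueError("expression must be nonnegative")
    return v, e


def _profiled_minimize(sse, lo, hi, n_grid=61):
    """Coarse grid followed by bounded local refinement."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([sse(b) for b in grid])
    k = int(np.argmin(vals))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        sse, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-12}
    )
    best = float(res.x)
    # the grid edge may genuinely be the optimum
    if vals[k] < res.fun:
        best = float(grid[k])
    return best, float(min(res.fun, vals[k]))


def fit_beta(
    volumes: Sequence[float],
    expression: Sequence[float],
    *,
    gene_id: str = "",
    bounds: tuple[float, float] | None = None,
) -> ScalingEstimate:
    """Fit the mRNA nonlinear degree ``beta``.

    Normalizes both axes to the smallest-volume bin and least-squares
    fits ``A * V~ (1 + beta)/(1 + beta V~)`` with the amplitude ``A``
    profiled out.  Default bounds ``[-0.99 / V~_max, 10]`` keep the
    curve's denominator positive on the data range.  A fit pinned at a
    bound is flagged (``converged=False``), not errored.
    """
    v, e = _check_xy(volumes, expression, 3)
    if np.all(e == 0):
        raise ValueError("all-zero expression: nothing to fit")
    if e[0] == 0:
        raise ValueError("zero expression in the reference (smallest-volume) bin")
    V = v / v[0]
    m = e / e[0]
    lo, hi = bounds if bounds is not None else (-0.99 / V.max(), 10.0)

    def sse(beta: float) -> float:
        h = V * (1.0 + beta) / (1.0 + beta * V)
        denom = float(np.dot(h, h))
        if denom == 0.0:
            return float(np.dot(m, m))
        A = float(np.dot(m, h)) / denom
        resid = m - A * h
        return float(np.dot(resid, resid))

    beta_hat, best = _profiled_minimize(sse, lo, hi)
    h = V * (1.0 + beta_hat) / (1.0 + beta_hat * V)
    C_hat = float(np.dot(m, h) / np.dot(h, h))
    at_bound = (beta_hat - lo) < _BOUND_TOL * (hi - lo) or (hi - beta_hat) < _BOUND_TOL * (
        hi - lo
    )
    return ScalingEstimate(
        gene_id=gene_id,
        beta_hat=float(beta_hat),
        C_hat=C_hat,
        residual_sse=best,
        converged=not at_bound,
        n_points=int(v.size),
    )


def fit_alpha(
    volumes: Sequence[float],
    protein_levels: Sequence[float],
    *,
    gene_id: str = "",
    bounds: tuple[float, float] | None = None,
) -> ScalingEstimate:
    """Fit ``(C, alpha)`` of the protein curve ``dp~ = C ln(1 + alpha dV~)``.

    ``C`` is profiled out analytically.  When ``alpha * dV~`` stays so
    small that the curve is indistinguishable from a straight line the
    likelihood is a flat ridge (only the product ``C * alpha`` is
    identified); such fits are flagged unconverged while still
    reporting the ridge estimates.
    """
    v, e = _check_xy(volumes, protein_levels, 4)
    if e[0] == 0:
        raise ValueError("zero protein level in the reference bin")
    V = v / v[0]
    dV = V - 1.0
    dp = e / e[0] - 1.0
    dV_max = dV.max()
    lo, hi = bounds if bounds is not None else (-0.99 / dV_max, 20.0)

    def sse(alpha: float) -> float:
        if alpha == 0.0:
            alpha = 1e-12
        ln = np.log1p(alpha * dV)
        denom = float(np.dot(ln, ln))
        if denom == 0.0:
            return float(np.dot(dp, dp))
        C = float(np.dot(dp, ln)) / denom
        resid = dp - C * ln
        return float(np.dot(resid, resid))

    alpha_hat, best = _profiled_minimize(sse, lo, hi, n_grid=121)
    a_eval = alpha_hat if alpha_hat != 0.0 else 1e-12
    ln = np.log1p(a_eval * dV)
    C_hat = float(np.dot(dp, ln) / np.dot(ln, ln))
    at_bound = (alpha_hat - lo) < _BOUND_TOL * (hi - lo) or (hi - alpha_hat) < _BOUND_TOL * (
        hi - lo
    )
    ridge = abs(alpha_hat) * dV_max < 1e-4
    if ridge:
        logger.info("%s: alpha on the linear ridge; only C*alpha identified", gene_id)
    return ScalingEstimate(
        gene_id=gene_id,
        alpha_hat=float(alpha_hat),
        C_hat=C_hat,
        residual_sse=best,
        converged=not (at_bound or ridge),
        n_points=int(v.size),
    )


def production_rate_proxy(expression_at_smallest_volume, tau_m):
    """Steady-state inversion ``k = m / tau_m`` of the mRNA balance.

    Vectorized; genes with missing (NaN) lifetimes propagate NaN and
    should be skipped by the caller.
    """
    e = np.asarray(expression_at_smallest_volume, dtype=float)
    tau = np.asarray(tau_m, dtype=float)
    if np.any(tau[~np.isnan(tau)] <= 0):
        raise ValueError("tau_m must be positive")
    if np.any(e[~np.isnan(e)] < 0):
        raise ValueError("expression must be nonnegative")
    out = e / tau
    return out if out.ndim else float(out)


def scaling_summary(
    estimates: Sequence[ScalingEstimate],
    rates: Sequence[float],
    *,
    n_bins: int = 20,
    n_rate_bins: int = 5,
) -> dict:
    """Distributional summary of fitted degrees and their rate correlation.

    Returns median degree, a histogram, Pearson/Spearman correlations of
    the degree against the production-rate proxy (two-sided p-values),
    and binned medians.  Only converged estimates enter; fewer than 10
    is an error.  Zero variance in either variable flags the summary as
    degenerate instead of erroring.
    """
    rates = np.asarray(rates, dtype=float)
    if len(estimates) != rates.size:
        raise ValueError("one rate per estimate required")
    deg = np.array(
        [
            (est.beta_hat if est.beta_hat is not None else est.alpha_hat)
            for est in estimates
        ],
        dtype=float,
    )
    keep = np.array([est.converged for est in estimates]) & ~np.isnan(rates) & ~np.isnan(deg)
    deg, rates = deg[keep], rates[keep]
    if deg.size < 10:
        raise ValueError(f"too few converged estimates ({deg.size} < 10)")

    counts, edges = np.histogram(deg, bins=n_bins)
    summary: dict = {
        "n_converged": int(deg.size),
        "median_degree": float(np.median(deg)),
        "iqr_degree": float(np.subtract(*np.percentile(deg, [75, 25]))),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
        "degenerate_zero_variance": False,
    }
    if np.std(deg) == 0 or np.std(rates) == 0:
        summary["degenerate_zero_variance"] = True
        summary["pearson"] = None
        summary["spearman"] = None
        summary["binned_medians"] = None
        return summary

    pear = stats.pearsonr(deg, rates)
    spear = stats.spearmanr(deg, rates)
    summary["pearson"] = {"r": float(pear.statistic), "p": float(pear.pvalue)}
    summary["spearman"] = {"rho": float(spear.statistic), "p": float(spear.pvalue)}

    order = np.argsort(rates)
    chunks = np.array_split(order, n_rate_bins)
    summary["binned_medians"] = [
        {
            "rate_median": float(np.median(rates[idx])),
            "degree_median": float(np.median(deg[idx])),
            "n": int(idx.size),
        }
        for idx in chunks
        if idx.size
    ]
    return summary


def _subsample(T: int, n_points: int) -> np.ndarray:
    if T <= n_points:
        return np.arange(T)
    return np.unique(np.linspace(0, T - 1, n_points).astype(int))


def fit_trajectory_betas(
    traj: Trajectory, *, n_points: int = 25, genes: Sequence[str] | None = None
) -> list[ScalingEstimate]:
    """Fit ``beta`` for every gene of a (monotonically growing) trajectory."""
    idx = _subsample(traj.t.size, n_points)
    V = traj.V[idx]
    gene_ids = traj.genome.gene_id.astype(str)
    cols = (
        range(traj.genome.n_genes)
        if genes is None
        else [traj.genome.index_of(g) for g in genes]
    )
    return [
        fit_beta(V, traj.m[idx, j], gene_id=str(gene_ids[j])) for j in cols
    ]


def fit_trajectory_alphas(
    traj: Trajectory, *, n_points: int = 25, genes: Sequence[str] | None = None
) -> list[ScalingEstimate]:
    """Fit ``(C, alpha)`` for every protein of a growing trajectory."""
    idx = _subsample(traj.t.size, n_points)
    V = traj.V[idx]
    gene_ids = traj.genome.gene_id.astype(str)
    cols = (
        range(traj.genome.n_genes)
        if genes is None
        else [traj.genome.index_of(g) for g in genes]
    )
    return [
        fit_alpha(V, traj.p[idx, j], gene_id=str(gene_ids[j])) for j in cols
    ]


def estimates_frame(estimates: Sequence[ScalingEstimate]) -> pd.DataFrame:
    """Tabular view of a collection of estimates."""
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in estimates],
            "beta_hat": [e.beta_hat for e in estimates],
            "alpha_hat": [e.alpha_hat for e in estimates],
            "C_hat": [e.C_hat for e in estimates],
            "residual_sse": [e.residual_sse for e in estimates],
            "converged": [e.converged for e in estimates],
            "n_points": [e.n_points for e in estimates],
        }
    )
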