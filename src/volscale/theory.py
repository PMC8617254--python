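"""Closed-form predictions for volume scaling of expression levels.

In the limiting-RNAP regime, the production rate of a gene whose
Michaelis-Menten constant ``K_i`` deviates from the (mass-fraction
weighted) genome average ``K_avg`` is a nonlinear function of the RNAP
number.  The deviation is summarized by a single nonlinear degree per
gene: ``beta`` for mRNA and ``alpha`` for nondegradable protein.
Negative degrees mean superlinear scaling with volume (rising
concentration); positive degrees mean sublinear scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Genome, GlobalParams

__all__ = [
    "weighted_K",
    "predicted_beta",
    "predicted_alpha",
    "mrna_curve",
    "protein_curve",
    "special_gene_rate",
    "predict_scaling",
]


def weighted_K(genome_or_K, phi) -> float:
    """Mass-fraction weighted average Michaelis-Menten constant.

    Parameters
    ----------
    genome_or_K : Genome or array
        Either a :class:`Genome` (its ``K_n`` column is used) or a bare
        array of constants.
    phi : array
        Nonnegative weights summing to 1 within 1e-9 (protein mass
        fractions at the normalization origin).
    """
    K = genome_or_K.K_n if isinstance(genome_or_K, Genome) else np.asarray(genome_or_K, float)
    phi = np.asarray(phi, dtype=float)
    if K.shape != phi.shape:
        raise ValueError("weights and constants must have the same length")
    if np.any(phi < 0):
        raise ValueError("weights must be nonnegative")
    if abs(phi.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1 within 1e-9")
    return float(np.dot(phi, K))


def _check_nu(n0_over_nc) -> np.ndarray:
    nu = np.asarray(n0_over_nc, dtype=float)
    if np.any(nu <= 0) or np.any(nu >= 1):
        raise ValueError("n0_over_nc must lie strictly between 0 and 1")
    return nu


def predicted_beta(K_i, K_avg, n0_over_nc):
    """Nonlinear degree of mRNA scaling: ``-(K_i - K_avg) * nu / K_i``.

    ``nu = n(0)/n_c`` is the RNAP saturation at the normalization origin.
    Zero when ``K_i == K_avg``; negative (superlinear) for genes with
    below-average recruitment ability (``K_i > K_avg``).
    """
    K_i = np.asarray(K_i, dtype=float)
    K_avg = np.asarray(K_avg, dtype=float)
    if np.any(K_i <= 0) or np.any(K_avg <= 0):
        raise ValueError("Michaelis-Menten constants must be positive")
    nu = _check_nu(n0_over_nc)
    out = -(K_i - K_avg) * nu / K_i
    return out if out.ndim else float(out)


def predicted_alpha(K_i, K_avg, n0_over_nc):
    """Nonlinear degree of nondegradable protein scaling.

    ``alpha = -dK * nu / (K_i - dK * nu)`` with ``dK = K_i - K_avg``;
    same sign as ``beta`` and bounded below by -1.  The denominator is
    positive for any ``0 < nu < 1`` since it equals
    ``K_i (1 - nu) + K_avg nu``; a nonpositive denominator (possible
    only for out-of-range inputs) raises.
    """
    K_i = np.asarray(K_i, dtype=float)
    K_avg = np.asarray(K_avg, dtype=float)
    if np.any(K_i <= 0) or np.any(K_avg <= 0):
        raise ValueError("Michaelis-Menten constants must be positive")
    nu = _check_nu(n0_over_nc)
    dK = K_i - K_avg
    denom = K_i - dK * nu
    if np.any(denom <= 0):
        raise ValueError("alpha undefined: nonpositive denominator (theory outside validity)")
    out = -dK * nu / denom
    return out if out.ndim else float(out)


def mrna_curve(beta, V_rel):
    """Normalized mRNA level ``m~ = V~ (1 + beta) / (1 + beta V~)``.

    ``V_rel`` is the volume relative to the normalization origin.  The
    curve has a pole at ``V~ = -1/beta``; crossing it is an error.
    """
    beta = np.asarray(beta, dtype=float)
    V_rel = np.asarray(V_rel, dtype=float)
    denom = 1.0 + beta * V_rel
    if np.any(denom <= 0):
        raise ValueError("mrna_curve evaluated past its pole: 1 + beta*V_rel <= 0")
    out = V_rel * (1.0 + beta) / denom
    return out if out.ndim else float(out)


def protein_curve(C, alpha, dV_rel):
    """Normalized protein change ``dp~ = C ln(1 + alpha dV~)``.

    ``dV_rel = V~ - 1``.  Log-domain violations raise.
    """
    C = np.asarray(C, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    dV_rel = np.asarray(dV_rel, dtype=float)
    arg = alpha * dV_rel
    if np.any(1.0 + arg <= 0):
        raise ValueError("protein_curve log-domain violation: 1 + alpha*dV_rel <= 0")
    out = C * np.log1p(arg)
    return out if out.ndim else float(out)


def special_gene_rate(K_i, K_avg, n, n_c, Gamma_g):
    """Production rate of one gene deviating from a homogeneous background.

    ``k = Gamma_g * K_avg * n / (K_i n_c - (K_i - K_avg) n)`` where
    ``Gamma_g`` is the initiation rate times the gene copy number.
    Reduces to the homogeneous law ``Gamma_g * n / n_c`` when
    ``K_i == K_avg``.  Requires ``n < n_c`` and a positive denominator.
    """
    K_i = np.asarray(K_i, dtype=float)
    K_avg = np.asarray(K_avg, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(K_i <= 0) or np.any(K_avg <= 0):
        raise ValueError("Michaelis-Menten constants must be positive")
    if np.any(n >= n_c):
        raise ValueError("special_gene_rate requires n < n_c")
    denom = K_i * n_c - (K_i - K_avg) * n
    if np.any(denom <= 0):
        raise ValueError("special_gene_rate denominator <= 0 (theory breakdown near saturation)")
    out = np.asarray(Gamma_g, dtype=float) * K_avg * n / denom
    return out if out.ndim else float(out)


def predict_scaling(
    genome: Genome,
    phi: np.ndarray,
    n0_over_nc: float,
) -> pd.DataFrame:
    """Per-gene predicted nonlinear degrees for a genome.

    ``phi`` are the protein mass fractions at the normalization origin.
    Returns a frame with columns ``gene_id, K_n, beta_pred, alpha_pred``
    plus the scalar inputs ``K_avg`` and ``n0_over_nc`` as attributes.
    """
    K_avg = weighted_K(genome, phi)
    beta = predicted_beta(genome.K_n, K_avg, n0_over_nc)
    alpha = predicted_alpha(genome.K_n, K_avg, n0_over_nc)
    frame = pd.DataFrame(
        {
            "gene_id": genome.gene_id.astype(str),
            "K_n": genome.K_n,
            "beta_pred": beta,
            "alpha_pred": alpha,
        }
    )
    frame.attrs["K_avg"] = K_avg
    frame.attrs["n0_over_nc"] = float(n0_over_nc)
    return frame
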