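"""Instantaneous partitioning of RNA polymerases and ribosomes.

At any instant, the cell holds ``n`` RNAPs competing for promoter and
elongation slots on the genome, and ``r`` ribosomes competing for
initiation and elongation slots on the mRNA pool.  Each binding follows
a Michaelis-Menten law in the *free* machine concentration, which is
itself fixed by a scalar self-consistency equation: machines bound plus
machines free must equal the total.  This module solves those two scalar
equations and converts the resulting occupancies into per-gene mRNA and
protein production rates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .genome import GlobalParams, Genome

logger = logging.getLogger(__name__)

__all__ = [
    "CellState",
    "AllocationResult",
    "cell_geometry",
    "solve_free_rnap",
    "solve_free_ribosome",
    "production_rates",
]


@dataclass
class CellState:
    """Instantaneous copy numbers of all mRNA and protein species.

    Parameters
    ----------
    t : float
        Time in minutes.
    m : ndarray
        Per-gene mRNA copy numbers (nonnegative reals; the model is
        mean-field, so copy numbers need not be integers).
    p : ndarray
        Per-gene protein copy numbers.
    """

    t: float
    m: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.m.shape != self.p.shape or self.m.ndim != 1:
            raise ValueError("m and p must be 1-D arrays of equal length")
        if np.any(self.m < 0) or np.any(self.p < 0):
            raise ValueError("copy numbers must be nonnegative")


@dataclass
class AllocationResult:
    """Free fractions, occupancies and production rates at one instant.

    ``P_b`` is the per-gene promoter occupancy by RNAP; ``P_rbs`` the
    per-mRNA ribosome-binding-site occupancy.  ``phase1`` is True while
    the RNAP count is below the genome capacity ``n_c``.
    """

    F_n: float
    F_r: float
    c_n_free: float
    c_r_free: float
    P_b: np.ndarray
    P_rbs: np.ndarray
    k_n: np.ndarray
    k_r: np.ndarray
    phase1: bool


def cell_geometry(state: "CellState", genome: "Genome", globals_: "GlobalParams"):
    """Derive (M, V, V_n, V_c, n, r) from a cell state.

    Total protein mass ``M = sum_i p_i L_i`` (amino acids) sets the cell
    volume through the fixed density ``rho``; the nuclear volume is the
    fixed fraction ``1/a`` of the cell volume.  RNAP and ribosome counts
    are the protein copy numbers of their coarse-grained genes.
    """
    M = float(np.dot(state.p, genome.L))
    if M <= 0:
        raise ValueError("total protein mass must be positive")
    V = M / globals_.rho
    V_n = V / globals_.a
    V_c = V - V_n
    n = float(state.p[genome.i_rnap])
    r = float(state.p[genome.i_ribosome])
    return M, V, V_n, V_c, n, r


def _solve_free_fraction(
    total: float,
    slots: np.ndarray,
    K: np.ndarray,
    c_total: float,
    guess: float | None = None,
    rtol: float = 1e-13,
    max_iter: int = 200,
) -> float:
    """Solve ``sum_i slots_i * cF/(cF + K_i) = total * (1 - F)`` for F in [0, 1].

    The left side (number of machines sequestered at binding sites plus
    elongating) is strictly increasing in F, while the right side
    (total minus free) is strictly decreasing, so a root in (0, 1) exists
    and is unique whenever ``total > 0`` and ``sum(slots) > 0``:
    at F=0 the left side is 0 < total, at F=1 the right side is 0 while
    the left side is positive.  A safeguarded Newton iteration on the
    residual keeps a bracket at all times, so convergence is guaranteed.
    """
    if total <= 0:
        return 0.0
    slots = np.asarray(slots, dtype=float)
    K = np.asarray(K, dtype=float)
    s_sum = float(slots.sum())
    if s_sum <= 0:
        # nothing to bind: every machine is free
        return 1.0
    c = float(c_total)
    if c <= 0:
        raise ValueError("total machine concentration must be positive")

    # starting point: exact solution of the homogeneous-K quadratic with the
    # slot-weighted mean constant  c*T*F^2 + (c*(S-T) + K*T)*F - K*T = 0
    if guess is not None and 0.0 < guess < 1.0:
        F = float(guess)
    else:
        K_eff = float(np.dot(slots, K) / s_sum)
        a2 = c * total
        b2 = c * (s_sum - total) + K_eff * total
        c2 = -K_eff * total
        F = (-b2 + math.sqrt(b2 * b2 - 4.0 * a2 * c2)) / (2.0 * a2)
        F = min(max(F, 1e-300), 1.0 - 1e-16)

    lo, hi = 0.0, 1.0
    stalled = 0
    for _ in range(max_iter):
        cF = c * F
        denom = cF + K
        bound = float(np.dot(slots, cF / denom))
        g = bound - total * (1.0 - F)
        # the residual has no internal cancellation beyond ~eps*total, so a
        # residual-based stop guarantees the bookkeeping closure downstream
        if abs(g) <= 1e-13 * total:
            return F
        if g > 0.0:
            hi = F
        else:
            lo = F
        dg = float(np.dot(slots, c * K / (denom * denom))) + total
        F_new = F - g / dg
        if not (lo < F_new < hi):
            F_new = 0.5 * (lo + hi)
        if abs(F_new - F) <= rtol * max(abs(F_new), 1e-300):
            stalled += 1
            if stalled >= 3:
                return F_new
        else:
            stalled = 0
        F = F_new
        if hi - lo <= 1e-18:
            break
    return F


def solve_free_rnap(
    state: "CellState",
    genome: "Genome",
    globals_: "GlobalParams",
    guess: float | None = None,
) -> tuple[float, float]:
    """Fraction and concentration of free RNAPs in the nucleus.

    Solves the self-consistency ``n (1 - F_n) = sum_i g_i (1 + Lambda_n_i)
    * c_n F_n / (c_n F_n + K_n_i)`` where ``Lambda_n_i = Gamma_n_i L_i / v_n``
    is the elongation capacity of one gene copy.  Returns ``(F_n, c_n_free)``.
    With ``n == 0`` the fraction is undefined; by convention ``(0.0, 0.0)``
    is returned with a warning.
    """
    _, _, V_n, _, n, _ = cell_geometry(state, genome, globals_)
    if n <= 0:
        warnings.warn("no RNAPs present: free fraction undefined, returning 0")
        return 0.0, 0.0
    if V_n <= 0:
        raise ValueError("nuclear volume must be positive")
    lam = genome.Gamma_n * genome.L / globals_.v_n
    slots = genome.g * (1.0 + lam)
    c_n = n / V_n
    F_n = _solve_free_fraction(n, slots, genome.K_n, c_n, guess=guess)
    return F_n, c_n * F_n


def solve_free_ribosome(
    state: "CellState",
    genome: "Genome",
    globals_: "GlobalParams",
    guess: float | None = None,
) -> tuple[float, float]:
    """Fraction and concentration of free ribosomes in the cytoplasm.

    Mirror image of :func:`solve_free_rnap` with mRNA-borne slots
    ``m_i (1 + Lambda_r_i)``, ``Lambda_r_i = Gamma_r_i L_i / v_r``.
    With no mRNA present all ribosomes are free (``F_r = 1``).
    """
    _, _, _, V_c, _, r = cell_geometry(state, genome, globals_)
    if r <= 0:
        warnings.warn("no ribosomes present: free fraction undefined, returning 0")
        return 0.0, 0.0
    if V_c <= 0:
        raise ValueError("cytoplasmic volume must be positive")
    m = np.maximum(state.m, 0.0)
    lam = genome.Gamma_r * genome.L / globals_.v_r
    slots = m * (1.0 + lam)
    c_r = r / V_c
    F_r = _solve_free_fraction(r, slots, genome.K_r, c_r, guess=guess)
    return F_r, c_r * F_r


def production_rates(
    state: "CellState",
    genome: "Genome",
    globals_: "GlobalParams",
    guess_F_n: float | None = None,
    guess_F_r: float | None = None,
) -> AllocationResult:
    """Per-gene mRNA and protein production rates at one instant.

    Runs both free-fraction solves and evaluates

    * ``k_n_i = Gamma_n_i g_i P_b_i`` with ``P_b_i = c_n_free/(c_n_free + K_n_i)``
    * ``k_r_i = Gamma_r_i m_i P_rbs_i`` with ``P_rbs_i = c_r_free/(c_r_free + K_r_i)``
    """
    F_n, c_n_free = solve_free_rnap(state, genome, globals_, guess=guess_F_n)
    F_r, c_r_free = solve_free_ribosome(state, genome, globals_, guess=guess_F_r)

    if c_n_free > 0:
        P_b = c_n_free / (c_n_free + genome.K_n)
    else:
        P_b = np.zeros(genome.n_genes)
    if c_r_free > 0:
        P_rbs = c_r_free / (c_r_free + genome.K_r)
    else:
        P_rbs = np.zeros(genome.n_genes)

    k_n = genome.Gamma_n * genome.g * P_b
    k_r = genome.Gamma_r * np.maximum(state.m, 0.0) * P_rbs

    lam_n = genome.Gamma_n * genome.L / globals_.v_n
    n_c = float(np.dot(genome.g, 1.0 + lam_n))
    n = float(state.p[genome.i_rnap])
    phase1 = n < n_c
    if not phase1:
        logger.warning(
            "RNAP number %.3g has reached the genome capacity n_c=%.3g "
            "(leaving phase 1)", n, n_c,
        )
    return AllocationResult(
        F_n=F_n,
        F_r=F_r,
        c_n_free=c_n_free,
        c_r_free=c_r_free,
        P_b=np.asarray(P_b, dtype=float),
        P_rbs=np.asarray(P_rbs, dtype=float),
        k_n=np.asarray(k_n, dtype=float),
        k_r=np.asarray(k_r, dtype=float),
        phase1=phase1,
    )
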