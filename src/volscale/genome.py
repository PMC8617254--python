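"""Parameter data model, synthetic genome generation, and calibration.

A *genome* here is a table of per-gene constants: gene length, copy
number, the Michaelis-Menten constants controlling RNAP and ribosome
recruitment, initiation rates, and mRNA/protein lifetimes.  Two genes
play distinguished roles: the coarse-grained RNAP gene and the
coarse-grained ribosome gene, whose protein copy numbers are the
machine counts that every other gene competes for.

Units used throughout the package: minutes, cubic micrometres, and
codon/amino-acid counts; concentrations are molecules per um^3 and
elongation speeds codons per minute.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .allocation import _solve_free_fraction

__all__ = [
    "ROLE_RNAP",
    "ROLE_RIBOSOME",
    "ROLE_GENERIC",
    "RNAP_PER_RIBOSOME",
    "GeneParams",
    "GlobalParams",
    "Genome",
    "CalibrationResult",
    "make_genome",
    "calibrate",
    "nc_of",
]

ROLE_RNAP = "rnap"
ROLE_RIBOSOME = "ribosome"
ROLE_GENERIC = "generic"
ROLES = (ROLE_RNAP, ROLE_RIBOSOME, ROLE_GENERIC)

#: attempted RNAP copy number per ribosome copy, fixed by the calibration
RNAP_PER_RIBOSOME = 0.1


def _lognormal_mu_sigma(mean: float, cv: float) -> tuple[float, float]:
    """Parameters of the underlying normal for a lognormal with a given
    *arithmetic* mean and coefficient of variation."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if cv < 0:
        raise ValueError("coefficient of variation must be nonnegative")
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def draw_lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with arithmetic mean ``mean`` and CV ``cv``.

    ``cv == 0`` degenerates to a constant.
    """
    if cv == 0:
        return np.full(size, float(mean))
    mu, sigma = _lognormal_mu_sigma(mean, cv)
    return rng.lognormal(mu, sigma, size)


@dataclass(frozen=True)
class GlobalParams:
    """Cell-level constants.

    Attributes
    ----------
    v_n, v_r : float
        RNAP and ribosome elongation speeds, codons/min.
    rho : float
        Protein mass per unit cell volume, amino acids per um^3.  The
        default is deliberately large so that the total RNAP
        concentration greatly exceeds the default Michaelis-Menten
        constant (6e3 per um^3): the limiting-machinery regime the model
        describes requires ``c_n >> K_n``.
    a : float
        Ratio of cell volume to nuclear volume (> 1).
    mu0 : float
        Attempted growth rate, 1/min.
    M_b : float
        Attempted initial total protein mass, amino acids.
    n_c_target : float
        Attempted genome-wide RNAP capacity ``sum_i g_i (1 + Lambda_n_i)``.
    """

    v_n: float = 2400.0
    v_r: float = 600.0
    rho: float = 5.0e11
    a: float = 10.0
    mu0: float = 0.006
    M_b: float = 1.0e9
    n_c_target: float = 1.0e4

    def __post_init__(self) -> None:
        for name in ("v_n", "v_r", "rho", "a", "mu0", "M_b", "n_c_target"):
            if not getattr(self, name) > 0:
                raise ValueError(f"GlobalParams.{name} must be strictly positive")
        if not self.a > 1:
            raise ValueError("GlobalParams.a must exceed 1 (nucleus inside the cell)")


@dataclass(frozen=True)
class GeneParams:
    """Constants of a single gene.

    ``tau_p`` may be ``inf`` for nondegradable proteins.  Initiation
    rates may be zero (a silent gene); every other parameter is strictly
    positive.
    """

    gene_id: str
    L: int
    g: int
    K_n: float
    K_r: float
    Gamma_n: float
    Gamma_r: float
    tau_m: float
    tau_p: float
    role: str = ROLE_GENERIC

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        for name in ("L", "g", "K_n", "K_r", "tau_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{self.gene_id}: {name} must be strictly positive")
        if not self.tau_p > 0:  # inf passes
            raise ValueError(f"{self.gene_id}: tau_p must be positive or infinite")
        if self.Gamma_n < 0 or self.Gamma_r < 0:
            raise ValueError(f"{self.gene_id}: initiation rates must be nonnegative")


_ARRAY_FIELDS = ("L", "g", "K_n", "K_r", "Gamma_n", "Gamma_r", "tau_m", "tau_p")


@dataclass
class Genome:
    """Array-backed collection of :class:`GeneParams`.

    Exactly one gene has role ``rnap`` and exactly one has role
    ``ribosome``.  ``gamma_mult`` optionally carries per-gene
    transcription-initiation multipliers (unit mean) that the
    calibration applies to generic genes; it models heterogeneity in
    initiation rates.
    """

    gene_id: np.ndarray
    role: np.ndarray
    L: np.ndarray
    g: np.ndarray
    K_n: np.ndarray
    K_r: np.ndarray
    Gamma_n: np.ndarray
    Gamma_r: np.ndarray
    tau_m: np.ndarray
    tau_p: np.ndarray
    gamma_mult: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        self.L = np.asarray(self.L, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        for name in ("K_n", "K_r", "Gamma_n", "Gamma_r", "tau_m", "tau_p"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.gamma_mult is not None:
            self.gamma_mult = np.asarray(self.gamma_mult, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.gene_id.size

    @property
    def i_rnap(self) -> int:
        return int(np.flatnonzero(self.role == ROLE_RNAP)[0])

    @property
    def i_ribosome(self) -> int:
        return int(np.flatnonzero(self.role == ROLE_RIBOSOME)[0])

    @property
    def is_generic(self) -> np.ndarray:
        return self.role == ROLE_GENERIC

    def index_of(self, gene_id: str) -> int:
        hits = np.flatnonzero(self.gene_id == gene_id)
        if hits.size == 0:
            raise KeyError(f"unknown gene id {gene_id!r}")
        return int(hits[0])

    def lambda_n(self, globals_: GlobalParams) -> np.ndarray:
        """Maximum number of elongating RNAPs per gene copy."""
        return self.Gamma_n * self.L / globals_.v_n

    def lambda_r(self, globals_: GlobalParams) -> np.ndarray:
        """Maximum number of elongating ribosomes per mRNA."""
        return self.Gamma_r * self.L / globals_.v_r

    def validate(self) -> None:
        shapes = {getattr(self, f).shape for f in _ARRAY_FIELDS}
        shapes.add(self.gene_id.shape)
        shapes.add(self.role.shape)
        if len(shapes) != 1:
            raise ValueError("all genome columns must have the same length")
        if np.unique(self.gene_id).size != self.n_genes:
            raise ValueError("gene ids must be unique")
        for r in np.unique(self.role):
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r}")
        if int(np.sum(self.role == ROLE_RNAP)) != 1:
            raise ValueError("exactly one gene must have role 'rnap'")
        if int(np.sum(self.role == ROLE_RIBOSOME)) != 1:
            raise ValueError("exactly one gene must have role 'ribosome'")
        for name in ("L", "g", "K_n", "K_r", "tau_m"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive for every gene")
        if np.any(self.tau_p <= 0):
            raise ValueError("tau_p must be positive (or infinite) for every gene")
        if np.any(self.Gamma_n < 0) or np.any(self.Gamma_r < 0):
            raise ValueError("initiation rates must be nonnegative")
        if self.gamma_mult is not None and np.any(self.gamma_mult <= 0):
            raise ValueError("gamma_mult entries must be strictly positive")

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_genes(cls, genes: Iterable[GeneParams]) -> "Genome":
        genes = list(genes)
        return cls(
            gene_id=np.array([g.gene_id for g in genes], dtype=object),
            role=np.array([g.role for g in genes], dtype=object),
            L=np.array([g.L for g in genes], dtype=float),
            g=np.array([g.g for g in genes], dtype=float),
            K_n=np.array([g.K_n for g in genes], dtype=float),
            K_r=np.array([g.K_r for g in genes], dtype=float),
            Gamma_n=np.array([g.Gamma_n for g in genes], dtype=float),
            Gamma_r=np.array([g.Gamma_r for g in genes], dtype=float),
            tau_m=np.array([g.tau_m for g in genes], dtype=float),
            tau_p=np.array([g.tau_p for g in genes], dtype=float),
        )

    def genes(self) -> list[GeneParams]:
        return [
            GeneParams(
                gene_id=str(self.gene_id[i]),
                L=int(self.L[i]),
                g=int(self.g[i]),
                K_n=float(self.K_n[i]),
                K_r=float(self.K_r[i]),
                Gamma_n=float(self.Gamma_n[i]),
                Gamma_r=float(self.Gamma_r[i]),
                tau_m=float(self.tau_m[i]),
                tau_p=float(self.tau_p[i]),
                role=str(self.role[i]),
            )
            for i in range(self.n_genes)
        ]

    def replace(self, **columns: np.ndarray) -> "Genome":
        """Return a copy with some columns substituted."""
        kwargs = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        kwargs.update(columns)
        return Genome(**kwargs)


@dataclass
class CalibrationResult:
    """Output of :func:`calibrate`.

    ``genome`` carries the calibrated transcription-initiation rates;
    ``m0``/``p0`` are the initial copy numbers consistent with the
    attempted machine provisioning, and ``M0_actual`` the (slightly
    shifted) initial protein mass such that the actual RNAP mass
    fraction times the actual mass equals the attempted product.
    """

    genome: Genome
    phi_r: float
    phi_n: float
    Gamma_n_r: float
    y: float
    x: float
    m0: np.ndarray
    p0: np.ndarray
    M0_actual: float
    n_c: float


def make_genome(
    n_genes: int,
    K_mean: float = 6.0e3,
    K_cv: float = 0.5,
    lifetime_mean: float = 10.0,
    lifetime_cv: float = 1.0,
    special_overrides: Mapping[str, float] | None = None,
    gamma_cv: float = 0.0,
    n_degradable: int = 0,
    tau_p_deg: float = 10.0,
    seed: int | None = None,
    *,
    L_mean: float = 500.0,
    L_cv: float = 0.3,
    L_rnap: int = 5000,
    L_ribosome: int = 10000,
    g_ribosome: int = 5,
    K_r: float = 6.0e3,
    Gamma_r: float = 10.0,
) -> Genome:
    """Generate a synthetic genome with heterogeneous recruitment abilities.

    The first two genes are the coarse-grained RNAP gene (copy number 1)
    and ribosome gene (copy number ``g_ribosome``, default 5); the
    remaining ``n_genes - 2`` genes are generic, with single copies and
    lognormal lengths.  Generic ``K_n`` values are drawn from a
    lognormal with arithmetic mean ``K_mean`` and CV ``K_cv``; the RNAP
    and ribosome genes receive the weighted average of the generic
    draws, where the weights are the calibration proxy for initial
    protein mass fractions (``g * tau_m * L / K_n``), so that the two
    machine genes scale linearly with volume by construction.

    ``special_overrides`` maps generic gene ids to multipliers ``x`` that
    pin ``K_n = x * K_mean`` exactly (overriding the machine genes is
    rejected: their linear scaling is a model assumption).  If
    ``gamma_cv > 0``, unit-mean lognormal multipliers for the generic
    transcription-initiation rates are drawn and stored; they are
    applied during calibration.  ``n_degradable`` generic genes, chosen
    at random, receive a finite protein lifetime ``tau_p_deg``.

    A fixed ``seed`` gives bit-identical output.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes (rnap, ribosome, one generic)")
    if seed is None:
        raise ValueError("a seed is required for reproducible genome generation")
    for name, value in (
        ("K_mean", K_mean), ("lifetime_mean", lifetime_mean), ("L_mean", L_mean),
        ("tau_p_deg", tau_p_deg), ("K_r", K_r),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive")
    for name, value in (("K_cv", K_cv), ("lifetime_cv", lifetime_cv), ("gamma_cv", gamma_cv)):
        if value < 0:
            raise ValueError(f"{name} must be nonnegative")
    if Gamma_r < 0:
        raise ValueError("Gamma_r must be nonnegative")
    n_generic = n_genes - 2
    if not 0 <= n_degradable <= n_generic:
        raise ValueError("n_degradable must be between 0 and the number of generic genes")

    ss = np.random.SeedSequence(seed)
    rng_K, rng_tau, rng_L, rng_gamma, rng_deg = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    gene_id = np.array(
        ["rnap", "ribosome"] + [f"g{i:04d}" for i in range(n_generic)], dtype=object
    )
    role = np.array([ROLE_RNAP, ROLE_RIBOSOME] + [ROLE_GENERIC] * n_generic, dtype=object)
    L = np.empty(n_genes)
    L[0] = L_rnap
    L[1] = L_ribosome
    L[2:] = np.maximum(1, np.rint(draw_lognormal(rng_L, L_mean, L_cv, n_generic)))
    g = np.ones(n_genes)
    g[1] = g_ribosome

    K_n = np.empty(n_genes)
    K_n[2:] = draw_lognormal(rng_K, K_mean, K_cv, n_generic)
    tau_m = draw_lognormal(rng_tau, lifetime_mean, lifetime_cv, n_genes)

    if special_overrides:
        for gid, mult in special_overrides.items():
            if gid in ("rnap", "ribosome"):
                raise ValueError(
                    "cannot override the RNAP or ribosome gene: their linear "
                    "scaling is a model assumption"
                )
            if not mult > 0:
                raise ValueError(f"override multiplier for {gid!r} must be positive")
            idx = np.flatnonzero(gene_id == gid)
            if idx.size == 0:
                raise KeyError(f"unknown gene id {gid!r} in special_overrides")
            K_n[int(idx[0])] = mult * K_mean

    # machine genes sit at the weighted average of the generic pool
    w = g[2:] * tau_m[2:] * L[2:] / K_n[2:]
    K_machine = float(np.dot(w, K_n[2:]) / w.sum())
    K_n[0] = K_n[1] = K_machine

    tau_p = np.full(n_genes, np.inf)
    if n_degradable > 0:
        deg = rng_deg.choice(n_generic, size=n_degradable, replace=False)
        tau_p[2 + deg] = tau_p_deg

    gamma_mult = None
    if gamma_cv > 0:
        gamma_mult = np.ones(n_genes)
        gamma_mult[2:] = draw_lognormal(rng_gamma, 1.0, gamma_cv, n_generic)

    return Genome(
        gene_id=gene_id,
        role=role,
        L=L,
        g=g,
        K_n=K_n,
        K_r=np.full(n_genes, float(K_r)),
        Gamma_n=np.ones(n_genes),  # placeholder; calibrate() sets these
        Gamma_r=np.full(n_genes, float(Gamma_r)),
        tau_m=tau_m,
        tau_p=tau_p,
        gamma_mult=gamma_mult,
    )


def nc_of(genome: Genome, globals_: GlobalParams) -> float:
    """Genome-wide RNAP capacity ``sum_i g_i (1 + Gamma_n_i L_i / v_n)``."""
    return float(np.dot(genome.g, 1.0 + genome.lambda_n(globals_)))


def calibrate(genome: Genome, globals_: GlobalParams) -> CalibrationResult:
    """Fix initiation rates and initial conditions for a genome.

    The attempted ribosome mass fraction is ``phi_r = mu0 * L_r / v_r``
    (every ribosome assumed translating at speed ``v_r``), and the
    attempted RNAP mass fraction provisions one RNAP per ten ribosomes:
    ``phi_n = 0.1 phi_r L_n / L_r``.  Transcription-initiation rates are
    then solved in the weak-binding limit (``c_n F_n << K_n_i``) so that

    * the ratio of RNAP-gene to ribosome-gene mRNA mass reproduces
      ``phi_n / phi_r``  (fixes ``y = Gamma_n_rnap / Gamma_n_ribosome``),
    * the ribosome gene's share of mRNA mass is ``phi_r``  (fixes
      ``x = Gamma_n_generic / Gamma_n_ribosome``), and
    * the realized capacity ``sum_i g_i (1 + Lambda_n_i)`` equals the
      attempted ``n_c`` exactly  (fixes the overall scale
      ``Gamma_n_ribosome``).

    If the genome carries heterogeneous initiation multipliers
    (``gamma_mult``), they are applied to the generic rates and the
    generic pool is rescaled by a common factor so the capacity
    constraint still holds exactly.

    Initial mRNA numbers are ``m0_i = k_n_i tau_m_i`` evaluated with the
    attempted RNAP count and the full free-RNAP solve; initial protein
    mass fractions are the mRNA mass shares, and the initial total mass
    is shifted so that the actual RNAP mass fraction times actual mass
    equals the attempted product (making the RNAP copy number continuous
    at t = 0).
    """
    gl = globals_
    i_n, i_r = genome.i_rnap, genome.i_ribosome
    gen = genome.is_generic

    L_r, L_n = genome.L[i_r], genome.L[i_n]
    phi_r = gl.mu0 * L_r / gl.v_r
    if phi_r >= 1:
        raise ValueError(
            f"attempted ribosome mass fraction phi_r={phi_r:.3g} >= 1: "
            "growth rate infeasible for the given v_r"
        )
    phi_n = RNAP_PER_RIBOSOME * phi_r * L_n / L_r

    # mRNA-mass weights in the weak-binding limit: m_i ~ Gamma_i g_i tau_i / K_i
    A_r = genome.g[i_r] * genome.tau_m[i_r] * L_r / genome.K_n[i_r]
    A_n = genome.g[i_n] * genome.tau_m[i_n] * L_n / genome.K_n[i_n]
    A_g = float(np.sum(genome.g[gen] * genome.tau_m[gen] * genome.L[gen] / genome.K_n[gen]))
    y = (phi_n / phi_r) * (A_r / A_n)
    x = (A_r * (1.0 / phi_r - 1.0) - y * A_n) / A_g
    if x <= 0:
        raise ValueError("calibration infeasible: generic initiation-rate ratio x <= 0")

    sum_g = float(genome.g.sum())
    denom = (
        genome.g[i_r] * L_r
        + y * genome.g[i_n] * L_n
        + x * float(np.sum(genome.g[gen] * genome.L[gen]))
    )
    if denom <= 0:
        raise ValueError("calibration infeasible: nonpositive rate denominator")
    if gl.n_c_target <= sum_g:
        raise ValueError(
            "n_c_target must exceed the total gene copy number "
            f"({gl.n_c_target:.3g} <= {sum_g:.3g})"
        )
    Gamma_n_r = (gl.n_c_target - sum_g) * gl.v_n / denom

    Gamma_n = np.empty(genome.n_genes)
    Gamma_n[i_r] = Gamma_n_r
    Gamma_n[i_n] = y * Gamma_n_r
    Gamma_n[gen] = x * Gamma_n_r

    if genome.gamma_mult is not None:
        Gamma_n[gen] *= genome.gamma_mult[gen]
        # restore the capacity constraint exactly with a common rescale
        machine_slots = (
            genome.g[i_r] * (1.0 + Gamma_n[i_r] * L_r / gl.v_n)
            + genome.g[i_n] * (1.0 + Gamma_n[i_n] * L_n / gl.v_n)
        )
        generic_elong = float(np.sum(genome.g[gen] * Gamma_n[gen] * genome.L[gen] / gl.v_n))
        target = gl.n_c_target - machine_slots - float(np.sum(genome.g[gen]))
        if target <= 0 or generic_elong <= 0:
            raise ValueError("calibration infeasible under initiation-rate heterogeneity")
        Gamma_n[gen] *= target / generic_elong

    cal_genome = genome.replace(Gamma_n=Gamma_n)
    n_c = nc_of(cal_genome, gl)

    # initial conditions from the attempted machine provisioning
    n_att = phi_n * gl.M_b / L_n
    V = gl.M_b / gl.rho
    V_n = V / gl.a
    c_n = n_att / V_n
    lam_n = cal_genome.lambda_n(gl)
    slots = cal_genome.g * (1.0 + lam_n)
    F_n = _solve_free_fraction(n_att, slots, cal_genome.K_n, c_n)
    c_n_free = c_n * F_n
    P_b = c_n_free / (c_n_free + cal_genome.K_n)
    m0 = cal_genome.Gamma_n * cal_genome.g * P_b * cal_genome.tau_m

    mass = m0 * cal_genome.L
    phi = mass / mass.sum()
    phi_n_actual = float(phi[i_n])
    if phi_n_actual <= 0:
        raise ValueError("calibration produced a zero RNAP mass fraction")
    M0_actual = phi_n * gl.M_b / phi_n_actual
    p0 = phi * M0_actual / cal_genome.L

    return CalibrationResult(
        genome=cal_genome,
        phi_r=float(phi_r),
        phi_n=float(phi_n),
        Gamma_n_r=float(Gamma_n_r),
        y=float(y),
        x=float(x),
        m0=m0,
        p0=p0,
        M0_actual=float(M0_actual),
        n_c=float(n_c),
    )
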