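"""Coupled mRNA/protein dynamics with volume bookkeeping.

The state vector stacks all mRNA copy numbers followed by all protein
copy numbers.  At every right-hand-side evaluation the free-machine
fractions are re-solved, so the competition for RNAPs and ribosomes
feeds back into every rate.  The system is only mildly stiff (the
fastest modes are the mRNA lifetimes), so an explicit high-order
Runge-Kutta integrator with warm-started allocation solves is both
accurate and fast; implicit methods would need dense Jacobians here
because the machine counts couple every equation to every other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .allocation import CellState, _solve_free_fraction, production_rates
from .genome import CalibrationResult, Genome, GlobalParams, calibrate, nc_of

logger = logging.getLogger(__name__)

__all__ = [
    "IntegrateOptions",
    "ExperimentOptions",
    "Trajectory",
    "integrate",
    "run_experiment",
    "run_cell_cycle",
]


@dataclass(frozen=True)
class IntegrateOptions:
    """Integrator controls: method/tolerances and the output cadence."""

    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-8
    grid_dt: float = 1.0
    max_step: float = np.inf


@dataclass(frozen=True)
class ExperimentOptions(IntegrateOptions):
    """Protocol controls for :func:`run_experiment`.

    ``burn_in`` minutes are discarded and the trajectory re-based there;
    the run stops when the total protein mass exceeds
    ``stop_mass_multiple`` times the attempted initial mass, or at
    ``t_end``, whichever comes first.
    """

    burn_in: float = 20.0
    t_end: float = 600.0
    stop_mass_multiple: float = 9.0


@dataclass
class Trajectory:
    """Sampled cell history with derived cell-level series.

    Per-time arrays: ``m``/``p`` are (T, n_genes); ``V, M, n, r, F_n,
    F_r`` are (T,).  ``meta`` carries protocol information (burn-in,
    normalization origin, division times, ...).
    """

    t: np.ndarray
    m: np.ndarray
    p: np.ndarray
    M: np.ndarray
    V: np.ndarray
    n: np.ndarray
    r: np.ndarray
    F_n: np.ndarray
    F_r: np.ndarray
    genome: Genome
    globals: GlobalParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    @property
    def v_rel(self) -> np.ndarray:
        """Volume normalized to the first snapshot."""
        return self.V / self.V[0]

    @property
    def m_rel(self) -> np.ndarray:
        """mRNA numbers normalized per gene to the first snapshot."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.m / self.m[0]

    @property
    def p_rel(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.p / self.p[0]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: t_min, series, gene_id, value."""
        frames = []
        gene_ids = self.genome.gene_id.astype(str)
        T, G = self.m.shape
        for series, arr in (("mRNA", self.m), ("protein", self.p)):
            frames.append(
                pd.DataFrame(
                    {
                        "t_min": np.repeat(self.t, G),
                        "series": series,
                        "gene_id": np.tile(gene_ids, T),
                        "value": arr.ravel(),
                    }
                )
            )
        for series, arr in (
            ("volume", self.V),
            ("mass", self.M),
            ("free_fraction_rnap", self.F_n),
            ("free_fraction_ribo", self.F_r),
        ):
            frames.append(
                pd.DataFrame(
                    {"t_min": self.t, "series": series, "gene_id": "", "value": arr}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_wide_frame(self) -> pd.DataFrame:
        """Compact per-time summary of the cell-level series."""
        return pd.DataFrame(
            {
                "t_min": self.t,
                "volume": self.V,
                "mass": self.M,
                "n_rnap": self.n,
                "n_ribosome": self.r,
                "F_n": self.F_n,
                "F_r": self.F_r,
            }
        )


def _make_rhs(genome: Genome, globals_: GlobalParams) -> Callable:
    """Right-hand side with warm-started free-fraction solves."""
    G = genome.n_genes
    inv_tau_m = 1.0 / genome.tau_m
    inv_tau_p = np.where(np.isinf(genome.tau_p), 0.0, 1.0 / genome.tau_p)
    lam_n = genome.lambda_n(globals_)
    lam_r = genome.lambda_r(globals_)
    slots_n = genome.g * (1.0 + lam_n)
    i_rnap, i_ribo = genome.i_rnap, genome.i_ribosome
    L = genome.L
    K_n, K_r = genome.K_n, genome.K_r
    Gn_g = genome.Gamma_n * genome.g
    Gr = genome.Gamma_r
    rho, a = globals_.rho, globals_.a
    cache = {"F_n": None, "F_r": None}

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        m = np.maximum(y[:G], 0.0)
        p = np.maximum(y[G:], 0.0)
        M = float(np.dot(p, L))
        V = M / rho
        V_n = V / a
        V_c = V - V_n
        n = p[i_rnap]
        r = p[i_ribo]

        if n > 0:
            c_n = n / V_n
            F_n = _solve_free_fraction(n, slots_n, K_n, c_n, guess=cache["F_n"])
            cache["F_n"] = F_n
            c_nf = c_n * F_n
            P_b = c_nf / (c_nf + K_n)
        else:
            P_b = 0.0
        k_n = Gn_g * P_b

        if r > 0:
            c_r = r / V_c
            slots_r = m * (1.0 + lam_r)
            F_r = _solve_free_fraction(r, slots_r, K_r, c_r, guess=cache["F_r"])
            cache["F_r"] = F_r
            c_rf = c_r * F_r
            P_rbs = c_rf / (c_rf + K_r)
        else:
            P_rbs = 0.0
        k_r = Gr * m * P_rbs

        dy = np.empty_like(y)
        dy[:G] = k_n - m * inv_tau_m
        dy[G:] = k_r - p * inv_tau_p
        return dy

    return rhs


def _fill_derived(traj_t, traj_m, traj_p, genome, globals_):
    """Recompute cell-level series at every output point."""
    T = traj_t.size
    M = traj_p @ genome.L
    V = M / globals_.rho
    n = traj_p[:, genome.i_rnap]
    r = traj_p[:, genome.i_ribosome]
    F_n = np.empty(T)
    F_r = np.empty(T)
    lam_n = genome.lambda_n(globals_)
    lam_r = genome.lambda_r(globals_)
    slots_n = genome.g * (1.0 + lam_n)
    guess_n = guess_r = None
    for k in range(T):
        V_n = V[k] / globals_.a
        V_c = V[k] - V_n
        if n[k] > 0:
            guess_n = _solve_free_fraction(n[k], slots_n, genome.K_n, n[k] / V_n, guess=guess_n)
            F_n[k] = guess_n
        else:
            F_n[k] = 0.0
        if r[k] > 0:
            slots_r = traj_m[k] * (1.0 + lam_r)
            guess_r = _solve_free_fraction(r[k], slots_r, genome.K_r, r[k] / V_c, guess=guess_r)
            F_r[k] = guess_r
        else:
            F_r[k] = 0.0
    return M, V, n, r, F_n, F_r


def integrate(
    state0: CellState,
    genome: Genome,
    globals_: GlobalParams,
    t_end: float,
    options: IntegrateOptions | None = None,
    *,
    events: Sequence[Callable] | None = None,
) -> Trajectory:
    """Integrate the coupled mRNA/protein system from ``state0.t`` to ``t_end``.

    Output is sampled on a uniform grid of spacing ``options.grid_dt``
    (the end point — or the terminal-event time — is always included).
    Raises if the integrator fails or if any state component dips below
    ``-1e-9`` relative to the solution scale.
    """
    options = options or IntegrateOptions()
    t0 = float(state0.t)
    if not t_end > t0:
        raise ValueError("t_end must exceed the initial time")
    G = genome.n_genes
    y0 = np.concatenate([state0.m, state0.p])
    rhs = _make_rhs(genome, globals_)
    t_eval = np.arange(t0, t_end, options.grid_dt)
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)

    sol = solve_ivp(
        rhs,
        (t0, t_end),
        y0,
        method=options.method,
        t_eval=t_eval,
        rtol=options.rtol,
        atol=options.atol,
        max_step=options.max_step,
        events=list(events) if events else None,
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"integrator failure: {sol.message}")

    ts = sol.t
    ys = sol.y.T
    if sol.status == 1 and events:
        # append the terminal-event point if it lies beyond the last sample
        for te, ye in zip(sol.t_events, sol.y_events):
            if te.size and te[-1] > ts[-1] + 1e-12:
                ts = np.append(ts, te[-1])
                ys = np.vstack([ys, ye[-1]])

    scale = max(1.0, float(np.max(np.abs(ys))))
    if float(ys.min()) < -1e-9 * scale:
        k, j = np.unravel_index(np.argmin(ys), ys.shape)
        raise RuntimeError(
            f"negative state component {ys[k, j]:.3e} at t={ts[k]:.3f} "
            f"(index {j}): integration diverged"
        )
    ys = np.maximum(ys, 0.0)

    m, p = ys[:, :G], ys[:, G:]
    M, V, n, r, F_n, F_r = _fill_derived(ts, m, p, genome, globals_)
    n_c = nc_of(genome, globals_)
    violations = int(np.sum(n >= n_c))
    if violations:
        logger.warning("phase-1 condition n < n_c violated at %d output points", violations)
    meta = {
        "t0": t0,
        "t_end": float(ts[-1]),
        "n_c": n_c,
        "phase1_violations": violations,
        "stopped_by_event": bool(sol.status == 1),
    }
    return Trajectory(
        t=ts, m=m, p=p, M=M, V=V, n=n, r=r, F_n=F_n, F_r=F_r,
        genome=genome, globals=globals_, meta=meta,
    )


def _rebase(traj: Trajectory, burn_in: float) -> Trajectory:
    """Drop the first ``burn_in`` minutes and shift the time origin."""
    keep = traj.t >= burn_in - 1e-9
    if not np.any(keep) or np.sum(keep) < 2:
        raise ValueError(
            f"burn-in ({burn_in} min) leaves fewer than two samples: "
            "the run stopped too early"
        )
    i0 = int(np.argmax(keep))
    out = Trajectory(
        t=traj.t[i0:] - traj.t[i0],
        m=traj.m[i0:],
        p=traj.p[i0:],
        M=traj.M[i0:],
        V=traj.V[i0:],
        n=traj.n[i0:],
        r=traj.r[i0:],
        F_n=traj.F_n[i0:],
        F_r=traj.F_r[i0:],
        genome=traj.genome,
        globals=traj.globals,
        meta=dict(traj.meta),
    )
    out.meta["burn_in"] = float(burn_in)
    return out


def run_experiment(
    genome: Genome,
    globals_: GlobalParams,
    options: ExperimentOptions | None = None,
) -> Trajectory:
    """Calibrated growth experiment with transient removal.

    Calibrates the genome, integrates from the calibrated initial
    conditions, stops when the total protein mass exceeds
    ``stop_mass_multiple * M_b`` (or at ``t_end``), then discards the
    burn-in and re-bases time and normalization there.  The returned
    trajectory's ``meta`` records the RNAP saturation ``n0_over_nc``,
    the origin mass fractions ``phi0`` and the weighted-average
    Michaelis-Menten constant ``K_avg`` used by the scaling theory.
    """
    options = options or ExperimentOptions()
    if options.burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    if options.burn_in >= options.t_end:
        raise ValueError("burn_in must be smaller than t_end")
    cal = calibrate(genome, globals_)
    gnm = cal.genome
    state0 = CellState(t=0.0, m=cal.m0, p=cal.p0)
    stop_mass = options.stop_mass_multiple * globals_.M_b

    def mass_event(t, y, L=gnm.L, G=gnm.n_genes):
        return float(np.dot(y[G:], L)) - stop_mass

    mass_event.terminal = True
    mass_event.direction = 1

    # make sure the burn-in instant is on the output grid
    base = integrate(
        state0, gnm, globals_, options.t_end,
        IntegrateOptions(
            method=options.method, rtol=options.rtol, atol=options.atol,
            grid_dt=options.grid_dt, max_step=options.max_step,
        ),
        events=[mass_event],
    )
    traj = _rebase(base, options.burn_in)
    phi0 = traj.p[0] * gnm.L / traj.M[0]
    traj.meta.update(
        {
            "calibration": cal,
            "n0": float(traj.n[0]),
            "n0_over_nc": float(traj.n[0] / traj.meta["n_c"]),
            "phi0": phi0,
            "K_avg": float(np.dot(phi0, gnm.K_n)),
            "stop_mass_multiple": float(options.stop_mass_multiple),
        }
    )
    return traj


def run_cell_cycle(
    genome: Genome,
    globals_: GlobalParams,
    reporter_super: str,
    reporter_sub: str,
    ratio_threshold: float,
    n_cycles: int,
    options: IntegrateOptions | None = None,
    *,
    t_max_cycle: float = 2000.0,
) -> Trajectory:
    """Concentration-ratio-triggered division cycles.

    The cell divides (all copy numbers exactly halved) whenever the
    concentration ratio of the superlinear reporter protein to the
    sublinear reporter protein rises through ``ratio_threshold``.  Since
    both reporters share the cell volume, the concentration ratio
    equals the copy-number ratio.  After division the superlinear
    reporter's production transiently lags (the RNAP number was
    halved), so the ratio dips and the next crossing is again from
    below.  ``meta`` records division times and per-cycle birth/division
    snapshots plus fold changes.

    Raises if the threshold is never crossed within ``t_max_cycle``
    minutes of one cycle.  A threshold at or below the initial ratio is
    flagged as degenerate (cycle length zero) and returned immediately.
    """
    options = options or IntegrateOptions()
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    cal = calibrate(genome, globals_)
    gnm = cal.genome
    i_sup = gnm.index_of(reporter_super)
    i_sub = gnm.index_of(reporter_sub)
    phi0 = cal.m0 * gnm.L / np.dot(cal.m0, gnm.L)
    K_avg0 = float(np.dot(phi0, gnm.K_n))
    if not (gnm.K_n[i_sup] > K_avg0 > gnm.K_n[i_sub]):
        raise ValueError(
            "reporter_super must have K_n above the weighted average and "
            "reporter_sub below it"
        )
    G = gnm.n_genes

    y = np.concatenate([cal.m0, cal.p0])
    ratio0 = y[G + i_sup] / y[G + i_sub]
    meta = {
        "division_times": [],
        "birth_states": [],
        "division_states": [],
        "cycle_fold_changes": [],
        "degenerate_cycle": False,
    }
    if ratio0 >= ratio_threshold * (1.0 - 1e-12):
        logger.warning("division threshold already met at t=0: cycle length -> 0")
        meta["degenerate_cycle"] = True
        meta["division_times"] = [0.0]
        state0 = CellState(t=0.0, m=cal.m0, p=cal.p0)
        traj = integrate(state0, gnm, globals_, options.grid_dt, options)
        traj.meta.update(meta)
        return traj

    def ratio_event(t, yv):
        return yv[G + i_sup] / yv[G + i_sub] - ratio_threshold

    ratio_event.terminal = True
    ratio_event.direction = 1

    # Copy numbers and volume halve together at division, so the reporter
    # ratio and its time derivative are continuous across division: right
    # after birth the ratio briefly overshoots the threshold before the
    # halved RNAP pool makes it dip.  Post-division cycles therefore first
    # wait for the ratio to drop marginally below the threshold (the
    # "disarm" phase) and only then arm the rising-crossing division event.
    def disarm_event(t, yv):
        return yv[G + i_sup] / yv[G + i_sub] - ratio_threshold * (1.0 - 1e-6)

    disarm_event.terminal = True
    disarm_event.direction = -1

    pieces: list[Trajectory] = []
    t_now = 0.0
    for cycle in range(n_cycles):
        t_birth = t_now
        y_birth = y.copy()
        if cycle > 0:
            state = CellState(t=t_now, m=y[:G], p=y[G:])
            seg = integrate(
                state, gnm, globals_, t_now + t_max_cycle, options,
                events=[disarm_event],
            )
            if not seg.meta["stopped_by_event"]:
                raise RuntimeError(
                    f"cycle {cycle}: reporter ratio never dipped below the "
                    f"threshold within {t_max_cycle} minutes"
                )
            pieces.append(seg)
            y = np.concatenate([seg.m[-1], seg.p[-1]])
            t_now = float(seg.t[-1])
        state = CellState(t=t_now, m=y[:G], p=y[G:])
        seg = integrate(
            state, gnm, globals_, t_birth + t_max_cycle, options, events=[ratio_event]
        )
        if not seg.meta["stopped_by_event"]:
            raise RuntimeError(
                f"cycle {cycle}: division threshold never crossed within "
                f"{t_max_cycle} minutes"
            )
        pieces.append(seg)
        y_div = np.concatenate([seg.m[-1], seg.p[-1]])
        meta["division_times"].append(float(seg.t[-1]))
        meta["birth_states"].append(y_birth)
        meta["division_states"].append(y_div.copy())
        meta["cycle_fold_changes"].append(y_div / y_birth)
        y = y_div / 2.0
        t_now = float(seg.t[-1])

    # stitch segments, dropping duplicated boundary points
    def cat(get):
        parts = [get(pieces[0])]
        for seg in pieces[1:]:
            parts.append(get(seg)[1:])
        return np.concatenate(parts)

    # perturb duplicate boundary times minutely so the grid stays increasing
    t_all = cat(lambda s: s.t)
    for k in range(1, t_all.size):
        if t_all[k] <= t_all[k - 1]:
            t_all[k] = t_all[k - 1] + 1e-9
    traj = Trajectory(
        t=t_all,
        m=cat(lambda s: s.m),
        p=cat(lambda s: s.p),
        M=cat(lambda s: s.M),
        V=cat(lambda s: s.V),
        n=cat(lambda s: s.n),
        r=cat(lambda s: s.r),
        F_n=cat(lambda s: s.F_n),
        F_r=cat(lambda s: s.F_r),
        genome=gnm,
        globals=globals_,
        meta={**pieces[-1].meta, **meta, "calibration": cal},
    )
    return traj
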