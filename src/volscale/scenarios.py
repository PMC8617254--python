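"""Run configuration and end-to-end scenario drivers.

A run configuration names one of four experiment scenarios —
``homogeneous`` (all recruitment abilities equal), ``two_special``
(homogeneous background plus two deviating genes), ``lognormal_ensemble``
(continuously distributed abilities) and ``cell_cycle`` (ratio-triggered
divisions) — together with the genome source, the global cell
parameters, the protocol knobs and the fitting controls.  The driver
generates/loads the genome, calibrates, simulates, predicts, fits and
summarizes, writing every artifact with a config-hash header.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy import stats

from . import io as vio
from .dynamics import ExperimentOptions, IntegrateOptions, run_cell_cycle, run_experiment
from .fitting import (
    estimates_frame,
    fit_trajectory_betas,
    production_rate_proxy,
    scaling_summary,
)
from .genome import Genome, GlobalParams, make_genome
from .theory import predict_scaling

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_scenario"]

SCENARIOS = ("homogeneous", "two_special", "lognormal_ensemble", "cell_cycle")


def _strict(cls_fields: set[str], data: Mapping, where: str) -> None:
    unknown = set(data) - cls_fields
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


@dataclass(frozen=True)
class GenomeConfig:
    """Either a path to a gene TSV or generator parameters."""

    path: str | None = None
    n_genes: int = 2000
    K_mean: float = 6.0e3
    K_cv: float = 0.5
    lifetime_mean: float = 10.0
    lifetime_cv: float = 1.0
    special_multipliers: tuple[float, ...] = ()
    gamma_cv: float = 0.0
    n_degradable: int = 0
    tau_p_deg: float = 10.0


@dataclass(frozen=True)
class ExperimentConfig:
    scenario: str = "homogeneous"
    burn_in: float = 20.0
    t_end: float = 600.0
    stop_mass_multiple: float = 9.0
    grid_dt: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-8
    # cell-cycle only
    ratio_threshold_factor: float = 1.05
    n_cycles: int = 8

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )


@dataclass(frozen=True)
class FitConfig:
    n_points: int = 25
    beta_upper: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    """Schema-validated run configuration (unknown keys rejected)."""

    globals: GlobalParams = field(default_factory=GlobalParams)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        _strict({"globals", "genome", "experiment", "fit", "seed"}, data, "config")
        sections = {}
        for name, section_cls in (
            ("globals", GlobalParams),
            ("genome", GenomeConfig),
            ("experiment", ExperimentConfig),
            ("fit", FitConfig),
        ):
            block = dict(data.get(name, {}) or {})
            if name == "genome" and "special_multipliers" in block:
                block["special_multipliers"] = tuple(block["special_multipliers"])
            _strict({f.name for f in dataclasses.fields(section_cls)}, block, name)
            sections[name] = section_cls(**block)
        return cls(seed=int(data.get("seed", 0)), **sections)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return vio.config_hash(self.to_dict())


def _build_genome(cfg: RunConfig) -> Genome:
    gc = cfg.genome
    if gc.path is not None:
        return vio.read_gene_table(gc.path)
    overrides = None
    if cfg.experiment.scenario == "two_special" or gc.special_multipliers:
        mults = gc.special_multipliers or (20.0, 0.2)
        overrides = {f"g{i:04d}": m for i, m in enumerate(mults)}
    K_cv = gc.K_cv
    lifetime_cv = gc.lifetime_cv
    if cfg.experiment.scenario in ("homogeneous", "two_special"):
        K_cv = 0.0
        lifetime_cv = 0.0
    return make_genome(
        gc.n_genes,
        K_mean=gc.K_mean,
        K_cv=K_cv,
        lifetime_mean=gc.lifetime_mean,
        lifetime_cv=lifetime_cv,
        special_overrides=overrides,
        gamma_cv=gc.gamma_cv,
        n_degradable=gc.n_degradable,
        tau_p_deg=gc.tau_p_deg,
        seed=cfg.seed,
    )


def run_scenario(config: RunConfig, out_dir) -> dict:
    """Execute a scenario end to end; returns (and writes) the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash, "seed": config.seed}
    ec = config.experiment

    genome = _build_genome(config)
    summary: dict = {"scenario": ec.scenario, "seed": config.seed, "config_hash": config.hash}

    if ec.scenario == "cell_cycle":
        mults = config.genome.special_multipliers or (20.0, 0.2)
        sup, sub = "g0000", "g0001"
        opts = IntegrateOptions(rtol=ec.rtol, atol=ec.atol, grid_dt=ec.grid_dt)
        # threshold relative to the calibrated starting ratio
        from .genome import calibrate

        cal = calibrate(genome, config.globals)
        i_sup = cal.genome.index_of(sup)
        i_sub = cal.genome.index_of(sub)
        ratio0 = cal.p0[i_sup] / cal.p0[i_sub]
        traj = run_cell_cycle(
            genome,
            config.globals,
            reporter_super=sup,
            reporter_sub=sub,
            ratio_threshold=ec.ratio_threshold_factor * ratio0,
            n_cycles=ec.n_cycles,
            options=opts,
        )
        folds = traj.meta["cycle_fold_changes"]
        last = folds[-1] if folds else np.array([])
        summary.update(
            {
                "n_divisions": len(traj.meta["division_times"]),
                "division_times": traj.meta["division_times"],
                "last_cycle_fold_min": float(last.min()) if last.size else None,
                "last_cycle_fold_max": float(last.max()) if last.size else None,
                "degenerate_cycle": traj.meta["degenerate_cycle"],
            }
        )
        vio.write_gene_table(traj.genome, out / "genome.tsv", meta)
        vio.write_trajectory(traj, out / "trajectory.tsv", meta)
        vio.write_summary_json(summary, out / "summary.json", meta)
        return summary

    opts = ExperimentOptions(
        burn_in=ec.burn_in,
        t_end=ec.t_end,
        stop_mass_multiple=ec.stop_mass_multiple,
        grid_dt=ec.grid_dt,
        rtol=ec.rtol,
        atol=ec.atol,
    )
    traj = run_experiment(genome, config.globals, opts)
    gnm = traj.genome
    predictions = predict_scaling(gnm, traj.meta["phi0"], traj.meta["n0_over_nc"])
    estimates = fit_trajectory_betas(traj, n_points=config.fit.n_points)
    est_frame = estimates_frame(estimates)
    merged = est_frame.merge(predictions, on="gene_id")

    betas = merged["beta_hat"].to_numpy(dtype=float)
    conv = merged["converged"].to_numpy(dtype=bool)
    summary.update(
        {
            "n_genes": gnm.n_genes,
            "n0_over_nc": traj.meta["n0_over_nc"],
            "K_avg": traj.meta["K_avg"],
            "v_rel_max": float(traj.v_rel[-1]),
            "max_abs_beta_hat": float(np.max(np.abs(betas[conv]))) if conv.any() else None,
        }
    )

    if ec.scenario == "two_special":
        rows = []
        for gid in ("g0000", "g0001"):
            row = merged.loc[merged["gene_id"] == gid].iloc[0]
            rows.append(
                {
                    "gene_id": gid,
                    "K_multiplier": float(row["K_n"] / config.genome.K_mean),
                    "beta_hat": float(row["beta_hat"]),
                    "beta_pred": float(row["beta_pred"]),
                }
            )
        summary["special_genes"] = rows

    if ec.scenario == "lognormal_ensemble":
        ok = conv.copy()
        reg = stats.linregress(
            merged.loc[ok, "beta_pred"], merged.loc[ok, "beta_hat"]
        )
        proxy = production_rate_proxy(traj.m[0], gnm.tau_m)
        rate_summary = scaling_summary(estimates, proxy)
        summary.update(
            {
                "regression_slope": float(reg.slope),
                "regression_r2": float(reg.rvalue**2),
                "beta_summary": rate_summary,
            }
        )

    vio.write_gene_table(gnm, out / "genome.tsv", meta)
    vio.write_trajectory(traj, out / "trajectory.tsv", meta)
    vio.write_table(predictions, out / "predictions.tsv", meta)
    vio.write_table(est_frame, out / "estimates.tsv", meta)
    vio.write_summary_json(summary, out / "summary.json", meta)
    return summary
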