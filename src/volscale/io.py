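"""File formats: gene tables, trajectories, expression tables, summaries.

All tabular artifacts are UTF-8 tab-separated text with ``.`` decimals,
``inf`` for infinite lifetimes, and values written at 12 significant
digits so round trips are lossless at that precision.  Every writer
prepends ``# key=value`` comment headers carrying the config hash, seed
and software version; readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fitting import ExpressionTable
from .genome import Genome, GlobalParams

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_gene_table",
    "read_gene_table",
    "write_trajectory",
    "read_trajectory",
    "write_expression_table",
    "read_expression_table",
    "write_summary_json",
]

GENE_COLUMNS = [
    "gene_id", "role", "L", "g", "K_n", "K_r",
    "Gamma_n", "Gamma_r", "tau_m", "tau_p",
]
_FLOAT_FMT = "%.12g"


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header_lines(meta: Mapping | None) -> str:
    lines = [f"# volscale_version={__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


def write_table(frame: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    """Write a data frame as commented TSV at 12 significant digits."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    """Read a commented TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_table_meta(path) -> dict:
    """Parse the ``# key=value`` comment header of a TSV artifact."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


# -- gene tables -----------------------------------------------------------

def write_gene_table(genome: Genome, path, meta: Mapping | None = None) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": genome.gene_id.astype(str),
            "role": genome.role.astype(str),
            "L": genome.L.astype(int),
            "g": genome.g.astype(int),
            "K_n": genome.K_n,
            "K_r": genome.K_r,
            "Gamma_n": genome.Gamma_n,
            "Gamma_r": genome.Gamma_r,
            "tau_m": genome.tau_m,
            "tau_p": genome.tau_p,
        }
    )
    write_table(frame, path, meta)


def read_gene_table(path) -> Genome:
    """Read a gene TSV, reporting malformed rows and missing columns."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "role": str})
    missing = [c for c in GENE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    numeric = [c for c in GENE_COLUMNS if c not in ("gene_id", "role")]
    for col in numeric:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna()
        if bad.any():
            rows = ", ".join(str(i + 2) for i in frame.index[bad][:5])
            raise ValueError(f"{path}: malformed {col!r} values at line(s) {rows}")
        frame[col] = values
    return Genome(
        gene_id=frame["gene_id"].to_numpy(dtype=object),
        role=frame["role"].to_numpy(dtype=object),
        L=frame["L"].to_numpy(),
        g=frame["g"].to_numpy(),
        K_n=frame["K_n"].to_numpy(),
        K_r=frame["K_r"].to_numpy(),
        Gamma_n=frame["Gamma_n"].to_numpy(),
        Gamma_r=frame["Gamma_r"].to_numpy(),
        tau_m=frame["tau_m"].to_numpy(),
        tau_p=frame["tau_p"].to_numpy(),
    )


# -- trajectories ----------------------------------------------------------

def write_trajectory(traj, path, meta: Mapping | None = None, *, wide: bool = False) -> None:
    frame = traj.to_wide_frame() if wide else traj.to_long_frame()
    write_table(frame, path, meta)


def read_trajectory(path) -> pd.DataFrame:
    """Read a long-format trajectory TSV back as a data frame."""
    frame = read_table(path)
    required = {"t_min", "series", "gene_id", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(sorted(missing))}")
    return frame


# -- expression tables -----------------------------------------------------

def write_expression_table(
    table: ExpressionTable, expr_path, volumes_path, lifetimes_path=None,
    meta: Mapping | None = None,
) -> None:
    bins = [f"volume_{b + 1}" for b in range(table.volumes.size)]
    frame = pd.DataFrame(table.X, columns=bins)
    frame.insert(0, "gene_id", table.gene_id.astype(str))
    write_table(frame, expr_path, meta)
    write_table(
        pd.DataFrame({"bin": bins, "volume": table.volumes}), volumes_path, meta
    )
    if lifetimes_path is not None:
        if table.tau_m is None:
            raise ValueError("expression table has no lifetimes to write")
        write_table(
            pd.DataFrame({"gene_id": table.gene_id.astype(str), "tau_m": table.tau_m}),
            lifetimes_path,
            meta,
        )


def read_expression_table(expr_path, volumes_path, lifetimes_path=None) -> ExpressionTable:
    expr = read_table(expr_path)
    if "gene_id" not in expr.columns:
        raise ValueError(f"{expr_path}: missing required column(s): gene_id")
    vol = read_table(volumes_path)
    for col in ("bin", "volume"):
        if col not in vol.columns:
            raise ValueError(f"{volumes_path}: missing required column(s): {col}")
    bins = list(vol["bin"])
    missing = [b for b in bins if b not in expr.columns]
    if missing:
        raise ValueError(f"{expr_path}: missing volume-bin column(s): {', '.join(missing)}")
    tau = None
    if lifetimes_path is not None:
        lt = read_table(lifetimes_path)
        for col in ("gene_id", "tau_m"):
            if col not in lt.columns:
                raise ValueError(f"{lifetimes_path}: missing required column(s): {col}")
        lookup = dict(zip(lt["gene_id"].astype(str), lt["tau_m"]))
        tau = np.array([lookup.get(g, np.nan) for g in expr["gene_id"].astype(str)])
    return ExpressionTable(
        gene_id=expr["gene_id"].to_numpy(dtype=object),
        volumes=vol["volume"].to_numpy(dtype=float),
        X=expr[bins].to_numpy(dtype=float),
        tau_m=tau,
    )


# -- summaries -------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_summary_json(summary: Mapping, path, meta: Mapping | None = None) -> None:
    payload = {"_meta": {"volscale_version": __version__, **(meta or {})}}
    payload.update(_jsonable(dict(summary)))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
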