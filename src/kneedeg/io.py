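"""File I/O: CSV round-trips, VTK legacy export, provenance headers.

All tabular artifacts are RFC-4180 CSV with ``#``-prefixed provenance
header lines (seed, configuration hash, package version) so any output
can be traced to the run that produced it.  Field exports use the VTK
legacy ASCII format (write-only), one file per time step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_synth import SubjectRecord
from .fe_solver import FieldHistory

__all__ = [
    "config_hash",
    "provenance_header",
    "write_table",
    "read_table",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_stress_csv",
    "read_stress_csv",
    "write_vtk",
]


def config_hash(obj) -> str:
    """Short deterministic hash of any JSON-serialisable configuration."""
    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    payload = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(seed: int | None, cfg_hash: str | None) -> str:
    lines = [f"# kneedeg {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, seed: int | None = None,
                cfg_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(provenance_header(seed, cfg_hash))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err


def write_cohort_csv(records: list[SubjectRecord], path,
                     seed: int | None = None, cfg_hash: str | None = None) -> None:
    from .cohort_synth import cohort_dataframe
    write_table(cohort_dataframe(records), path, seed, cfg_hash)


def read_cohort_csv(path) -> list[SubjectRecord]:
    df = read_table(path)
    required = {"subject_id", "side", "age", "bmi", "height", "body_weight",
                "medial_thickness", "lateral_thickness", "kl_group", "pain"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [SubjectRecord(
        subject_id=str(r.subject_id), side=str(r.side), age=float(r.age),
        bmi=float(r.bmi), height=float(r.height),
        body_weight=float(r.body_weight),
        medial_thickness=float(r.medial_thickness),
        lateral_thickness=float(r.lateral_thickness),
        kl_group=str(r.kl_group), pain=bool(r.pain),
        thickness_factor=float(getattr(r, "thickness_factor", 1.0)),
    ) for r in df.itertuples()]


def write_stress_csv(knee_id: str, volumes: np.ndarray, max_stress: np.ndarray,
                     path, seed: int | None = None,
                     cfg_hash: str | None = None) -> None:
    """Per-element stress-field table consumed by the degeneration stage."""
    df = pd.DataFrame({
        "element": np.arange(len(volumes)),
        "volume_mm3": volumes,
        "max_tensile_stress_MPa": max_stress,
    })
    df.insert(0, "knee_id", knee_id)
    write_table(df, path, seed, cfg_hash)


def read_stress_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = read_table(path)
    for col in ("volume_mm3", "max_tensile_stress_MPa"):
        bad = np.where(~np.isfinite(df[col].to_numpy(dtype=float)))[0]
        if len(bad):
            raise ValueError(
                f"non-finite value in {path} column {col!r}, row {bad[0]}")
    return (df["volume_mm3"].to_numpy(dtype=float),
            df["max_tensile_stress_MPa"].to_numpy(dtype=float))


def write_vtk(fh: FieldHistory, step: int, path,
              nodes: np.ndarray | None = None,
              elems: np.ndarray | None = None) -> None:
    """Write one recorded time step as legacy ASCII VTK (write-only).

    ``nodes``/``elems`` default to the deformed configuration being
    unavailable here, so they must be supplied from the model that
    produced the history (``model.nodes``, ``model.elems``).
    """
    if nodes is None or elems is None:
        raise ValueError("supply the model's nodes and elems arrays")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nn, ne = len(nodes), len(elems)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"kneedeg fields t={fh.times[step]:.6f}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {nn} double\n")
        for (r, z) in nodes:
            f.write(f"{r:.8e} {z:.8e} 0.0\n")
        f.write(f"CELLS {ne} {5 * ne}\n")
        for el in elems:
            f.write("4 " + " ".join(str(i) for i in el) + "\n")
        f.write(f"CELL_TYPES {ne}\n")
        f.write("\n".join(["9"] * ne) + "\n")
        f.write(f"POINT_DATA {nn}\n")
        f.write("VECTORS displacement double\n")
        for (ur, uz) in fh.displacement[step]:
            f.write(f"{ur:.8e} {uz:.8e} 0.0\n")
        f.write("SCALARS pore_pressure double 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(f"{p:.8e}" for p in fh.pore_pressure[step]) + "\n")
        f.write(f"CELL_DATA {ne}\n")
        f.write("SCALARS max_principal_stress double 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(f"{s:.8e}" for s in fh.tensile_stress[step]) + "\n")
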