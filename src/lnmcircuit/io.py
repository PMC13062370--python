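"""Readers/writers for the on-disk formats, pipeline configuration, logging.

One on-disk volume dialect: NIfTI-1 (.nii / .nii.gz) with RAS+ affines and
world coordinates in mm.  Score tables, gene matrices and cluster tables are
TSV; configuration is a single JSON file whose defaults are the protocol's
printed thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GRID_ATOL, BinaryMap, Bold4D, StatMap, Volume, VolumeGrid
from .severity import PatientRecord

logger = logging.getLogger("lnmcircuit")


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the requested level."""
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, defaulting to the protocol's
    printed values (see docs/methods.md for units and rationale)."""

    t_sensitivity: float = 7.0        # per-lesion t-map threshold
    p_sensitivity: float = 1e-6       # FWE p for per-lesion t-maps
    overlap_fraction: float = 0.95    # sensitivity-map overlap proportion
    fwe_alpha_specificity: float = 0.05
    t_circuit: float = 5.0            # circuit t-map threshold
    p_circuit: float = 1e-6           # FWE p for the circuit t-map
    sphere_radius_mm: float = 3.0
    voxel_p: float = 0.01             # cluster-defining voxel p
    cluster_p: float = 0.05           # cluster-level p
    n_perm_dominance: int = 10_000
    n_perm_pls: int = 1_000
    n_boot_pls: int = 1_000
    top_n_genes: int = 1_500
    fdr_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("p_sensitivity", "fwe_alpha_specificity", "p_circuit",
                     "voxel_p", "cluster_p", "fdr_alpha", "overlap_fraction"):
            v = float(getattr(self, name))
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        for name in ("t_sensitivity", "t_circuit", "sphere_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_perm_dominance", "n_perm_pls", "n_boot_pls", "top_n_genes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

_DESCRIP_RE = re.compile(r"lnmcircuit:(?P<kind>\w+)(?::df=(?P<df>[0-9.]+))?")


def read_grid(path: Union[str, Path]) -> VolumeGrid:
    """Build the session grid from a brain-mask NIfTI (nonzero = in mask)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"brain mask must be 3D, got {data.ndim}D in {path}")
    return VolumeGrid(shape=data.shape, affine=img.affine, brain_mask=data > 0)


def read_volume(
    path: Union[str, Path],
    grid: Optional[VolumeGrid] = None,
    kind: Optional[str] = None,
    df: Optional[float] = None,
) -> Volume:
    """Read a 3D or 4D NIfTI volume onto the session grid.

    3D volumes whose values are a subset of {0, 1} are flagged binary and
    returned as :class:`BinaryMap`; other 3D volumes become :class:`StatMap`
    (``kind``/``df`` taken from the argument, else from the header descrip
    written by :func:`write_volume`, else ``generic``).  4D volumes return a
    :class:`Bold4D` stack with frames in acquisition order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.float64)
    if grid is None:
        mask = np.ones(data.shape[:3], dtype=bool)
        grid = VolumeGrid(shape=data.shape[:3], affine=img.affine, brain_mask=mask)
    else:
        probe = VolumeGrid(shape=data.shape[:3], affine=img.affine,
                           brain_mask=np.ones(data.shape[:3], dtype=bool))
        if not grid.matches(probe):
            raise ValueError(
                f"{path.name}: volume geometry differs from the session grid by more "
                f"than {GRID_ATOL} (shape {data.shape[:3]} vs {grid.shape})"
            )
    if data.ndim == 4:
        return Bold4D(grid=grid, data=data)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected 3D or 4D volume, got {data.ndim}D")

    bad = ~np.isfinite(data[grid.brain_mask])
    uniq = np.unique(data[np.isfinite(data)])
    if uniq.size and np.isin(uniq, [0.0, 1.0]).all():
        if bad.any():
            raise ValueError(f"{path.name}: {int(bad.sum())} non-finite voxels inside the mask")
        return BinaryMap(grid=grid, values=data)

    if kind is None:
        m = _DESCRIP_RE.search(str(img.header.get("descrip", b""), errors="ignore")
                               if isinstance(img.header["descrip"].item(), bytes)
                               else str(img.header["descrip"]))
        if m:
            kind = m.group("kind")
            if df is None and m.group("df") is not None:
                df = float(m.group("df"))
        else:
            kind = "generic"
    if kind != "t" and bad.any():
        raise ValueError(f"{path.name}: {int(bad.sum())} non-finite voxels inside the mask")
    return StatMap(grid=grid, values=data, kind=kind, df=df)


def write_volume(volume: Volume, path: Union[str, Path]) -> None:
    """Write a map or BOLD stack as NIfTI-1, preserving the grid affine.

    Binary maps are written as uint8; stat maps as float64 with the kind
    (and df) recorded in the header descrip so a round trip restores them.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, BinaryMap):
        img = nib.Nifti1Image(volume.values.astype(np.uint8), volume.grid.affine)
        img.header["descrip"] = b"lnmcircuit:binary"
    elif isinstance(volume, StatMap):
        img = nib.Nifti1Image(volume.values.astype(np.float64), volume.grid.affine)
        tag = f"lnmcircuit:{volume.kind}"
        if volume.df is not None:
            tag += f":df={volume.df:g}"
        img.header["descrip"] = tag.encode()
    elif isinstance(volume, Bold4D):
        img = nib.Nifti1Image(np.asarray(volume.data), volume.grid.affine)
    else:
        raise TypeError(f"cannot write {type(volume).__name__}")
    nib.save(img, str(path))


def write_sidecar(path: Union[str, Path], payload: dict) -> None:
    """JSON provenance sidecar next to a written volume."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("subject_id", "mmse", "moca")


def read_scores(path: Union[str, Path]) -> List[PatientRecord]:
    """Read a per-patient score TSV into :class:`PatientRecord` rows.

    Required columns: subject_id, mmse, moca (integers in 0-30); optional:
    lesion_volume, lesion_path.  Rows violating the score ranges and
    duplicated subject ids are rejected with their line number (header =
    line 1).  Severity fields are left unset; the severity module fills them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: List[PatientRecord] = []
    seen = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based, after the header
        for col in ("mmse", "moca"):
            val = getattr(row, col)
            if float(val) != int(val):
                raise ValueError(f"{path} line {line}: {col}={val} is not an integer")
            if not 0 <= int(val) <= 30:
                raise ValueError(f"{path} line {line}: {col}={val} outside [0, 30]")
        sid = str(row.subject_id)
        if sid in seen:
            raise ValueError(
                f"{path} line {line}: duplicated subject id {sid!r} (first at line {seen[sid]})"
            )
        seen[sid] = line
        records.append(
            PatientRecord(
                subject_id=sid,
                mmse=int(row.mmse),
                moca=int(row.moca),
                lesion_volume=int(row.lesion_volume) if hasattr(row, "lesion_volume") else None,
                lesion_path=str(row.lesion_path) if hasattr(row, "lesion_path") else None,
            )
        )
    return records


def write_scores(records: List[PatientRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "mmse": r.mmse, "moca": r.moca}
        if r.lesion_volume is not None:
            row["lesion_volume"] = r.lesion_volume
        if r.lesion_path is not None:
            row["lesion_path"] = r.lesion_path
        if r.group is not None:
            row.update(
                mmse_scale=r.mmse_scale, moca_scale=r.moca_scale,
                combined=r.combined, group=r.group,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
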