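"""Readers and writers for the package's delimited-text formats.

Formats:

* TAC table CSV: columns ``frame_start_min, frame_end_min`` then one column
  per region (kBq/mL).
* Blood CSV: ``time_min, plasma_kBq_per_mL, whole_blood_kBq_per_mL``.
* Voxel matrix TSV (one row per voxel) with a JSON sidecar holding the
  frame schedule, brain mask and geometry.
* Kinetic class-set CSV (frame times + one column per class) with a JSON
  sidecar carrying names and the background-frame flag.
* Optional 4D NIfTI reader mapping an image plus schedule onto a
  :class:`~pkquant.core.VoxelDataset`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TAC, BloodInput, FrameSchedule, ScheduleError, VoxelDataset


def read_tac_table(path, **dialect) -> dict[str, TAC]:
    """Read a region TAC table; all TACs share one FrameSchedule.

    ``dialect`` options (e.g. ``sep='\\t'``) are passed to the CSV reader.
    """
    df = pd.read_csv(path, **dialect)
    for col in ("frame_start_min", "frame_end_min"):
        if col not in df.columns:
            raise ValueError(f"TAC table {path} lacks required column {col!r}")
    regions = [c for c in df.columns if c not in ("frame_start_min", "frame_end_min")]
    if not regions:
        raise ValueError(f"TAC table {path} has no region columns")
    try:
        schedule = FrameSchedule(df["frame_start_min"].to_numpy(float),
                                 df["frame_end_min"].to_numpy(float))
    except ScheduleError as exc:
        raise ScheduleError(f"{path}: {exc}") from exc
    tacs = {}
    for region in regions:
        col = pd.to_numeric(df[region], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric or empty cell in column {region!r}, row {row}"
            )
        tacs[region] = TAC(schedule, col.to_numpy(float), region_label=region)
    return tacs


def write_tac_table(path, tacs: dict[str, TAC]) -> None:
    regions = list(tacs)
    schedule = tacs[regions[0]].schedule
    for r in regions[1:]:
        if tacs[r].schedule != schedule:
            raise ValueError("all TACs in one table must share a schedule")
    df = pd.DataFrame({"frame_start_min": schedule.start_times,
                       "frame_end_min": schedule.end_times})
    for r in regions:
        df[r] = tacs[r].values
    df.to_csv(path, index=False, float_format="%.10g")


def read_blood(path) -> BloodInput:
    df = pd.read_csv(path)
    cols = ("time_min", "plasma_kBq_per_mL", "whole_blood_kBq_per_mL")
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"blood file {path} lacks column {col!r}")
    return BloodInput(df["time_min"].to_numpy(float),
                      df["plasma_kBq_per_mL"].to_numpy(float),
                      df["whole_blood_kBq_per_mL"].to_numpy(float))


def write_blood(path, blood: BloodInput) -> None:
    pd.DataFrame({
        "time_min": blood.sample_times,
        "plasma_kBq_per_mL": blood.plasma_parent,
        "whole_blood_kBq_per_mL": blood.whole_blood,
    }).to_csv(path, index=False, float_format="%.10g")


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_voxels(path, voxels: VoxelDataset) -> None:
    np.savetxt(path, voxels.voxel_tacs, delimiter="\t", fmt="%.10g")
    meta = {
        "frame_start_min": voxels.schedule.start_times.tolist(),
        "frame_end_min": voxels.schedule.end_times.tolist(),
        "brain_mask": voxels.brain_mask.astype(int).tolist(),
        "voxel_size_mm": list(voxels.voxel_size_mm),
        "grid_shape": list(voxels.grid_shape) if voxels.grid_shape else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_voxels(path) -> VoxelDataset:
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(_sidecar_path(path).read_text())
    schedule = FrameSchedule(np.asarray(meta["frame_start_min"], float),
                             np.asarray(meta["frame_end_min"], float))
    grid = meta.get("grid_shape")
    return VoxelDataset(
        mat, schedule,
        brain_mask=np.asarray(meta["brain_mask"], bool),
        voxel_size_mm=tuple(meta.get("voxel_size_mm", (2.0, 2.0, 2.0))),
        grid_shape=tuple(grid) if grid else None,
    )


def read_nifti_voxels(img_path, schedule: FrameSchedule,
                      mask_path=None) -> VoxelDataset:
    """Map a 4D NIfTI image (and optional 3D mask) to a VoxelDataset."""
    import nibabel as nib

    img = nib.load(str(img_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D dynamic image")
    if data.shape[3] != schedule.n_frames:
        raise ValueError("image frame count does not match schedule")
    grid_shape = data.shape[:3]
    mat = data.reshape(-1, data.shape[3])
    mask = None
    if mask_path is not None:
        m = np.asanyarray(nib.load(str(mask_path)).dataobj)
        if m.shape != grid_shape:
            raise ValueError("mask shape does not match image grid")
        mask = m.reshape(-1) > 0
    zooms = img.header.get_zooms()[:3]
    return VoxelDataset(mat, schedule, brain_mask=mask,
                        voxel_size_mm=tuple(float(z) for z in zooms),
                        grid_shape=grid_shape)


def write_class_set(path, classes) -> None:
    from .svca import KineticClassSet  # local import to avoid a cycle

    assert isinstance(classes, KineticClassSet)
    df = pd.DataFrame({"frame_start_min": classes.schedule.start_times,
                       "frame_end_min": classes.schedule.end_times})
    for name, curve in zip(classes.class_names, classes.curves):
        df[name] = curve
    df.to_csv(path, index=False, float_format="%.10g")
    _sidecar_path(path).write_text(json.dumps({
        "class_names": list(classes.class_names),
        "has_background_frame": bool(classes.has_background_frame),
    }))


def read_class_set(path):
    from .svca import KineticClassSet

    df = pd.read_csv(path)
    meta = json.loads(_sidecar_path(path).read_text())
    schedule = FrameSchedule(df["frame_start_min"].to_numpy(float),
                             df["frame_end_min"].to_numpy(float))
    names = meta["class_names"]
    curves = np.vstack([df[n].to_numpy(float) for n in names])
    return KineticClassSet(names, curves, schedule,
                           has_background_frame=meta["has_background_frame"])
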