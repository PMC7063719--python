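"""Grid, plan and contour I/O.

Grids travel as NRRD or MetaImage (MHD/RAW) through SimpleITK; treatment
plans and contours as JSON.  Internally grids are (nx, ny, nz) arrays
with the origin at the centre of voxel (0, 0, 0); SimpleITK's (z, y, x)
layout is transposed on the way in and out.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .geometry import VoxelGrid
from .mc_engine import DoseGrid, TreatmentPlan

__all__ = [
    "read_grid", "write_grid", "write_dose", "read_dose",
    "read_plan", "write_plan", "read_contours",
]


def read_grid(path) -> VoxelGrid:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid(values, np.array(img.GetSpacing()),
                     np.array(img.GetOrigin()))


def write_grid(grid: VoxelGrid, path, metadata: dict = None) -> None:
    arr = np.asarray(grid.values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    for key, val in (metadata or {}).items():
        img.SetMetaData(key, str(val))
    sitk.WriteImage(img, str(path))


def write_dose(dose: DoseGrid, path) -> None:
    """Dose grid as NRRD with run metadata keys."""
    write_grid(dose.dose, path, metadata={
        "mode": dose.mode,
        "histories": dose.histories,
        "seed": dose.seed,
        "max_rel_unc_30pct": dose.max_rel_unc_30pct,
    })


def read_dose(path) -> DoseGrid:
    img = sitk.ReadImage(str(path))
    grid = VoxelGrid(sitk.GetArrayFromImage(img).transpose(2, 1, 0),
                     np.array(img.GetSpacing()), np.array(img.GetOrigin()))
    meta = {k: img.GetMetaData(k) for k in img.GetMetaDataKeys()}
    zeros = grid.with_values(np.zeros(grid.shape))
    return DoseGrid(grid, zeros, meta.get("mode", "w,w"),
                    int(meta.get("histories", 0)), int(meta.get("seed", 0)),
                    float(meta.get("max_rel_unc_30pct", "nan")))


def write_plan(plan: TreatmentPlan, path) -> None:
    Path(path).write_text(json.dumps({
        "dwell_positions_mm": plan.dwell_positions.tolist(),
        "dwell_times_s": plan.dwell_times.tolist(),
        "source_strength_U": plan.source_strength_U,
        "prescription_Gy": plan.prescription_Gy,
    }, indent=1))


def read_plan(path) -> TreatmentPlan:
    d = json.loads(Path(path).read_text())
    return TreatmentPlan(
        dwell_positions=np.asarray(d["dwell_positions_mm"], dtype=float),
        dwell_times=np.asarray(d["dwell_times_s"], dtype=float),
        source_strength_U=float(d["source_strength_U"]),
        prescription_Gy=float(d["prescription_Gy"]),
    )


def read_contours(path) -> dict:
    """Contour JSON: {"structures": [{"name", "slices": [...]}, ...]}."""
    d = json.loads(Path(path).read_text())
    return {s["name"]: s["slices"] for s in d["structures"]}
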