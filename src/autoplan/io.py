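"""File I/O: NIfTI volumes for masks and dose, plan artifacts as CSV/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .autoplanner import AutoPlanResult
from .phantoms import StructureMask, StructureSet, VoxelGrid
from .plan_metrics import PlanMetrics, cumulative_dvh

__all__ = [
    "save_structure_set",
    "load_structure_set",
    "save_dose",
    "load_dose",
    "write_plan_outputs",
]

MANIFEST_NAME = "structures.json"


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_img(img) -> VoxelGrid:
    aff = img.affine
    return VoxelGrid(shape=tuple(int(n) for n in img.shape[:3]),
                     spacing=tuple(float(aff[i, i]) for i in range(3)),
                     origin=tuple(float(aff[i, 3]) for i in range(3)))


def save_structure_set(directory, structures: StructureSet) -> Path:
    """Write one NIfTI volume per structure plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(structures.grid)
    manifest = {"grid": {"shape": structures.grid.shape, "spacing": structures.grid.spacing,
                         "origin": structures.grid.origin},
                "structures": []}
    for s in structures.structures:
        fname = f"{s.name}.nii.gz"
        nib.save(nib.Nifti1Image(s.mask.astype(np.uint8), aff), directory / fname)
        manifest["structures"].append({"name": s.name, "role": s.role, "file": fname})
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return directory / MANIFEST_NAME


def load_structure_set(directory) -> StructureSet:
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    g = manifest["grid"]
    grid = VoxelGrid(shape=tuple(g["shape"]), spacing=tuple(g["spacing"]),
                     origin=tuple(g["origin"]))
    structures = []
    for entry in manifest["structures"]:
        img = nib.load(directory / entry["file"])
        mask = np.asarray(img.dataobj).astype(bool).reshape(grid.shape)
        structures.append(StructureMask(entry["name"], entry["role"], mask))
    return StructureSet(grid=grid, structures=structures)


def save_dose(path, dose: np.ndarray, grid: VoxelGrid) -> None:
    vol = np.asarray(dose, dtype=np.float32).reshape(grid.shape)
    nib.save(nib.Nifti1Image(vol, _affine(grid)), str(path))


def load_dose(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float).ravel()


def write_plan_outputs(directory, result: AutoPlanResult) -> dict[str, Path]:
    """Write dose (NIfTI), fluence (CSV), DVH table (CSV), trace (JSON lines)
    and a metrics report (JSON) for a finished plan."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    out["dose"] = directory / "dose.nii.gz"
    save_dose(out["dose"], result.dose, result.structures.grid)

    out["fluence"] = directory / "fluence.csv"
    pd.DataFrame({"beamlet": np.arange(result.fluence.size),
                  "weight": result.fluence}).to_csv(out["fluence"], index=False)

    frames = [cumulative_dvh(result.dose, s).as_frame()
              for s in result.structures.structures if s.voxel_count]
    out["dvh"] = directory / "dvh.csv"
    pd.concat(frames, ignore_index=True).to_csv(out["dvh"], index=False)

    out["trace"] = directory / "trace.jsonl"
    with open(out["trace"], "w") as fh:
        for rec in result.trace.cycles:
            fh.write(json.dumps(rec.to_dict()) + "\n")

    metrics = PlanMetrics.from_dose(result.dose, result.structures,
                                    result.config.prescription)
    report = {"prescription_gy": result.config.prescription,
              "termination_reason": result.trace.termination_reason,
              "outer_cycles": result.trace.n_cycles,
              "metrics": metrics.table.round(4).to_dict(orient="index")}
    out["metrics"] = directory / "metrics.json"
    out["metrics"].write_text(json.dumps(report, indent=2))
    return out
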