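"""File-based cohort store: a JSON manifest plus one compressed array file.

The bundle is a directory holding ``manifest.json`` (patient ids, structure
names, grid specs, plan metadata, schema version) and ``arrays.npz`` with
the dose grids and binary masks.  Loading validates every array shape
against the manifest; masks round-trip losslessly and dose within float
precision.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .grid import PatientCase, PlanMeta, StructureMask, VoxelGrid

__all__ = ["write_bundle", "read_bundle"]

SCHEMA_VERSION = 1


def _grid_to_json(grid: VoxelGrid) -> dict:
    return {"origin": list(grid.origin), "spacing": list(grid.spacing), "shape": list(grid.shape)}


def _grid_from_json(payload: dict) -> VoxelGrid:
    return VoxelGrid(
        origin=tuple(payload["origin"]),
        spacing=tuple(payload["spacing"]),
        shape=tuple(payload["shape"]),
    )


def write_bundle(cases: Sequence[PatientCase], path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a cohort to a bundle directory (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "patients": [], "extra": extra_meta or {}}
    arrays: dict[str, np.ndarray] = {}
    for case in cases:
        entry = {
            "patient_id": case.patient_id,
            "grid": _grid_to_json(case.grid),
            "structures": [case.ptv.name] + sorted(case.oars),
            "ptv_name": case.ptv.name,
            "has_dose": case.has_dose,
            "meta": {
                "prescription_dose_gy": case.meta.prescription_dose_gy,
                "n_fractions": case.meta.n_fractions,
                "monitor_units": case.meta.monitor_units,
            },
        }
        manifest["patients"].append(entry)
        arrays[f"{case.patient_id}/mask/{case.ptv.name}"] = case.ptv.voxels
        for name in sorted(case.oars):
            arrays[f"{case.patient_id}/mask/{name}"] = case.oars[name].voxels
        if case.has_dose:
            arrays[f"{case.patient_id}/dose"] = case.dose
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    np.savez_compressed(path / "arrays.npz", **arrays)
    return path


def read_bundle(path: str | Path) -> list[PatientCase]:
    """Load a cohort bundle, validating arrays against the manifest."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in bundle {path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"bundle schema version {manifest.get('schema_version')} unsupported"
        )
    with np.load(path / "arrays.npz") as npz:
        cases = []
        for entry in manifest["patients"]:
            pid = entry["patient_id"]
            grid = _grid_from_json(entry["grid"])
            shape = tuple(grid.shape)
            masks = {}
            for name in entry["structures"]:
                key = f"{pid}/mask/{name}"
                if key not in npz:
                    raise ValueError(f"bundle missing array {key!r}")
                arr = npz[key]
                if arr.shape != shape:
                    raise ValueError(f"array {key!r} shape {arr.shape} != manifest {shape}")
                masks[name] = StructureMask(name=name, grid=grid, voxels=arr)
            dose = None
            if entry["has_dose"]:
                key = f"{pid}/dose"
                if key not in npz:
                    raise ValueError(f"bundle missing array {key!r}")
                dose = npz[key]
                if dose.shape != shape:
                    raise ValueError(f"dose shape {dose.shape} != manifest {shape}")
            ptv_name = entry["ptv_name"]
            meta = entry.get("meta", {})
            cases.append(
                PatientCase(
                    patient_id=pid,
                    grid=grid,
                    ptv=masks.pop(ptv_name),
                    oars=masks,
                    dose=dose,
                    meta=PlanMeta(
                        prescription_dose_gy=meta.get("prescription_dose_gy"),
                        n_fractions=meta.get("n_fractions"),
                        monitor_units=meta.get("monitor_units"),
                    ),
                )
            )
    return cases
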