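"""Population dose-distance percentile model.

The training step of the DVH prediction method: per-patient average
dose-distance curves are resampled onto a common distance grid and, at each
grid point, the 25th/50th/75th percentiles across patients are taken.  The
band between the 25th and 75th percentile curves spans the best 25% to 75%
of training plans (lower dose at a fixed distance means better sparing, so
the 25th percentile is the lower prediction bound).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .dose_distance import DoseDistanceCurve

__all__ = ["PopulationModel", "train_population_model", "save_model", "load_model"]

SCHEMA_VERSION = 1

#: Minimum fraction of training patients that must contribute to a distance
#: grid point for the percentiles to be defined there.
DEFAULT_MIN_FRACTION = 0.5


@dataclasses.dataclass
class PopulationModel:
    """Per-OAR 25/50/75 percentile dose-vs-distance curves.

    ``p25``/``p50``/``p75`` are NaN at grid points where fewer than the
    configured fraction of training patients had data.
    """

    oar: str
    distance_grid: np.ndarray
    p25: np.ndarray
    p50: np.ndarray
    p75: np.ndarray
    n_patients: int
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance_grid = np.asarray(self.distance_grid, dtype=float)
        self.p25 = np.asarray(self.p25, dtype=float)
        self.p50 = np.asarray(self.p50, dtype=float)
        self.p75 = np.asarray(self.p75, dtype=float)
        if np.any(np.diff(self.distance_grid) <= 0):
            raise ValueError("distance_grid must be strictly increasing")
        for name in ("p25", "p50", "p75"):
            if getattr(self, name).shape != self.distance_grid.shape:
                raise ValueError(f"{name} must align with distance_grid")
        if self.n_patients < 2:
            raise ValueError("a population model needs at least 2 patients")
        defined = self.defined
        if np.any(self.p25[defined] > self.p50[defined] + 1e-9) or np.any(
            self.p50[defined] > self.p75[defined] + 1e-9
        ):
            raise ValueError("percentile ordering p25 <= p50 <= p75 violated")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.p50)

    def percentile_curve(self, which: int) -> np.ndarray:
        return {25: self.p25, 50: self.p50, 75: self.p75}[which]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationModel):
            return NotImplemented
        return (
            self.oar == other.oar
            and self.n_patients == other.n_patients
            and self.provenance == other.provenance
            and np.array_equal(self.distance_grid, other.distance_grid)
            and all(
                np.array_equal(
                    getattr(self, f), getattr(other, f), equal_nan=True
                )
                for f in ("p25", "p50", "p75")
            )
        )


def _resample_curve(curve: DoseDistanceCurve, grid: np.ndarray) -> np.ndarray:
    """Linearly interpolate a curve's occupied-bin means onto a grid.

    Interpolation only, never extrapolation: grid points outside the curve's
    occupied distance range are NaN.  Interior empty bins are bridged by the
    interpolation between neighbouring occupied bins.
    """
    centers = curve.bin_centers
    occupied = curve.occupancy > 0
    xc = centers[occupied]
    yc = curve.mean_dose[occupied]
    out = np.interp(grid, xc, yc)
    out[(grid < xc[0]) | (grid > xc[-1])] = np.nan
    return out


def train_population_model(
    curves: Sequence[DoseDistanceCurve],
    oar: str,
    percentiles: Sequence[float] = (25, 50, 75),
    min_fraction: float = DEFAULT_MIN_FRACTION,
    provenance: dict | None = None,
) -> PopulationModel:
    """Train the population percentile curves from per-patient curves.

    Parameters
    ----------
    curves
        Per-patient average dose-distance curves for this OAR (at a common
        bin width; curves whose ``oar`` label differs are rejected).
    percentiles
        Three percentile levels, low/median/high; default (25, 50, 75).
    min_fraction
        Grid points where fewer than this fraction of patients contribute
        are left undefined (NaN).
    """
    curves = [c for c in curves]
    if any(c.oar != oar for c in curves):
        raise ValueError(f"all curves must belong to OAR {oar!r}")
    if len(curves) < 2:
        raise ValueError(f"need >= 2 training curves, got {len(curves)}")
    if len(percentiles) != 3 or list(percentiles) != sorted(percentiles):
        raise ValueError("percentiles must be three increasing levels")

    width = curves[0].bin_width
    if any(abs(c.bin_width - width) > 1e-9 for c in curves):
        raise ValueError("training curves must share one bin width")

    occ_centers = [c.bin_centers[c.occupancy > 0] for c in curves]
    lo = min(c[0] for c in occ_centers)
    hi = max(c[-1] for c in occ_centers)
    # Common grid = union extent of the occupied ranges, stepped at the
    # training bin width (alignment of the grid itself is immaterial: each
    # curve is interpolated, never extrapolated, onto it).
    first = np.floor((lo - width / 2) / width) * width + width / 2
    grid = first + np.arange(int(round((hi - first) / width)) + 1) * width

    stacked = np.vstack([_resample_curve(c, grid) for c in curves])
    n_def = np.sum(~np.isnan(stacked), axis=0)
    defined = n_def >= max(2, int(np.ceil(min_fraction * len(curves))))
    if not defined.any():
        raise ValueError("training curves have no overlapping distance support")

    out = np.full((3, grid.size), np.nan)
    cols = np.where(defined)[0]
    for j in cols:
        vals = stacked[:, j]
        vals = vals[~np.isnan(vals)]
        out[:, j] = np.percentile(vals, percentiles, method="linear")

    prov = dict(provenance or {})
    prov.setdefault(
        "patient_ids", [c.patient_id for c in curves if c.patient_id is not None]
    )
    prov.setdefault("bin_width_mm", width)
    prov.setdefault("percentiles", list(float(p) for p in percentiles))
    prov.setdefault("min_fraction", float(min_fraction))
    return PopulationModel(
        oar=oar,
        distance_grid=grid,
        p25=out[0],
        p50=out[1],
        p75=out[2],
        n_patients=len(curves),
        provenance=prov,
    )


def _arr_to_json(a: np.ndarray) -> list:
    return [None if np.isnan(v) else float(v) for v in a]


def _arr_from_json(values: list) -> np.ndarray:
    return np.array([np.nan if v is None else float(v) for v in values])


def save_model(model: PopulationModel, path: str | Path) -> None:
    """Write a model to a schema-versioned JSON file (lossless round trip)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "oar": model.oar,
        "distance_grid_mm": [float(v) for v in model.distance_grid],
        "p25_gy": _arr_to_json(model.p25),
        "p50_gy": _arr_to_json(model.p50),
        "p75_gy": _arr_to_json(model.p75),
        "n_patients": model.n_patients,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> PopulationModel:
    """Load a model saved by :func:`save_model`.

    Raises
    ------
    ValueError
        On schema version mismatch or a corrupt/truncated file.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file {path} is corrupt or truncated: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ValueError(f"model file {path} lacks a schema_version")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {payload['schema_version']} is not "
            f"supported (expected {SCHEMA_VERSION})"
        )
    try:
        return PopulationModel(
            oar=payload["oar"],
            distance_grid=np.asarray(payload["distance_grid_mm"], dtype=float),
            p25=_arr_from_json(payload["p25_gy"]),
            p50=_arr_from_json(payload["p50_gy"]),
            p75=_arr_from_json(payload["p75_gy"]),
            n_patients=int(payload["n_patients"]),
            provenance=payload.get("provenance", {}),
        )
    except KeyError as exc:
        raise ValueError(f"model file {path} is missing field {exc}") from exc
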