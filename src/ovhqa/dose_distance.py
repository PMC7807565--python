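"""Per-patient dose-distance scatter and the average dose-distance relation.

The overlap-volume-histogram view of plan quality: every OAR voxel becomes a
point (signed distance from the PTV, planned dose), and the volume-weighted
mean dose per distance bin is the patient's dose-distance curve.  Steeper
curves indicate better OAR sparing.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grid import PatientCase

__all__ = [
    "DoseDistancePoints",
    "DoseDistanceCurve",
    "dose_distance_points",
    "average_dose_distance_curve",
    "DEFAULT_BIN_WIDTH_MM",
]

#: Default distance bin width (mm); matches a typical dose-grid resolution.
DEFAULT_BIN_WIDTH_MM = 2.5


@dataclasses.dataclass
class DoseDistancePoints:
    """One (distance, dose, volume) point per OAR voxel."""

    oar: str
    distance_mm: np.ndarray
    dose_gy: np.ndarray
    voxel_volume_cm3: np.ndarray
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.voxel_volume_cm3 = np.asarray(self.voxel_volume_cm3, dtype=float)
        n = self.distance_mm.size
        if self.dose_gy.size != n or self.voxel_volume_cm3.size != n:
            raise ValueError("distance, dose and volume arrays must align")

    @property
    def total_volume_cm3(self) -> float:
        return float(self.voxel_volume_cm3.sum())


@dataclasses.dataclass
class DoseDistanceCurve:
    """Volume-weighted mean OAR dose per signed-distance bin.

    ``mean_dose`` is NaN for bins with no occupancy (undefined, never
    zero-filled); ``occupancy`` is the OAR volume (cm^3) falling in each bin,
    so occupancies sum to the OAR volume.
    """

    oar: str
    bin_edges: np.ndarray
    mean_dose: np.ndarray
    occupancy: np.ndarray
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mean_dose = np.asarray(self.mean_dose, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.mean_dose.size != self.bin_edges.size - 1:
            raise ValueError("mean_dose must have one value per bin")
        if self.occupancy.size != self.mean_dose.size:
            raise ValueError("occupancy must have one value per bin")
        if np.any(self.occupancy < 0):
            raise ValueError("occupancy must be >= 0")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.bin_edges)))

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per bin (edge_lo, edge_hi, mean_dose, occupancy)."""
        return pd.DataFrame(
            {
                "edge_lo_mm": self.bin_edges[:-1],
                "edge_hi_mm": self.bin_edges[1:],
                "mean_dose_gy": self.mean_dose,
                "occupancy_cm3": self.occupancy,
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, oar: str, patient_id: str | None = None
    ) -> "DoseDistanceCurve":
        edges = np.append(
            frame["edge_lo_mm"].to_numpy(), frame["edge_hi_mm"].to_numpy()[-1]
        )
        return cls(
            oar=oar,
            bin_edges=edges,
            mean_dose=frame["mean_dose_gy"].to_numpy(),
            occupancy=frame["occupancy_cm3"].to_numpy(),
            patient_id=patient_id,
        )


def dose_distance_points(case: PatientCase, oar: str) -> DoseDistancePoints:
    """Emit the dose-distance point for every voxel of one OAR.

    Each OAR voxel contributes (signed PTV distance, planned dose, voxel
    volume).  OAR voxels overlapping the PTV carry negative distances and are
    kept.
    """
    if not case.has_dose:
        raise ValueError(f"case {case.patient_id!r} has no dose grid")
    mask = case.structure(oar)
    if mask.is_empty():
        raise ValueError(f"OAR {oar!r} mask is empty for case {case.patient_id!r}")
    sel = mask.voxels
    d = case.ptv_distance_map()[sel]
    dose = case.dose[sel]
    vol = np.full(d.size, case.grid.voxel_volume_cm3)
    return DoseDistancePoints(
        oar=oar,
        distance_mm=d,
        dose_gy=dose,
        voxel_volume_cm3=vol,
        patient_id=case.patient_id,
    )


def average_dose_distance_curve(
    points: DoseDistancePoints, bin_width_mm: float = DEFAULT_BIN_WIDTH_MM
) -> DoseDistanceCurve:
    """Volume-weighted mean dose per half-open distance bin.

    Bins are ``[edge, edge + width)`` starting at the minimum observed
    distance and spanning to the maximum, so refining the bin width and
    re-aggregating reproduces the coarse-bin means exactly.
    """
    if bin_width_mm <= 0:
        raise ValueError(f"bin_width_mm must be > 0, got {bin_width_mm}")
    if points.distance_mm.size == 0:
        raise ValueError("no dose-distance points")
    d = points.distance_mm
    w = float(bin_width_mm)
    lo = float(d.min())
    n_bins = int(np.floor((d.max() - lo) / w)) + 1
    edges = lo + np.arange(n_bins + 1) * w
    idx = np.floor((d - lo) / w).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    occ = np.bincount(idx, weights=points.voxel_volume_cm3, minlength=n_bins)
    wdose = np.bincount(
        idx, weights=points.voxel_volume_cm3 * points.dose_gy, minlength=n_bins
    )
    with np.errstate(invalid="ignore"):
        mean = np.where(occ > 0, wdose / np.where(occ > 0, occ, 1.0), np.nan)
    return DoseDistanceCurve(
        oar=points.oar,
        bin_edges=edges,
        mean_dose=mean,
        occupancy=occ,
        patient_id=points.patient_id,
    )
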