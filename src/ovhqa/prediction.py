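"""DVH prediction for a new patient from contours alone.

Every OAR voxel's signed distance from the PTV is looked up in the
population dose-distance percentile curves to obtain a predicted voxel dose;
the inverse cumulative histogram of those doses, weighted on the patient's
own anatomy, is the predicted DVH.  Pushing all voxels through the 25th and
75th percentile curves wholesale yields the prediction band.  No dose
information from the new patient enters the computation.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .grid import PatientCase
from .metrics import (
    DEFAULT_DOSE_BIN_GY,
    DVHCurve,
    MetricSpec,
    cumulative_ge,
    evaluate_metric,
    make_dose_axis,
)
from .population import PopulationModel

logger = logging.getLogger("ovhqa")

__all__ = ["PredictedDVH", "PredictedMetric", "predict_dvh", "predict_metrics"]


@dataclasses.dataclass
class PredictedDVH:
    """Predicted cumulative DVH band (25th/50th/75th percentile curves).

    ``clamped_fraction`` is the fraction of OAR volume whose PTV distance
    fell outside the model's defined range and was clamped to the nearest
    defined grid point; large values signal the model does not cover this
    anatomy.
    """

    oar: str
    dose_axis: np.ndarray
    volume_fraction_p25: np.ndarray
    volume_fraction_p50: np.ndarray
    volume_fraction_p75: np.ndarray
    oar_volume_cm3: float
    clamped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        for name in ("p25", "p50", "p75"):
            arr = np.asarray(getattr(self, f"volume_fraction_{name}"), dtype=float)
            setattr(self, f"volume_fraction_{name}", arr)
            if arr.shape != self.dose_axis.shape:
                raise ValueError("volume fractions must align with dose_axis")
            if np.any(np.diff(arr) > 1e-12) or abs(arr[0] - 1.0) > 1e-12:
                raise ValueError(f"{name} DVH must be non-increasing from 1.0")

    def curve(self, which: int) -> DVHCurve:
        """The predicted DVH for one percentile as a plain :class:`DVHCurve`."""
        vf = {
            25: self.volume_fraction_p25,
            50: self.volume_fraction_p50,
            75: self.volume_fraction_p75,
        }[which]
        return DVHCurve(
            structure=self.oar,
            dose_axis=self.dose_axis,
            volume_fraction=vf,
            structure_volume_cm3=self.oar_volume_cm3,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_gy": self.dose_axis,
                "vf_p25": self.volume_fraction_p25,
                "vf_p50": self.volume_fraction_p50,
                "vf_p75": self.volume_fraction_p75,
            }
        )


@dataclasses.dataclass(frozen=True)
class PredictedMetric:
    """A predicted scalar metric with its 25/75 confidence bounds."""

    oar: str
    name: str
    unit: str
    p25: float
    p50: float
    p75: float

    @property
    def value(self) -> float:
        return self.p50


def predict_dvh(
    case: PatientCase,
    model: PopulationModel,
    oar: str,
    dose_bin_gy: float = DEFAULT_DOSE_BIN_GY,
) -> PredictedDVH:
    """Predict the DVH band for one OAR of a contours-only case.

    Distances below/above the model's defined range are clamped to the
    nearest defined grid point (far voxels receive the lowest defined dose);
    the clamped volume fraction is recorded on the result and logged.
    """
    if model.oar != oar:
        raise ValueError(f"model is for OAR {model.oar!r}, requested {oar!r}")
    mask = case.structure(oar)
    if mask.is_empty():
        raise ValueError(f"OAR {oar!r} mask is empty for case {case.patient_id!r}")

    d = case.ptv_distance_map()[mask.voxels]
    defined = model.defined
    grid = model.distance_grid[defined]
    clamped = float(np.mean((d < grid[0]) | (d > grid[-1])))
    if clamped > 0:
        logger.warning(
            "case %s OAR %s: %.1f%% of volume outside model distance range "
            "[%.1f, %.1f] mm, clamped",
            case.patient_id,
            oar,
            100 * clamped,
            grid[0],
            grid[-1],
        )

    weights = np.full(d.size, case.grid.voxel_volume_cm3)
    voxel_doses = {
        p: np.interp(d, grid, model.percentile_curve(p)[defined]) for p in (25, 50, 75)
    }
    max_dose = max(float(v.max()) for v in voxel_doses.values())
    axis = make_dose_axis(max_dose, dose_bin_gy)
    vfs = {p: cumulative_ge(voxel_doses[p], weights, axis) for p in (25, 50, 75)}
    return PredictedDVH(
        oar=oar,
        dose_axis=axis,
        volume_fraction_p25=vfs[25],
        volume_fraction_p50=vfs[50],
        volume_fraction_p75=vfs[75],
        oar_volume_cm3=mask.volume_cm3,
        clamped_fraction=clamped,
    )


def predict_metrics(pred: PredictedDVH, spec: MetricSpec) -> PredictedMetric:
    """Evaluate a metric on each of the three predicted DVH curves.

    The central value is the median-model (p50) prediction; the 25th/75th
    values are the band bounds, as plotted as error bars in cohort QA.
    """
    vals = {p: evaluate_metric(pred.curve(p), spec) for p in (25, 50, 75)}
    return PredictedMetric(
        oar=pred.oar,
        name=spec.name,
        unit=spec.unit,
        p25=vals[25],
        p50=vals[50],
        p75=vals[75],
    )
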