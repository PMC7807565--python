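"""Achieved DVH curves and scalar plan metrics (Dmean, Dmax, VxGy).

Conventions: cumulative DVHs give the fraction of structure volume receiving
at least each dose level; Dmean is the integral of the cumulative curve over
dose (equal to the volume-weighted mean voxel dose up to half a dose bin);
Dmax is the per-voxel maximum.  Volume metrics come in absolute (cm^3) and
relative (% of structure volume) flavours, e.g. the bowel-bag V45Gy in cm^3
and the bladder V35Gy in %; both the threshold dose and the flavour are
configuration, not code.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .grid import PatientCase

logger = logging.getLogger("ovhqa")

__all__ = [
    "DVHCurve",
    "MetricSpec",
    "achieved_dvh",
    "evaluate_metric",
    "plan_summary",
    "cumulative_ge",
    "DEFAULT_DOSE_BIN_GY",
]

#: Default DVH dose-axis resolution (Gy).
DEFAULT_DOSE_BIN_GY = 0.1

KINDS = ("Dmean", "Dmax", "V_dose_abs_cm3", "V_dose_rel_percent")


@dataclasses.dataclass(frozen=True)
class MetricSpec:
    """A named scalar DVH metric.

    ``kind`` is one of ``Dmean``, ``Dmax``, ``V_dose_abs_cm3`` (absolute
    volume above ``threshold_dose_gy``) or ``V_dose_rel_percent`` (relative
    volume above the threshold).
    """

    name: str
    kind: str
    threshold_dose_gy: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}; expected {KINDS}")
        if self.kind.startswith("V_"):
            if self.threshold_dose_gy is None or self.threshold_dose_gy < 0:
                raise ValueError(f"{self.kind} needs threshold_dose_gy >= 0")

    @property
    def unit(self) -> str:
        return {
            "Dmean": "Gy",
            "Dmax": "Gy",
            "V_dose_abs_cm3": "cm3",
            "V_dose_rel_percent": "%",
        }[self.kind]

    @classmethod
    def dmean(cls) -> "MetricSpec":
        return cls("Dmean", "Dmean")

    @classmethod
    def dmax(cls) -> "MetricSpec":
        return cls("Dmax", "Dmax")

    @classmethod
    def v_abs(cls, threshold_gy: float) -> "MetricSpec":
        return cls(f"V{threshold_gy:g}Gy_cm3", "V_dose_abs_cm3", threshold_gy)

    @classmethod
    def v_rel(cls, threshold_gy: float) -> "MetricSpec":
        return cls(f"V{threshold_gy:g}Gy_%", "V_dose_rel_percent", threshold_gy)


@dataclasses.dataclass
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving >= each dose."""

    structure: str
    dose_axis: np.ndarray
    volume_fraction: np.ndarray
    structure_volume_cm3: float
    #: exact per-voxel maximum, when the curve was built from voxel doses
    max_dose_gy: float | None = None

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_axis[0] != 0 or np.any(np.diff(self.dose_axis) <= 0):
            raise ValueError("dose_axis must increase strictly from 0")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")
        if abs(self.volume_fraction[0] - 1.0) > 1e-12:
            raise ValueError("DVH must start at 1.0 at dose 0")


def cumulative_ge(
    doses: np.ndarray, weights: np.ndarray, dose_axis: np.ndarray
) -> np.ndarray:
    """Weighted fraction of volume with dose >= each axis value (inverse
    cumulative histogram)."""
    order = np.argsort(doses, kind="stable")
    ds = doses[order]
    cum = np.cumsum(weights[order])
    total = cum[-1]
    idx = np.searchsorted(ds, dose_axis, side="left")
    below = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    return (total - below) / total


def make_dose_axis(max_dose: float, dose_bin_gy: float) -> np.ndarray:
    """Dose axis from 0 to just past ``max_dose`` in ``dose_bin_gy`` steps."""
    if dose_bin_gy <= 0:
        raise ValueError(f"dose_bin_gy must be > 0, got {dose_bin_gy}")
    n = int(np.floor(max(max_dose, 0.0) / dose_bin_gy)) + 2
    return np.arange(n) * dose_bin_gy


def achieved_dvh(
    case: PatientCase, structure: str, dose_bin_gy: float = DEFAULT_DOSE_BIN_GY
) -> DVHCurve:
    """Cumulative DVH of the achieved (planned) dose for one structure."""
    if not case.has_dose:
        raise ValueError(f"case {case.patient_id!r} has no dose grid")
    mask = case.structure(structure)
    if mask.is_empty():
        raise ValueError(f"structure {structure!r} mask is empty")
    doses = case.dose[mask.voxels]
    weights = np.full(doses.size, case.grid.voxel_volume_cm3)
    axis = make_dose_axis(float(doses.max()), dose_bin_gy)
    vf = cumulative_ge(doses, weights, axis)
    return DVHCurve(
        structure=structure,
        dose_axis=axis,
        volume_fraction=vf,
        structure_volume_cm3=mask.volume_cm3,
        max_dose_gy=float(doses.max()),
    )


def evaluate_metric(dvh: DVHCurve, spec: MetricSpec) -> float:
    """Evaluate a scalar metric on a cumulative DVH curve.

    Thresholds are evaluated by linear interpolation on the dose axis; a
    threshold beyond the axis returns 0 with a warning.
    """
    axis, vf = dvh.dose_axis, dvh.volume_fraction
    if spec.kind == "Dmean":
        return float(np.trapezoid(vf, axis))
    if spec.kind == "Dmax":
        if dvh.max_dose_gy is not None:
            return float(dvh.max_dose_gy)
        pos = vf > 0
        return float(axis[pos][-1]) if pos.any() else 0.0
    thr = float(spec.threshold_dose_gy)
    if thr > axis[-1]:
        logger.warning(
            "threshold %.3g Gy beyond DVH dose axis (max %.3g Gy); returning 0",
            thr,
            axis[-1],
        )
        frac = 0.0
    else:
        frac = float(np.interp(thr, axis, vf))
    if spec.kind == "V_dose_abs_cm3":
        return frac * dvh.structure_volume_cm3
    return 100.0 * frac


@dataclasses.dataclass
class PlanSummary:
    """Per-structure metric table plus plan-level MU statistics."""

    patient_id: str
    prescription_dose_gy: float | None
    n_fractions: int | None
    monitor_units: float | None
    mu_per_gy: float | None
    table: pd.DataFrame
    missing_structures: list[str]


def plan_summary(
    case: PatientCase,
    goal_config: dict[str, list[MetricSpec]],
    dose_bin_gy: float = DEFAULT_DOSE_BIN_GY,
) -> PlanSummary:
    """Evaluate a goal sheet (structure -> metric specs) on one plan.

    Structures missing from the case are reported, not fatal.  MU and MU per
    Gy of prescription dose are copied from the plan metadata.
    """
    rows = []
    missing: list[str] = []
    for structure, specs in goal_config.items():
        try:
            dvh = achieved_dvh(case, structure, dose_bin_gy)
        except KeyError:
            missing.append(structure)
            logger.warning(
                "case %s: structure %r missing, metrics skipped",
                case.patient_id,
                structure,
            )
            continue
        for spec in specs:
            rows.append(
                {
                    "structure": structure,
                    "metric": spec.name,
                    "value": evaluate_metric(dvh, spec),
                    "unit": spec.unit,
                }
            )
    meta = case.meta
    return PlanSummary(
        patient_id=case.patient_id,
        prescription_dose_gy=meta.prescription_dose_gy,
        n_fractions=meta.n_fractions,
        monitor_units=meta.monitor_units,
        mu_per_gy=meta.mu_per_gy,
        table=pd.DataFrame(rows, columns=["structure", "metric", "value", "unit"]),
        missing_structures=missing,
    )
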