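"""Synthetic pelvic phantom cohorts for training and validating the model.

Each phantom carries one PTV (a GTV ellipsoid expanded by the clinical
5 mm GTV->CTV and 10 mm CTV->PTV margins) and two OARs: a bladder ellipsoid
anterior-inferior to the target and a large bowel-bag ellipsoid superior to
it.  The dose field is the prescription (50 Gy in 25 fractions) inside the
PTV and falls off exponentially with the signed PTV distance outside,
``D(x) = D_rx * exp(-d(x)/tau)``, with a per-patient fall-off scale tau and
optional additive Gaussian noise.  Patient-to-patient variability covers
target position/size, bladder filling, bowel size, fall-off steepness and
monitor units.

The generator reproduces the geometric premise of the dose-distance model
(dose decreases monotonically with distance from the PTV); it makes no
attempt at realistic VMAT dose calculation.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose_distance import DEFAULT_BIN_WIDTH_MM, DoseDistanceCurve
from .grid import PatientCase, PlanMeta, StructureMask, VoxelGrid, signed_distance_map

__all__ = [
    "EllipsoidSpec",
    "PhantomSpec",
    "CohortVariability",
    "SyntheticCohort",
    "default_spec",
    "dilate_mm",
    "generate_patient",
    "generate_cohort",
    "synthetic_curve_cohort",
]


@dataclasses.dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid: center and semi-axes in mm, (z, y, x) order."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semiaxes_mm):
            raise ValueError("ellipsoid semi-axes must be > 0")

    def scaled(self, factor: float, offset: Sequence[float] = (0, 0, 0)) -> "EllipsoidSpec":
        return EllipsoidSpec(
            center_mm=tuple(c + o for c, o in zip(self.center_mm, offset)),
            semiaxes_mm=tuple(s * factor for s in self.semiaxes_mm),
        )


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom: geometry, margins and dose model."""

    grid: VoxelGrid
    gtv: EllipsoidSpec
    oars: dict[str, EllipsoidSpec]
    gtv_to_ctv_mm: float = 5.0
    ctv_to_ptv_mm: float = 10.0
    prescription_dose_gy: float = 50.0
    n_fractions: int = 25
    tau_mm: float = 30.0
    noise_sd_gy: float = 0.5
    monitor_units: float = 520.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_mm <= 0:
            raise ValueError("tau_mm must be > 0")
        if self.noise_sd_gy < 0:
            raise ValueError("noise_sd_gy must be >= 0")
        if self.gtv_to_ctv_mm < 0 or self.ctv_to_ptv_mm < 0:
            raise ValueError("margins must be >= 0")


def default_spec(seed: int = 0) -> PhantomSpec:
    """The reference pelvic phantom: 2.5 mm grid, rectal-target geometry."""
    grid = VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=(2.5, 2.5, 2.5), shape=(80, 120, 120))
    return PhantomSpec(
        grid=grid,
        gtv=EllipsoidSpec(center_mm=(95.0, 160.0, 148.75), semiaxes_mm=(22.0, 20.0, 18.0)),
        oars={
            "bladder": EllipsoidSpec(
                center_mm=(90.0, 103.0, 148.75), semiaxes_mm=(28.0, 32.0, 30.0)
            ),
            "bowel_bag": EllipsoidSpec(
                center_mm=(140.0, 140.0, 148.75), semiaxes_mm=(50.0, 55.0, 55.0)
            ),
        },
        seed=seed,
    )


def _ellipsoid_mask(grid: VoxelGrid, ell: EllipsoidSpec) -> np.ndarray:
    zz = (grid.axis_coords(0) - ell.center_mm[0]) / ell.semiaxes_mm[0]
    yy = (grid.axis_coords(1) - ell.center_mm[1]) / ell.semiaxes_mm[1]
    xx = (grid.axis_coords(2) - ell.center_mm[2]) / ell.semiaxes_mm[2]
    return (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    ) <= 1.0


def dilate_mm(mask: np.ndarray, margin_mm: float, grid: VoxelGrid) -> np.ndarray:
    """Isotropic morphological dilation by a metric margin.

    Implemented as thresholding the exact Euclidean distance transform of
    the exterior: a voxel joins the dilated set iff its center lies within
    ``margin_mm`` of a set voxel center.
    """
    if margin_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    return mask | (dist <= margin_mm)


def generate_patient(spec: PhantomSpec, patient_index: int = 0) -> PatientCase:
    """Build one phantom: masks, margins, dose and metadata.

    Deterministic given ``(spec.seed, patient_index)``; the only random
    element is the additive dose noise.
    """
    grid = spec.grid
    gtv = _ellipsoid_mask(grid, spec.gtv)
    if not gtv.any():
        raise ValueError("GTV ellipsoid lies outside the grid")
    ctv = dilate_mm(gtv, spec.gtv_to_ctv_mm, grid)
    ptv = dilate_mm(ctv, spec.ctv_to_ptv_mm, grid)
    border = (
        ptv[0].any()
        or ptv[-1].any()
        or ptv[:, 0].any()
        or ptv[:, -1].any()
        or ptv[:, :, 0].any()
        or ptv[:, :, -1].any()
    )
    if border:
        raise ValueError("PTV exceeds the grid; enlarge the grid or shrink the target")

    ptv_mask = StructureMask(name="ptv", grid=grid, voxels=ptv)
    oars = {}
    for name, ell in spec.oars.items():
        voxels = _ellipsoid_mask(grid, ell)
        if not voxels.any():
            raise ValueError(f"OAR {name!r} ellipsoid lies outside the grid")
        oars[name] = StructureMask(name=name, grid=grid, voxels=voxels)

    d = signed_distance_map(ptv_mask)
    dose = np.where(
        d <= 0, spec.prescription_dose_gy, spec.prescription_dose_gy * np.exp(-d / spec.tau_mm)
    )
    if spec.noise_sd_gy > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), int(patient_index)])
        )
        dose = dose + rng.normal(0.0, spec.noise_sd_gy, size=dose.shape)
    dose = np.clip(dose, 0.0, None)

    case = PatientCase(
        patient_id=f"SYN{patient_index:03d}",
        grid=grid,
        ptv=ptv_mask,
        oars=oars,
        dose=dose,
        meta=PlanMeta(
            prescription_dose_gy=spec.prescription_dose_gy,
            n_fractions=spec.n_fractions,
            monitor_units=spec.monitor_units,
        ),
    )
    case._ptv_distance = d
    return case


@dataclasses.dataclass(frozen=True)
class CohortVariability:
    """Patient-to-patient variability of the phantom generator.

    Center offsets are Gaussian per axis (mm); sizes vary by a multiplicative
    Gaussian scale (clipped to keep shapes valid); the dose fall-off scale
    tau is uniform over ``tau_range_mm``; the bladder carries its own,
    larger, size variability to emulate different levels of bladder filling.
    """

    center_offset_sd_mm: float = 3.0
    size_scale_sd: float = 0.08
    bladder_scale_sd: float = 0.15
    tau_range_mm: tuple[float, float] = (25.0, 35.0)
    mu_mean: float = 520.0
    mu_sd: float = 45.0

    def __post_init__(self) -> None:
        if min(self.center_offset_sd_mm, self.size_scale_sd, self.bladder_scale_sd, self.mu_sd) < 0:
            raise ValueError("variability scales must be >= 0")
        lo, hi = self.tau_range_mm
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("tau_range_mm must be positive with lo <= hi")
        if self.mu_mean <= 0:
            raise ValueError("mu_mean must be > 0")


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort plus the per-patient parameter log."""

    cases: list[PatientCase]
    params: pd.DataFrame

    def __iter__(self):
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    variability: CohortVariability | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate ``n`` independent phantoms around a base specification.

    Per-patient parameters are drawn from sub-streams keyed by
    ``(seed, patient_index)``, so extending a cohort never re-randomizes
    earlier patients.  The drawn parameters are returned as a log for
    parameter-recovery checks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec if base_spec is not None else default_spec()
    var = variability if variability is not None else CohortVariability()
    master_seed = int(base.seed if seed is None else seed)

    cases: list[PatientCase] = []
    rows = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, i, 101]))
        gtv_offset = rng.normal(0.0, var.center_offset_sd_mm, size=3)
        gtv_scale = float(np.clip(1.0 + rng.normal(0.0, var.size_scale_sd), 0.75, 1.3))
        tau = float(rng.uniform(*var.tau_range_mm))
        mu = float(max(rng.normal(var.mu_mean, var.mu_sd), 100.0))
        oars = {}
        oar_scales = {}
        for name, ell in base.oars.items():
            offset = rng.normal(0.0, var.center_offset_sd_mm, size=3)
            sd = var.bladder_scale_sd if name == "bladder" else var.size_scale_sd
            scale = float(np.clip(1.0 + rng.normal(0.0, sd), 0.5, 1.6))
            oars[name] = ell.scaled(scale, offset)
            oar_scales[name] = scale
        spec_i = dataclasses.replace(
            base,
            gtv=base.gtv.scaled(gtv_scale, gtv_offset),
            oars=oars,
            tau_mm=tau,
            monitor_units=mu,
            seed=master_seed,
        )
        case = generate_patient(spec_i, i)
        cases.append(case)
        rows.append(
            {
                "patient_id": case.patient_id,
                "tau_mm": tau,
                "gtv_scale": gtv_scale,
                "monitor_units": mu,
                **{f"{name}_scale": s for name, s in oar_scales.items()},
            }
        )
    return SyntheticCohort(cases=cases, params=pd.DataFrame(rows))


def synthetic_curve_cohort(
    n: int,
    tau_range_mm: tuple[float, float] = (25.0, 35.0),
    noise_sd_gy: float = 0.5,
    prescription_dose_gy: float = 50.0,
    d_min_mm: float = -10.0,
    d_max_mm: float = 60.0,
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM,
    oar: str = "oar",
    seed: int = 0,
) -> tuple[list[DoseDistanceCurve], np.ndarray]:
    """Analytic dose-distance curves for model-recovery checks.

    Each curve is the plateau-plus-exponential profile evaluated at the bin
    centers, ``D_rx`` for d <= 0 and ``D_rx * exp(-d/tau_i)`` beyond, with
    i.i.d. Gaussian noise per bin; tau_i ~ Uniform(tau_range).  Returns the
    curves and the drawn tau values.
    """
    w = float(bin_width_mm)
    lo = np.floor(d_min_mm / w) * w
    n_bins = int(np.floor((d_max_mm - lo) / w)) + 1
    edges = lo + np.arange(n_bins + 1) * w
    centers = 0.5 * (edges[:-1] + edges[1:])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    taus = rng.uniform(*tau_range_mm, size=n)
    curves = []
    for i, tau in enumerate(taus):
        dose = np.where(
            centers <= 0,
            prescription_dose_gy,
            prescription_dose_gy * np.exp(-np.maximum(centers, 0.0) / tau),
        )
        dose = dose + rng.normal(0.0, noise_sd_gy, size=dose.shape)
        curves.append(
            DoseDistanceCurve(
                oar=oar,
                bin_edges=edges,
                mean_dose=np.clip(dose, 0.0, None),
                occupancy=np.ones(n_bins),
                patient_id=f"CURVE{i:03d}",
            )
        )
    return curves, taus
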