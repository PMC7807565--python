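"""Voxel-grid data model, contour rasterization and signed PTV distance maps.

All arrays are indexed ``(slice, row, col)`` = ``(z, y, x)``; origin and
spacing follow the same axis order, in millimetres.  The world coordinate of
voxel index ``(i, j, k)`` is ``origin + index * spacing`` (voxel-center
convention), so the mapping between indices and patient coordinates is
invertible.  When reading DICOM the patient axes are LPS.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger("ovhqa")

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "PlanMeta",
    "PatientCase",
    "rasterize_contours",
    "signed_distance_map",
    "resample_to_grid",
]


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D grid shared by dose and structure masks.

    Parameters
    ----------
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0), in
        (z, y, x) order.
    spacing : tuple of float
        Voxel spacing in mm per axis, (z, y, x); all strictly positive.
    shape : tuple of int
        Number of voxels per axis, (slices, rows, cols).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def index_to_world(self, index: Sequence[float]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, world: Sequence[float]) -> np.ndarray:
        """Continuous (fractional) voxel index of a world point."""
        return (np.asarray(world) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclasses.dataclass
class StructureMask:
    """Binary mask of a delineated structure on a :class:`VoxelGrid`."""

    name: str
    grid: VoxelGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match grid {self.grid.shape}"
            )

    @property
    def volume_cm3(self) -> float:
        return int(self.voxels.sum()) * self.grid.voxel_volume_cm3

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())


@dataclasses.dataclass
class PlanMeta:
    """Plan metadata carried alongside the dose grid."""

    prescription_dose_gy: float | None = None
    n_fractions: int | None = None
    monitor_units: float | None = None

    @property
    def mu_per_gy(self) -> float | None:
        if self.monitor_units is None or not self.prescription_dose_gy:
            return None
        return self.monitor_units / self.prescription_dose_gy


@dataclasses.dataclass
class PatientCase:
    """PTV/OAR masks plus optional dose grid and plan metadata for one patient.

    All masks and the dose array live on the single master grid; structures
    delivered on a different grid must be resampled first
    (:func:`resample_to_grid`).
    """

    patient_id: str
    grid: VoxelGrid
    ptv: StructureMask
    oars: dict[str, StructureMask] = dataclasses.field(default_factory=dict)
    dose: np.ndarray | None = None
    meta: PlanMeta = dataclasses.field(default_factory=PlanMeta)
    _ptv_distance: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.ptv.grid != self.grid:
            raise ValueError("PTV mask grid differs from case grid")
        for name, mask in self.oars.items():
            if mask.grid != self.grid:
                raise ValueError(f"OAR {name!r} grid differs from case grid")
        if self.dose is not None:
            self.dose = np.asarray(self.dose, dtype=float)
            if self.dose.shape != self.grid.shape:
                raise ValueError("dose shape does not match grid")
            if np.any(self.dose < 0):
                raise ValueError("dose values must be >= 0")

    @property
    def has_dose(self) -> bool:
        return self.dose is not None

    def structure(self, label: str) -> StructureMask:
        """Look up a structure by canonical label (the PTV or an OAR)."""
        if label == self.ptv.name:
            return self.ptv
        try:
            return self.oars[label]
        except KeyError:
            raise KeyError(
                f"case {self.patient_id!r} has no structure {label!r}; "
                f"available: {[self.ptv.name, *self.oars]}"
            ) from None

    def ptv_distance_map(self) -> np.ndarray:
        """Signed distance (mm) from the PTV surface, cached per case."""
        if self._ptv_distance is None:
            self._ptv_distance = signed_distance_map(self.ptv)
        return self._ptv_distance

    def without_dose(self) -> "PatientCase":
        """Contours-only copy of the case (dose and MU stripped)."""
        return PatientCase(
            patient_id=self.patient_id,
            grid=self.grid,
            ptv=self.ptv,
            oars=dict(self.oars),
            dose=None,
            meta=PlanMeta(
                prescription_dose_gy=self.meta.prescription_dose_gy,
                n_fractions=self.meta.n_fractions,
            ),
        )


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd ray-cast containment of grid points in one closed polygon.

    Standard half-open crossing rule: a ray toward +x toggles on edges whose
    y-span half-openly brackets the point, so shared edges between adjacent
    polygons are never double-counted and the result is deterministic for
    points lying exactly on an edge.
    """
    X = xs[None, :]
    Y = ys[:, None]
    inside = np.zeros((ys.size, xs.size), dtype=bool)
    x0, y0 = verts[-1]
    for x1, y1 in verts:
        if y0 != y1:
            cond = (y0 > Y) != (y1 > Y)
            xint = x0 + (Y - y0) * (x1 - x0) / (y1 - y0)
            inside ^= cond & (X < xint)
        x0, y0 = x1, y1
    return inside


def rasterize_contours(
    contours: Iterable[tuple[float, np.ndarray]],
    grid: VoxelGrid,
    name: str = "structure",
) -> StructureMask:
    """Rasterize closed planar contours onto a grid.

    Parameters
    ----------
    contours : iterable of (z_mm, vertices)
        Each item is the axial plane position in mm and an (N, 2) array of
        (x, y) vertex coordinates in mm of one closed, non-self-intersecting
        polygon.  Multiple polygons on one slice are XOR-combined, which
        represents holes.
    grid : VoxelGrid
        Target grid; a voxel is set iff its center is contained (even-odd
        rule) in the polygon of its slice.

    Raises
    ------
    ValueError
        If a polygon has fewer than 3 vertices or its z position does not
        match any grid slice within half a slice spacing.
    """
    voxels = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(2)
    ys = grid.axis_coords(1)
    dz = grid.spacing[0]
    for z, verts in contours:
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ValueError("contour vertices must be an (N, 2) array of (x, y) mm")
        if len(verts) >= 2 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(f"polygon at z={z} mm has fewer than 3 vertices")
        k = int(round((z - grid.origin[0]) / dz))
        if k < 0 or k >= grid.shape[0] or abs(z - (grid.origin[0] + k * dz)) > dz / 2 + 1e-9:
            raise ValueError(f"contour z={z} mm does not match any grid slice")
        voxels[k] ^= _points_in_polygon(xs, ys, verts)
    return StructureMask(name=name, grid=grid, voxels=voxels)


def signed_distance_map(ptv: StructureMask) -> np.ndarray:
    """Signed Euclidean distance (mm) from each voxel center to the PTV.

    Negative inside the PTV, positive outside; the magnitude is the distance
    to the nearest voxel center of the opposite class, computed with two
    exact distance transforms using the anisotropic voxel spacing.
    """
    m = ptv.voxels
    if not m.any():
        raise ValueError("PTV mask is empty")
    if m.all():
        raise ValueError("PTV mask fills the whole grid; no exterior voxels")
    sampling = ptv.grid.spacing
    outside = ndimage.distance_transform_edt(~m, sampling=sampling)
    inside = ndimage.distance_transform_edt(m, sampling=sampling)
    return np.where(m, -inside, outside)


def resample_to_grid(
    values: np.ndarray,
    source: VoxelGrid,
    target: VoxelGrid,
    mode: str = "trilinear",
) -> tuple[np.ndarray, int]:
    """Resample an array from one grid onto another.

    ``mode='trilinear'`` is for dose, ``mode='nearest'`` for masks.  Target
    voxel centers outside the source extent are set to 0; their count is
    returned and a warning logged.

    Returns
    -------
    (resampled, n_outside)

    Raises
    ------
    ValueError
        If no target voxel center lies inside the source extent.
    """
    values = np.asarray(values)
    if values.shape != source.shape:
        raise ValueError("array shape does not match source grid")
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown mode {mode!r}")

    frac = [
        (target.axis_coords(ax) - source.origin[ax]) / source.spacing[ax]
        for ax in range(3)
    ]
    inb = [
        (f >= -1e-9) & (f <= source.shape[ax] - 1 + 1e-9) for ax, f in enumerate(frac)
    ]
    outside_mask = ~(
        inb[0][:, None, None] & inb[1][None, :, None] & inb[2][None, None, :]
    )
    n_outside = int(outside_mask.sum())
    if n_outside == np.prod(target.shape):
        raise ValueError("source and target grid extents are disjoint")
    if n_outside:
        logger.warning(
            "resample_to_grid: %d target voxels outside source extent set to 0",
            n_outside,
        )

    coords = np.meshgrid(*frac, indexing="ij")
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        values.astype(float), np.stack(coords), order=order, mode="nearest"
    )
    out[outside_mask] = 0.0
    if values.dtype == bool:
        out = out.astype(bool) if mode == "nearest" else out
    return out, n_outside
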