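"""Shared fixtures: small synthetic cases and the session-scoped cohorts.

The cohort fixtures reproduce the package's reference self-consistency
experiment (22 training phantoms, 30 validation phantoms, fixed seeds) once
per session; everything else runs on small hand-built grids.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ovhqa.dose_distance import average_dose_distance_curve, dose_distance_points
from ovhqa.grid import PatientCase, PlanMeta, StructureMask, VoxelGrid
from ovhqa.phantoms import (
    CohortVariability,
    EllipsoidSpec,
    PhantomSpec,
    generate_cohort,
)
from ovhqa.population import train_population_model
from ovhqa.qa import compare_predicted_achieved, default_metric_specs

TRAIN_SEED = 11
VAL_SEED = 22
OARS = ("bowel_bag", "bladder")


def make_case(
    dose=None,
    ptv_slice=(slice(3, 7), slice(3, 7), slice(3, 7)),
    oar_voxels=None,
    shape=(10, 10, 10),
    spacing=(2.0, 2.0, 2.0),
    patient_id="T",
    meta=None,
) -> PatientCase:
    """A small cubic-PTV case; ``oar_voxels`` is a list of index triples."""
    grid = VoxelGrid(origin=(0, 0, 0), spacing=spacing, shape=shape)
    ptv = np.zeros(shape, dtype=bool)
    ptv[ptv_slice] = True
    oar = np.zeros(shape, dtype=bool)
    if oar_voxels is None:
        oar[~ptv] = True
        oar[0] = oar[-1] = False
    else:
        for idx in oar_voxels:
            oar[idx] = True
    return PatientCase(
        patient_id=patient_id,
        grid=grid,
        ptv=StructureMask("ptv", grid, ptv),
        oars={"oar": StructureMask("oar", grid, oar)},
        dose=dose,
        meta=meta or PlanMeta(),
    )


def small_phantom_spec(seed: int = 0, noise_sd_gy: float = 0.5) -> PhantomSpec:
    """A compact phantom (3 mm grid) for fast unit and I/O tests."""
    grid = VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=(3.0, 3.0, 3.0), shape=(40, 64, 64))
    return PhantomSpec(
        grid=grid,
        gtv=EllipsoidSpec(center_mm=(58.0, 115.0, 94.5), semiaxes_mm=(13.0, 12.0, 11.0)),
        oars={
            "bladder": EllipsoidSpec(center_mm=(55.0, 70.0, 94.5), semiaxes_mm=(18.0, 20.0, 19.0)),
            "bowel_bag": EllipsoidSpec(center_mm=(95.0, 100.0, 94.5), semiaxes_mm=(20.0, 30.0, 30.0)),
        },
        noise_sd_gy=noise_sd_gy,
        seed=seed,
    )


@pytest.fixture(scope="session")
def training_cohort():
    return generate_cohort(22, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def models(training_cohort):
    out = {}
    for oar in OARS:
        curves = [
            average_dose_distance_curve(dose_distance_points(c, oar))
            for c in training_cohort
        ]
        out[oar] = train_population_model(curves, oar)
    return out


@pytest.fixture(scope="session")
def validation_cohort():
    return generate_cohort(30, seed=VAL_SEED)


@pytest.fixture(scope="session")
def validation_records(models, validation_cohort):
    return compare_predicted_achieved(
        validation_cohort.cases, models, default_metric_specs()
    )


@pytest.fixture(scope="session")
def wide_bladder_records(models):
    """Validation arm with doubled bladder-size variance, coupled seed."""
    base = CohortVariability()
    wide = dataclasses.replace(
        base, bladder_scale_sd=base.bladder_scale_sd * np.sqrt(2.0)
    )
    cohort = generate_cohort(30, variability=wide, seed=VAL_SEED)
    from ovhqa.metrics import MetricSpec

    return compare_predicted_achieved(
        cohort.cases,
        {"bladder": models["bladder"]},
        {"bladder": [MetricSpec.dmean()]},
    )
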