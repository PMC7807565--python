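"""Cohort-level QA: predicted-vs-achieved deltas, summaries and comparisons.

Produces the per-patient delta records and the cohort tables (mean +/- SD,
min-max range, paired t-test) used to judge a planning technique against the
population model, plus two-cohort comparisons of achieved-metric
interquartile ranges and monitor-unit distributions.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import PatientCase
from .metrics import DEFAULT_DOSE_BIN_GY, MetricSpec, achieved_dvh, evaluate_metric
from .population import PopulationModel
from .prediction import predict_dvh, predict_metrics

logger = logging.getLogger("ovhqa")

__all__ = [
    "DeltaRecord",
    "CohortReport",
    "CohortComparison",
    "default_metric_specs",
    "compare_predicted_achieved",
    "summarize_cohort",
    "compare_cohorts",
    "compare_mu",
    "records_to_frame",
]


def default_metric_specs() -> dict[str, list[MetricSpec]]:
    """The validation metrics: mean dose per OAR, plus bowel-bag V45Gy in
    cm^3 and bladder V35Gy in % of bladder volume."""
    return {
        "bowel_bag": [MetricSpec.dmean(), MetricSpec.v_abs(45.0)],
        "bladder": [MetricSpec.dmean(), MetricSpec.v_rel(35.0)],
    }


@dataclasses.dataclass(frozen=True)
class DeltaRecord:
    """Predicted-vs-achieved result for one (patient, OAR, metric).

    ``delta`` is predicted_p50 - achieved (model under-prediction is
    negative).  ``normalized_delta`` (percent of the patient's own OAR
    volume) is present only for volume metrics: for absolute-volume metrics
    it is delta / volume x 100; relative-volume deltas are already a percent
    of the structure volume and pass through unchanged.
    """

    patient_id: str
    oar: str
    metric: str
    unit: str
    predicted_p25: float
    predicted_p50: float
    predicted_p75: float
    achieved: float
    delta: float
    normalized_delta: float | None
    oar_volume_cm3: float


def records_to_frame(records: Sequence[DeltaRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def compare_predicted_achieved(
    cases: Sequence[PatientCase],
    models: Mapping[str, PopulationModel],
    metric_specs: Mapping[str, Sequence[MetricSpec]] | None = None,
    dose_bin_gy: float = DEFAULT_DOSE_BIN_GY,
) -> list[DeltaRecord]:
    """Predict contours-only and compare against the achieved dose, per
    patient, OAR and metric.

    Patients missing a structure are skipped for that OAR with a log line,
    never fatally.
    """
    if metric_specs is None:
        metric_specs = {oar: [MetricSpec.dmean()] for oar in models}
    records: list[DeltaRecord] = []
    for case in sorted(cases, key=lambda c: c.patient_id):
        if not case.has_dose:
            raise ValueError(f"case {case.patient_id!r} has no dose grid")
        for oar, model in models.items():
            if oar not in case.oars or case.oars[oar].is_empty():
                logger.warning(
                    "case %s: OAR %s absent/empty, skipped", case.patient_id, oar
                )
                continue
            pred = predict_dvh(case, model, oar, dose_bin_gy)
            dvh = achieved_dvh(case, oar, dose_bin_gy)
            for spec in metric_specs.get(oar, []):
                pm = predict_metrics(pred, spec)
                achieved = evaluate_metric(dvh, spec)
                delta = pm.p50 - achieved
                if spec.kind == "V_dose_abs_cm3":
                    norm = delta / dvh.structure_volume_cm3 * 100.0
                elif spec.kind == "V_dose_rel_percent":
                    norm = delta
                else:
                    norm = None
                records.append(
                    DeltaRecord(
                        patient_id=case.patient_id,
                        oar=oar,
                        metric=spec.name,
                        unit=spec.unit,
                        predicted_p25=pm.p25,
                        predicted_p50=pm.p50,
                        predicted_p75=pm.p75,
                        achieved=achieved,
                        delta=delta,
                        normalized_delta=norm,
                        oar_volume_cm3=dvh.structure_volume_cm3,
                    )
                )
    return records


@dataclasses.dataclass
class CohortReport:
    """Per-metric cohort summary in Mean +/- SD / Range (min-max) form.

    ``table`` columns: oar, metric, n, mean_delta, sd_delta, min_delta,
    max_delta, mean_normalized_delta, sd_normalized_delta, p_paired,
    degenerate, achieved_p25/p50/p75, achieved_iqr.  ``p_paired`` is the
    two-sided paired t-test of predicted_p50 vs achieved; when the
    difference vector is constant the test is degenerate and the p-value is
    reported as NaN with ``degenerate`` flagged, never silently as 1.0.
    """

    cohort: str
    table: pd.DataFrame
    n_records: int
    achieved_values: dict[tuple[str, str], np.ndarray]
    mu_values: np.ndarray | None = None

    @property
    def mu_percentiles(self) -> dict[int, float] | None:
        if self.mu_values is None or self.mu_values.size == 0:
            return None
        p = np.percentile(self.mu_values, [25, 50, 75], method="linear")
        return {25: float(p[0]), 50: float(p[1]), 75: float(p[2])}


def _paired_p(pred: np.ndarray, ach: np.ndarray) -> tuple[float, bool]:
    diff = pred - ach
    if diff.size < 2 or np.ptp(diff) == 0:
        return float("nan"), True
    return float(stats.ttest_rel(pred, ach).pvalue), False


def summarize_cohort(
    records: Sequence[DeltaRecord],
    cohort: str = "cohort",
    monitor_units: Sequence[float] | None = None,
) -> CohortReport:
    """Aggregate delta records into the cohort QA report."""
    if not records:
        raise ValueError("no records to summarize")
    frame = records_to_frame(records)
    rows = []
    achieved_values: dict[tuple[str, str], np.ndarray] = {}
    for (oar, metric), grp in frame.groupby(["oar", "metric"], sort=True):
        d = grp["delta"].to_numpy()
        ach = grp["achieved"].to_numpy()
        achieved_values[(oar, metric)] = ach
        n = d.size
        if n < 2:
            logger.warning("%s/%s: n=%d < 2, SD and p-value unavailable", oar, metric, n)
        p, degen = _paired_p(grp["predicted_p50"].to_numpy(), ach)
        norm = grp["normalized_delta"].dropna().to_numpy()
        q = np.percentile(ach, [25, 50, 75], method="linear")
        rows.append(
            {
                "oar": oar,
                "metric": metric,
                "unit": grp["unit"].iloc[0],
                "n": n,
                "mean_delta": float(d.mean()),
                "sd_delta": float(d.std(ddof=1)) if n >= 2 else float("nan"),
                "min_delta": float(d.min()),
                "max_delta": float(d.max()),
                "mean_normalized_delta": float(norm.mean()) if norm.size else float("nan"),
                "sd_normalized_delta": (
                    float(norm.std(ddof=1)) if norm.size >= 2 else float("nan")
                ),
                "p_paired": p if n >= 2 else float("nan"),
                "degenerate": degen,
                "achieved_p25": float(q[0]),
                "achieved_p50": float(q[1]),
                "achieved_p75": float(q[2]),
                "achieved_iqr": float(q[2] - q[0]),
            }
        )
    mu = None
    if monitor_units is not None:
        mu = np.asarray([m for m in monitor_units if m is not None], dtype=float)
    return CohortReport(
        cohort=cohort,
        table=pd.DataFrame(rows),
        n_records=len(records),
        achieved_values=achieved_values,
        mu_values=mu,
    )


@dataclasses.dataclass(frozen=True)
class CohortComparison:
    """IQR and two-sample t-test comparison of one achieved metric."""

    oar: str
    metric: str
    iqr_a: float
    iqr_b: float
    iqr_ratio: float
    p_two_sample: float


def compare_cohorts(
    report_a: CohortReport, report_b: CohortReport, oar: str, metric: str
) -> CohortComparison:
    """Compare the achieved-value spread of a metric between two cohorts.

    IQR is p75 - p25 with linear-interpolation percentiles; the t-test is
    Student's two-sample (equal variance), two-sided, on the per-patient
    achieved values.
    """
    key = (oar, metric)
    for rep in (report_a, report_b):
        if key not in rep.achieved_values or rep.achieved_values[key].size == 0:
            raise ValueError(f"cohort {rep.cohort!r} has no values for {key}")
    a = report_a.achieved_values[key]
    b = report_b.achieved_values[key]
    iqr_a = float(np.subtract(*np.percentile(a, [75, 25], method="linear")))
    iqr_b = float(np.subtract(*np.percentile(b, [75, 25], method="linear")))
    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return CohortComparison(
        oar=oar,
        metric=metric,
        iqr_a=iqr_a,
        iqr_b=iqr_b,
        iqr_ratio=iqr_a / iqr_b if iqr_b else float("inf"),
        p_two_sample=p,
    )


def compare_mu(
    mu_a: Sequence[float], mu_b: Sequence[float], label_a: str = "a", label_b: str = "b"
) -> pd.DataFrame:
    """Monitor-unit distribution comparison at the 25th/50th/75th percentiles.

    One row per percentile with both cohort values and the percent
    difference of cohort a relative to cohort b.
    """
    a = np.asarray(mu_a, dtype=float)
    b = np.asarray(mu_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both cohorts need monitor-unit values")
    rows = []
    for pct in (25, 50, 75):
        qa_ = float(np.percentile(a, pct, method="linear"))
        qb = float(np.percentile(b, pct, method="linear"))
        rows.append(
            {
                "percentile": pct,
                f"mu_{label_a}": qa_,
                f"mu_{label_b}": qb,
                "percent_difference": 100.0 * (qa_ - qb) / qb,
            }
        )
    return pd.DataFrame(rows)
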