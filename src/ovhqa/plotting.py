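"""Plot helpers for cohort QA: population bands and predicted-vs-achieved."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .population import PopulationModel
from .qa import DeltaRecord


def plot_population_band(
    model: PopulationModel, out_path: str | Path, title: str | None = None
) -> Path:
    """Dose-distance percentile band for one OAR (25th-75th shaded)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    defined = model.defined
    d = model.distance_grid[defined]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(d, model.p25[defined], model.p75[defined], alpha=0.3, label="25th-75th")
    ax.plot(d, model.p50[defined], label="median")
    ax.set_xlabel("distance from PTV [mm]")
    ax.set_ylabel("mean dose [Gy]")
    ax.set_title(title or f"{model.oar} (n={model.n_patients})")
    ax.legend()
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_predicted_vs_achieved(
    records: Sequence[DeltaRecord], metric: str, out_path: str | Path
) -> Path:
    """Scatter of predicted (with 25/75 error bars) against achieved values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = [r for r in records if r.metric == metric]
    if not recs:
        raise ValueError(f"no records for metric {metric!r}")
    ach = np.array([r.achieved for r in recs])
    p50 = np.array([r.predicted_p50 for r in recs])
    lo = p50 - np.array([r.predicted_p25 for r in recs])
    hi = np.array([r.predicted_p75 for r in recs]) - p50
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(ach, p50, yerr=[lo, hi], fmt="o", ms=4, capsize=2)
    span = [min(ach.min(), p50.min()), max(ach.max(), p50.max())]
    ax.plot(span, span, "k--", lw=1)
    ax.set_xlabel(f"achieved {metric} [{recs[0].unit}]")
    ax.set_ylabel(f"predicted {metric} [{recs[0].unit}]")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
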