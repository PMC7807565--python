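"""Goal sheets, generator configuration and config hashing.

The goal sheet maps structure labels to metric specifications and is a
plain YAML document so clinics can edit thresholds without touching code.
The default sheet shipped here carries PLACEHOLDER, NON-CLINICAL values and
must be reviewed before any clinical use.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .metrics import MetricSpec

__all__ = ["default_goal_config", "load_goal_config", "dump_goal_config", "config_hash"]


def default_goal_config() -> dict[str, list[MetricSpec]]:
    """Placeholder goal sheet (NON-CLINICAL values, for testing only)."""
    return {
        "ptv": [MetricSpec.dmean(), MetricSpec.dmax()],
        "bowel_bag": [MetricSpec.dmean(), MetricSpec.dmax(), MetricSpec.v_abs(45.0)],
        "bladder": [MetricSpec.dmean(), MetricSpec.dmax(), MetricSpec.v_rel(35.0)],
    }


def _spec_to_dict(spec: MetricSpec) -> dict:
    d: dict = {"name": spec.name, "kind": spec.kind}
    if spec.threshold_dose_gy is not None:
        d["threshold_dose_gy"] = spec.threshold_dose_gy
    return d


def dump_goal_config(config: dict[str, list[MetricSpec]], path: str | Path) -> None:
    payload = {
        "note": "placeholder goal sheet - values are NOT clinical",
        "structures": {
            structure: [_spec_to_dict(s) for s in specs]
            for structure, specs in config.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_goal_config(path: str | Path) -> dict[str, list[MetricSpec]]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "structures" not in payload:
        raise ValueError(f"goal config {path} must contain a 'structures' mapping")
    out: dict[str, list[MetricSpec]] = {}
    for structure, entries in payload["structures"].items():
        specs = []
        for entry in entries:
            specs.append(
                MetricSpec(
                    name=entry.get("name") or entry["kind"],
                    kind=entry["kind"],
                    threshold_dose_gy=entry.get("threshold_dose_gy"),
                )
            )
        out[structure] = specs
    return out


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
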