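"""Config loading, schedule serialization and run manifests.

Conventions: YAML for configs, JSON for schedules and fit results, CSV for
tabular data.  Times are seconds, temperatures degC at every file interface
(kelvin appears only inside the Eyring math).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .kinetics import ConcentrationState, KineticDataset, KineticGroup
from .optimizer import DomainSpec
from .resource_model import (
    HardwareConfig,
    ReactionJob,
    ResourceInterval,
    Schedule,
)

__all__ = [
    "load_hardware_config",
    "load_domain_spec",
    "load_jobs",
    "write_schedule",
    "read_schedule",
    "load_kinetic_csv",
    "write_manifest",
]

_HW_FIELDS = {f for f in HardwareConfig.__dataclass_fields__}


def load_hardware_config(path: str | Path) -> HardwareConfig:
    """Read and validate a hardware config from YAML (or JSON).

    Missing fields fall back to defaults (ten reactors, 1 s shift unit,
    0-200 degC limits); unknown or out-of-range fields raise with the field
    named.
    """
    raw = _load_mapping(path)
    unknown = set(raw) - _HW_FIELDS
    if unknown:
        raise ValueError(
            f"{path}: unknown hardware config fields {sorted(unknown)}; "
            f"expected a subset of {sorted(_HW_FIELDS)}"
        )
    if raw.get("temp_max", 200.0) > 200.0 or raw.get("temp_min", 0.0) < 0.0:
        raise ValueError(
            f"{path}: temperature bounds must stay within the platform's "
            "0-200 degC envelope "
            f"(temp_min={raw.get('temp_min', 0.0)}, "
            f"temp_max={raw.get('temp_max', 200.0)})"
        )
    try:
        return HardwareConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid hardware config: {exc}") from exc


def _load_mapping(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if data is None:
        raise ValueError(
            f"{path} is empty; required structure: a mapping of field: value"
        )
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    return data


def load_domain_spec(path: str | Path) -> DomainSpec:
    """Read an optimization domain from YAML.

    Expected structure::

        continuous:
          - {name: temperature, low: 50, high: 100}
        categorical:
          - {name: catalyst, levels: [A, B]}
    """
    raw = _load_mapping(path)
    cont = tuple(
        (str(c["name"]), float(c["low"]), float(c["high"]))
        for c in raw.get("continuous", [])
    )
    cat = tuple(
        (str(c["name"]), tuple(str(v) for v in c["levels"]))
        for c in raw.get("categorical", [])
    )
    return DomainSpec(continuous=cont, categorical=cat)


def load_jobs(path: str | Path) -> list[ReactionJob]:
    """Read a job list from CSV (job_id, temperature_C, residence_time_s,
    mode, led_power) or from a JSON list of records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        required = {"job_id", "temperature_C", "residence_time_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        records = df.to_dict("records")
    jobs = []
    for rec in records:
        led = rec.get("led_power")
        if led is not None and pd.isna(led):
            led = None
        jobs.append(
            ReactionJob(
                job_id=str(rec["job_id"]),
                temperature=float(rec["temperature_C"]),
                residence_time=float(rec["residence_time_s"]),
                mode=str(rec.get("mode", "thermal") or "thermal"),
                led_power=None if led is None else float(led),
            )
        )
    return jobs


def write_schedule(path: str | Path, schedule: Schedule) -> None:
    """Serialize a schedule to JSON, allocations sorted canonically by start."""
    allocations = sorted(
        schedule.allocations, key=lambda iv: (iv.start, iv.resource, iv.job_id)
    )
    payload = {
        "jobs": [
            {
                "job_id": j.job_id,
                "temperature_C": j.temperature,
                "residence_time_s": j.residence_time,
                "mode": j.mode,
                "led_power": j.led_power,
            }
            for j in schedule.jobs
        ],
        "reactor_of": schedule.reactor_of,
        "prep_start": {k: round(v, 6) for k, v in schedule.prep_start.items()},
        "allocations": [
            {
                "job_id": iv.job_id,
                "stage": iv.stage,
                "resource": iv.resource,
                "start_s": round(iv.start, 6),
                "end_s": round(iv.end, 6),
            }
            for iv in allocations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


_KNOWN_RESOURCE_PREFIXES = ("liquid_handler", "main_flowpath", "hplc", "reactor_")


def read_schedule(path: str | Path) -> Schedule:
    """Inverse of :func:`write_schedule`; validates resource names."""
    data = json.loads(Path(path).read_text())
    jobs = [
        ReactionJob(
            job_id=str(j["job_id"]),
            temperature=float(j["temperature_C"]),
            residence_time=float(j["residence_time_s"]),
            mode=j.get("mode", "thermal"),
            led_power=j.get("led_power"),
        )
        for j in data["jobs"]
    ]
    allocations = []
    for rec in data["allocations"]:
        res = str(rec["resource"])
        if not res.startswith(_KNOWN_RESOURCE_PREFIXES):
            raise ValueError(f"{path}: unknown resource {res!r}")
        allocations.append(
            ResourceInterval(
                resource=res,
                start=float(rec["start_s"]),
                end=float(rec["end_s"]),
                job_id=str(rec["job_id"]),
                stage=str(rec["stage"]),
            )
        )
    return Schedule(
        jobs=jobs,
        allocations=allocations,
        reactor_of={k: int(v) for k, v in data["reactor_of"].items()},
        prep_start={k: float(v) for k, v in data["prep_start"].items()},
    )


def load_kinetic_csv(path: str | Path) -> KineticDataset:
    """Read concentration-time data (temperature_C, arf0_M, amine0_M,
    time_s, arf_M), grouping rows by condition."""
    df = pd.read_csv(path)
    required = {"temperature_C", "arf0_M", "amine0_M", "time_s", "arf_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    groups = []
    for (temp, arf0, amine0), sub in df.groupby(
        ["temperature_C", "arf0_M", "amine0_M"], sort=True
    ):
        sub = sub.sort_values("time_s")
        groups.append(
            KineticGroup(
                temperature_c=float(temp),
                c0=ConcentrationState(arf=float(arf0), amine=float(amine0)),
                times_s=tuple(float(t) for t in sub["time_s"]),
                arf_measured=tuple(float(a) for a in sub["arf_M"]),
            )
        )
    return KineticDataset(groups)


def write_kinetic_csv(path: str | Path, data: KineticDataset) -> None:
    rows = []
    for g in data.groups:
        for t, a in zip(g.times_s, g.arf_measured):
            rows.append(
                {
                    "temperature_C": g.temperature_c,
                    "arf0_M": g.c0.arf,
                    "amine0_M": g.c0.amine,
                    "time_s": t,
                    "arf_M": a,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(
    path: str | Path,
    command: str,
    seed: int | None,
    inputs: dict[str, str],
    outputs: dict[str, str],
) -> dict[str, Any]:
    """Emit the run manifest every CLI command writes next to its output."""
    from . import __version__

    digest = hashlib.sha256()
    for key in sorted(inputs):
        p = Path(inputs[key])
        if p.exists():
            digest.update(p.read_bytes())
    manifest = {
        "command": command,
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
        "config_hash": digest.hexdigest(),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
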