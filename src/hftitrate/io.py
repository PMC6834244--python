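"""File interfaces: YAML config, JSONL event logs, CSV ledgers and samples."""
from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import ValidationError

from .engagement import LedgerEntry
from .errors import ConfigurationError
from .events import Event, events_from_jsonl, events_to_jsonl
from .simulate import SimConfig
from .telemetry import Source, VitalSample

log = logging.getLogger(__name__)

#: CSV column layout for input vital samples; empty cells mean "not measured".
SAMPLE_COLUMNS = [
    "patient_id",
    "date",
    "weight_kg",
    "sbp_mmhg",
    "dbp_mmhg",
    "hr_bpm",
    "source",
    "recorded_at",
]


def load_config(path: str | Path) -> SimConfig:
    """Read a simulation config from YAML; raises ConfigurationError on bad input."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    try:
        return SimConfig(**data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def write_events(events: Sequence[Event], path: str | Path) -> None:
    Path(path).write_text(events_to_jsonl(events))


def read_events(path: str | Path) -> list[Event]:
    return events_from_jsonl(Path(path).read_text())


def write_ledger_csv(entries: Sequence[LedgerEntry], path: str | Path) -> None:
    rows = [
        {
            "patient_id": e.action.patient_id,
            "date": e.action.ideal_time.date().isoformat(),
            "kind": e.action.kind.value,
            "drug": e.action.drug.value if e.action.drug else "",
            "outcome": e.outcome.value,
            "resolved_at": e.resolved_at.isoformat(),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=["patient_id", "date", "kind", "drug", "outcome", "resolved_at"]).to_csv(
        path, index=False
    )


def write_ground_truth(ground_truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ground_truth, fh, sort_keys=True)


def read_samples_csv(path: str | Path) -> tuple[list[VitalSample], list[tuple[int, str]]]:
    """Read vital samples from CSV; malformed rows are rejected individually
    (returned as (row_number, reason)) and the read continues."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"sample CSV missing columns: {missing}")
    samples: list[VitalSample] = []
    rejects: list[tuple[int, str]] = []

    def _num(v):
        return None if pd.isna(v) else float(v)

    for i, row in df.iterrows():
        try:
            samples.append(
                VitalSample(
                    patient_id=row["patient_id"],
                    date=pd.Timestamp(row["date"]).date(),
                    weight=_num(row["weight_kg"]),
                    systolic=_num(row["sbp_mmhg"]),
                    diastolic=_num(row["dbp_mmhg"]),
                    heart_rate=_num(row["hr_bpm"]),
                    source=Source(row["source"]) if pd.notna(row["source"]) else Source.device_auto,
                    recorded_at=datetime.fromisoformat(str(row["recorded_at"])),
                )
            )
        except (ValidationError, ValueError) as exc:
            reason = str(exc).splitlines()[0]
            log.warning("rejecting sample row %d: %s", i, reason)
            rejects.append((int(i), reason))
    return samples, rejects
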