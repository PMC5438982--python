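"""On-disk interchange formats for traces, event logs and cohort metadata.

Plain diff-able text: ``traces.csv`` (bee_id, t_s, position_cm,
sensor_index), ``events.csv`` (bee_id, t_s, kind, side, label,
intensity_pct, trial_index, phase) and ``cohort.json`` (per-bee records,
schema version, optional protocol documents).  Times are seconds from
session start; trial-relative times are always derived, never stored.
Every invariant on the in-memory types is re-validated on load, with row
numbers in the error message.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .arena import ChamberSpec, ProtocolSpec, protocol_from_dict, protocol_to_dict

__all__ = [
    "PositionTrace",
    "BeeRecord",
    "EVENT_COLUMNS",
    "EVENT_KINDS",
    "write_dataset",
    "read_dataset",
    "validate_events",
]

SCHEMA_VERSION = "apisim-dataset/1"
POSITION_DECIMALS = 3

EVENT_COLUMNS = [
    "bee_id",
    "t_s",
    "kind",
    "side",
    "label",
    "intensity_pct",
    "trial_index",
    "phase",
]
EVENT_KINDS = {"light_on", "light_off", "shock_pulse", "phase_mark"}

# shock pulses must fall inside the armed window relative to light onset
SHOCK_WINDOW_S = (3.0, 14.0)


class ValidationError(ValueError):
    """A dataset violated a structural invariant (message cites the row)."""


@dataclass
class PositionTrace:
    """A 16 Hz 1-D trajectory of one bee."""

    bee_id: str
    times_s: np.ndarray
    positions_cm: np.ndarray
    chamber: ChamberSpec = field(default_factory=ChamberSpec)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if self.times_s.shape != self.positions_cm.shape:
            raise ValidationError(f"{self.bee_id}: times/positions length mismatch")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            bad = int(np.argmin(np.diff(self.times_s)))
            raise ValidationError(
                f"{self.bee_id}: times not strictly increasing at sample {bad + 1}"
            )
        out = (self.positions_cm < 0) | (self.positions_cm > self.chamber.length_cm)
        if out.any():
            bad = int(np.argmax(out))
            raise ValidationError(
                f"{self.bee_id}: position {self.positions_cm[bad]} cm outside "
                f"chamber at sample {bad}"
            )

    def sensor_indices(self) -> np.ndarray:
        pitch = self.chamber.sensor_pitch_cm
        idx = np.floor(self.positions_cm / pitch).astype(int)
        return np.clip(idx, 0, self.chamber.n_sensors - 1)

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class BeeRecord:
    bee_id: str
    paradigm: str  # reinforced | unreinforced
    protocol_name: str
    excluded: Optional[bool] = None  # pending until the exclusion filter runs

    def __post_init__(self) -> None:
        if self.paradigm not in ("reinforced", "unreinforced"):
            raise ValidationError(
                f"{self.bee_id}: paradigm must be reinforced/unreinforced"
            )


def validate_events(events: pd.DataFrame) -> None:
    """Check the event-log invariants; raise ValidationError with the row."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event log missing columns {missing}")
    bad_kind = ~events["kind"].isin(EVENT_KINDS)
    if bad_kind.any():
        row = int(np.argmax(bad_kind.to_numpy()))
        raise ValidationError(f"unknown event kind at row {row}")

    lights = events[events["kind"].isin(["light_on", "light_off"])]
    for (bee, trial), grp in lights.groupby(["bee_id", "trial_index"]):
        for side, sgrp in grp.groupby("side"):
            n_on = int((sgrp["kind"] == "light_on").sum())
            n_off = int((sgrp["kind"] == "light_off").sum())
            if n_on != 1 or n_off != 1:
                raise ValidationError(
                    f"{bee} trial {trial} side {side}: expected one light_on and "
                    f"one light_off, got {n_on}/{n_off}"
                )

    shocks = events[events["kind"] == "shock_pulse"]
    if len(shocks):
        onsets = (
            events[events["kind"] == "light_on"]
            .groupby(["bee_id", "trial_index"])["t_s"]
            .min()
        )
        for row_idx, row in shocks.iterrows():
            key = (row["bee_id"], row["trial_index"])
            if key not in onsets.index:
                raise ValidationError(
                    f"row {row_idx}: shock_pulse in trial without light_on"
                )
            rel = row["t_s"] - onsets.loc[key]
            if not (SHOCK_WINDOW_S[0] <= rel < SHOCK_WINDOW_S[1]):
                raise ValidationError(
                    f"row {row_idx}: shock_pulse at {rel:.3f} s after onset, "
                    f"outside [{SHOCK_WINDOW_S[0]}, {SHOCK_WINDOW_S[1]}) window"
                )


def _validate_paradigms(events: pd.DataFrame, records: Iterable[BeeRecord]) -> None:
    shocked = set(events.loc[events["kind"] == "shock_pulse", "bee_id"])
    for rec in records:
        if rec.paradigm == "unreinforced" and rec.bee_id in shocked:
            raise ValidationError(
                f"{rec.bee_id}: unreinforced record but shock events present"
            )


def write_dataset(
    traces: Iterable[PositionTrace],
    events: pd.DataFrame,
    records: Iterable[BeeRecord],
    path,
    protocols: Optional[dict[str, ProtocolSpec]] = None,
    provenance: Optional[dict] = None,
) -> Path:
    """Write traces.csv / events.csv / cohort.json under ``path``."""
    traces = list(traces)
    records = list(records)
    validate_events(events)
    _validate_paradigms(events, records)

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    if traces:
        trace_df = pd.concat(
            [
                pd.DataFrame(
                    {
                        "bee_id": tr.bee_id,
                        "t_s": tr.times_s,
                        "position_cm": np.round(tr.positions_cm, POSITION_DECIMALS),
                        "sensor_index": tr.sensor_indices(),
                    }
                )
                for tr in traces
            ],
            ignore_index=True,
        )
    else:
        trace_df = pd.DataFrame(
            columns=["bee_id", "t_s", "position_cm", "sensor_index"]
        )
    trace_df.to_csv(path / "traces.csv", index=False)
    events.to_csv(path / "events.csv", index=False)

    chamber = traces[0].chamber if traces else ChamberSpec()
    meta = {
        "schema": SCHEMA_VERSION,
        "chamber": {
            "length_cm": chamber.length_cm,
            "n_sensors": chamber.n_sensors,
            "sample_rate_hz": chamber.sample_rate_hz,
        },
        "bees": [
            {
                "bee_id": r.bee_id,
                "paradigm": r.paradigm,
                "protocol_name": r.protocol_name,
                "excluded": r.excluded,
            }
            for r in records
        ],
        "protocols": {
            name: protocol_to_dict(p) for name, p in (protocols or {}).items()
        },
        "provenance": provenance or {},
    }
    (path / "cohort.json").write_text(json.dumps(meta, indent=1))
    return path


def read_dataset(
    path,
) -> tuple[list[PositionTrace], pd.DataFrame, list[BeeRecord], dict[str, ProtocolSpec]]:
    """Load and re-validate a dataset written by :func:`write_dataset`."""
    path = Path(path)
    meta = json.loads((path / "cohort.json").read_text())
    if meta.get("schema") != SCHEMA_VERSION:
        raise ValidationError(
            f"schema mismatch: expected {SCHEMA_VERSION}, got {meta.get('schema')}"
        )
    chamber = ChamberSpec(**meta["chamber"])
    trace_df = pd.read_csv(path / "traces.csv")
    events = pd.read_csv(
        path / "events.csv",
        dtype={"side": str, "label": str, "phase": str},
        keep_default_na=False,
        na_values=[],
    )
    if len(events):
        events["t_s"] = events["t_s"].astype(float)
        events["intensity_pct"] = events["intensity_pct"].astype(float)
        events["trial_index"] = events["trial_index"].astype(int)
    validate_events(events)

    traces = []
    for bee_id, grp in trace_df.groupby("bee_id", sort=False):
        traces.append(
            PositionTrace(
                bee_id=str(bee_id),
                times_s=grp["t_s"].to_numpy(),
                positions_cm=grp["position_cm"].to_numpy(),
                chamber=chamber,
            )
        )
    records = [
        BeeRecord(
            bee_id=b["bee_id"],
            paradigm=b["paradigm"],
            protocol_name=b["protocol_name"],
            excluded=b["excluded"],
        )
        for b in meta["bees"]
    ]
    _validate_paradigms(events, records)
    protocols = {
        name: protocol_from_dict(d) for name, d in meta.get("protocols", {}).items()
    }
    return traces, events, records, protocols
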