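"""Readers and writers for the pipeline's plain-text formats.

Canonical formats are long CSVs: plate tables (time_h, well, channel,
value) with a JSON well-metadata sidecar, cytometry event tables
(sample_id, transfer, is_blank, FITC, AmCyan) and dose-response tables
(dose_M, response, replicate, condition).  A wide plate layout
("A1:A600"-style columns) is read as a convenience adapter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .plates import CHANNELS, PlateTimeSeries, WellInfo

__all__ = [
    "PlateValidationError",
    "read_plate_table",
    "write_plate_table",
    "read_well_metadata",
    "write_well_metadata",
    "read_event_table",
    "write_event_table",
    "read_dose_response_table",
    "write_ground_truth",
]

PLATE_COLUMNS = ["time_h", "well", "channel", "value"]
EVENT_COLUMNS = ["sample_id", "transfer", "is_blank", "FITC", "AmCyan"]


class PlateValidationError(ValueError):
    """Malformed plate table (missing columns, duplicates, bad time grid)."""


def _validate_long(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise PlateValidationError(f"missing columns: {sorted(missing)}")
    if df.duplicated(subset=["well", "channel", "time_h"]).any():
        raise PlateValidationError("duplicate (well, channel, time) rows")
    for (well, channel), sub in df.groupby(["well", "channel"]):
        t = sub["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(np.sort(t)) <= 0):
            raise PlateValidationError(f"non-monotone time grid in well {well}, {channel}")
    unknown = set(df["channel"].unique()) - set(CHANNELS)
    if unknown:
        raise PlateValidationError(f"unknown channels: {sorted(unknown)}")
    return df


def read_plate_table(path, layout: str = "long", metadata_path=None) -> PlateTimeSeries:
    """Read a plate CSV (long or wide layout) plus optional metadata sidecar."""
    df = pd.read_csv(path)
    if layout == "wide":
        # wide: one time_h column plus one "<well>:<channel>" column each
        value_cols = [c for c in df.columns if c != "time_h"]
        records = []
        for col in value_cols:
            try:
                well, channel = col.split(":")
            except ValueError:
                raise PlateValidationError(f"wide column {col!r} is not '<well>:<channel>'")
            records.append(
                pd.DataFrame(
                    {"time_h": df["time_h"], "well": well, "channel": channel, "value": df[col]}
                )
            )
        df = pd.concat(records, ignore_index=True)
    elif layout != "long":
        raise ValueError("layout must be 'long' or 'wide'")
    df = _validate_long(df)[PLATE_COLUMNS]
    wells: dict[str, WellInfo]
    if metadata_path is not None:
        wells = read_well_metadata(metadata_path)
    else:
        wells = {w: WellInfo(strains=[], markers=[]) for w in df["well"].unique()}
    return PlateTimeSeries(data=df.reset_index(drop=True), wells=wells)


def write_plate_table(plate: PlateTimeSeries, path, layout: str = "long") -> None:
    df = plate.data[PLATE_COLUMNS].copy()
    if layout == "long":
        df.sort_values(["well", "channel", "time_h"]).to_csv(path, index=False)
        return
    if layout != "wide":
        raise ValueError("layout must be 'long' or 'wide'")
    wide = df.pivot_table(
        index="time_h", columns=["well", "channel"], values="value", sort=True
    )
    wide.columns = [f"{w}:{c}" for w, c in wide.columns]
    wide.reset_index().to_csv(path, index=False)


def read_well_metadata(path) -> dict[str, WellInfo]:
    raw = json.loads(Path(path).read_text())
    return {
        well: WellInfo(
            strains=entry["strains"],
            markers=entry["markers"],
            day=entry.get("day", 0),
            medium=entry.get("medium", "glycerol-minimal"),
            extra=entry.get("extra", {}),
        )
        for well, entry in raw.items()
    }


def write_well_metadata(plate: PlateTimeSeries, path) -> None:
    out = {
        well: {
            "strains": info.strains,
            "markers": info.markers,
            "day": info.day,
            "medium": info.medium,
            "extra": info.extra,
        }
        for well, info in plate.wells.items()
    }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["FITC"])) or not np.all(np.isfinite(df["AmCyan"])):
        raise ValueError("event intensities must be finite")
    df["is_blank"] = df["is_blank"].astype(bool)
    return df


def write_event_table(events: pd.DataFrame, path) -> None:
    cols = EVENT_COLUMNS + [c for c in events.columns if c not in EVENT_COLUMNS]
    events[cols].to_csv(path, index=False)


def read_dose_response_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"dose_M", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_ground_truth(params, path) -> None:
    """Sidecar JSON recording every generator parameter of a simulation."""
    Path(path).write_text(json.dumps(_jsonable(params), indent=2, sort_keys=True))
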