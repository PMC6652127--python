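"""CSV dialects of the pipeline: sensor streams, beacon layout, per-window
results and feature/statistics reports.  Everything is plain CSV so outputs
are human-auditable and round-trip losslessly at the printed precision."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Beacon, BeaconLayout, BeaconObservationStream
from .signal import AccelStream

ACCEL_COLUMNS = ["timestamp_s", "ax_g", "ay_g", "az_g"]
RSSI_COLUMNS = ["timestamp_s", "beacon_id", "rssi_dbm"]
LAYOUT_COLUMNS = ["beacon_id", "location_id", "room", "x_m", "y_m"]
SCHEMAS = {"accel": ACCEL_COLUMNS, "rssi": RSSI_COLUMNS}


def _check_header(df: pd.DataFrame, schema_cols: list[str], path) -> None:
    missing = [c for c in schema_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]  # +2: header line and 1-based count
        raise ValueError(f"{path}: malformed values in '{col}' at line(s) {lines}")
    if vals.isna().any():
        lines = (df.index[vals.isna()] + 2).tolist()[:5]
        raise ValueError(f"{path}: empty values in '{col}' at line(s) {lines}")
    return vals.to_numpy(dtype=float)


def read_sensor_csv(path: str | Path, schema: str) -> AccelStream | BeaconObservationStream:
    """Load and validate a sensor stream ('accel' or 'rssi' schema)."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema id '{schema}' (expected one of {list(SCHEMAS)})")
    df = pd.read_csv(path)
    _check_header(df, SCHEMAS[schema], path)
    if schema == "accel":
        t = _numeric(df, "timestamp_s", path)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{path}: timestamps are not strictly increasing")
        return AccelStream(
            t,
            _numeric(df, "ax_g", path),
            _numeric(df, "ay_g", path),
            _numeric(df, "az_g", path),
        )
    t = _numeric(df, "timestamp_s", path)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: timestamps are not non-decreasing")
    return BeaconObservationStream(
        t, df["beacon_id"].astype(str).to_numpy(dtype=object), _numeric(df, "rssi_dbm", path)
    )


def write_accel_csv(stream: AccelStream, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp_s": stream.t, "ax_g": stream.ax, "ay_g": stream.ay, "az_g": stream.az}
    ).to_csv(path, index=False, float_format="%.6f")


def write_rssi_csv(stream: BeaconObservationStream, path: str | Path) -> None:
    stream.to_frame().to_csv(path, index=False, float_format="%.3f")


def write_layout_csv(layout: BeaconLayout, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "beacon_id": b.beacon_id,
                "location_id": b.location_id,
                "room": layout.rooms[b.location_id],
                "x_m": b.x_m,
                "y_m": b.y_m,
            }
            for b in layout.beacons
        ]
    ).to_csv(path, index=False)


def read_layout_csv(path: str | Path) -> BeaconLayout:
    df = pd.read_csv(path)
    _check_header(df, LAYOUT_COLUMNS, path)
    beacons = [
        Beacon(str(r.beacon_id), str(r.location_id), float(r.x_m), float(r.y_m))
        for r in df.itertuples()
    ]
    rooms = {str(r.location_id): str(r.room) for r in df.itertuples()}
    return BeaconLayout(beacons=beacons, rooms=rooms)
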