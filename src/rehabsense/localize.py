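"""Beacon-RSSI indoor localization.

Nearest-beacon proximity rule: per analysis window, each beacon's clipped
RSSI observations are summarised by their median, the window is assigned to
the sublocation of the strongest beacon, and sublocations are aggregated to
canonical locations of interest (shower/toilet/sink -> bathroom, numbered
walls -> wall, numbered beds -> bed).  Windows with no observations are
"unknown"; they stay in the uptime accounting but never enter location
feature denominators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BeaconLayout, BeaconObservationStream, default_beacon_layout

RSSI_CLIP_DBM = (-100.0, -50.0)

UNKNOWN = "unknown"

# Raw-sublocation vocabulary of the default deployment plus its canonical
# aggregates; aggregation accepts anything here (identity where no rule fires).
DEFAULT_VOCABULARY = frozenset(
    set(default_beacon_layout().rooms)
    | {
        "bathroom",
        "wall",
        "resident_bed",
        "therapy_bed",
        "bike",
        "resband",
        "strip",
        "table",
        "small_table",
        "hallway_seats",
        "scifit",
        "chair",
        "hallway",
        "stairs",
        "midstrip",
        "endorphine",
        "seats",
        "bed",
        "therapy_bed3",
        "therapy_bed4",
    }
)

_BATHROOM_RAW = {"shower", "toilet", "sink", "bath"}


@dataclass
class LocationAssignment:
    """One window's location: raw beacon-level sublocation, its canonical
    aggregate, and the room it belongs to."""

    start_time_s: float
    raw_location: str
    canonical_location: str
    room: str

    def __post_init__(self) -> None:
        if self.raw_location == UNKNOWN and self.room != UNKNOWN:
            raise ValueError("an unknown location cannot have a known room")


def clip_rssi(rssi, lo: float = RSSI_CLIP_DBM[0], hi: float = RSSI_CLIP_DBM[1]):
    """Clamp RSSI into the considered [-100, -50] dBm range."""
    arr = np.asarray(rssi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("RSSI must be finite")
    out = np.clip(arr, lo, hi)
    return float(out) if np.isscalar(rssi) or arr.ndim == 0 else out


def smooth_rssi(
    events: pd.DataFrame | BeaconObservationStream,
    window: tuple[float, float],
    clip: tuple[float, float] = RSSI_CLIP_DBM,
) -> dict[str, float]:
    """Per-beacon median of clipped RSSI over [start, start + duration).

    Beacons with no events in the window are absent from the summary.
    """
    start, duration = window
    if duration <= 0:
        raise ValueError("window duration must be > 0")
    if isinstance(events, BeaconObservationStream):
        events = events.to_frame()
    sel = events[(events["timestamp_s"] >= start) & (events["timestamp_s"] < start + duration)]
    if sel.empty:
        return {}
    rssi = clip_rssi(sel["rssi_dbm"].to_numpy(), *clip)
    return (
        pd.Series(rssi, index=sel["beacon_id"].to_numpy()).groupby(level=0).median().to_dict()
    )


def assign_location(
    window_start: float,
    summaries: dict[str, float],
    layout: BeaconLayout,
) -> LocationAssignment:
    """Nearest-beacon rule: the sublocation of the beacon with the highest
    summary RSSI; ties break to the lexicographically smallest beacon id;
    an empty summary is unknown."""
    if not summaries:
        return LocationAssignment(window_start, UNKNOWN, UNKNOWN, UNKNOWN)
    beacon_loc = layout.beacon_location()
    for bid in summaries:
        if bid not in beacon_loc:
            raise KeyError(f"beacon id '{bid}' is not in the layout")
    best = min(summaries.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    raw = beacon_loc[best]
    return LocationAssignment(
        start_time_s=window_start,
        raw_location=raw,
        canonical_location=aggregate_location(raw),
        room=layout.rooms[raw],
    )


def aggregate_location(raw_location: str, vocabulary: frozenset | set | None = None) -> str:
    """Canonical location of interest for a raw sublocation.

    shower/toilet/sink/bath -> bathroom; wallN -> wall; therapy_bedN ->
    therapy_bed; resident_bedN -> resident_bed; identity otherwise.  Items
    outside the configured vocabulary are rejected.
    """
    vocab = DEFAULT_VOCABULARY if vocabulary is None else vocabulary
    if raw_location == UNKNOWN:
        return UNKNOWN
    if raw_location not in vocab:
        raise KeyError(f"'{raw_location}' is not in the location vocabulary")
    if raw_location in _BATHROOM_RAW:
        return "bathroom"
    m = re.fullmatch(r"(wall)\d+", raw_location)
    if m:
        return m.group(1)
    m = re.fullmatch(r"(therapy_bed|resident_bed)\d+", raw_location)
    if m:
        return m.group(1)
    return raw_location


def localize_windows(
    events: BeaconObservationStream | pd.DataFrame,
    starts: np.ndarray,
    layout: BeaconLayout,
    window_s: float = 10.0,
    clip: tuple[float, float] = RSSI_CLIP_DBM,
) -> pd.DataFrame:
    """Location assignment for every window start (one row per window)."""
    if isinstance(events, BeaconObservationStream):
        frame = events.to_frame()
    else:
        frame = events
    t = frame["timestamp_s"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(frame["beacon_id"].to_numpy())
    rssi = np.clip(frame["rssi_dbm"].to_numpy(dtype=float), *clip)
    beacon_loc = layout.beacon_location()
    for bid in uniques:
        if bid not in beacon_loc:
            raise KeyError(f"beacon id '{bid}' is not in the layout")

    rows = []
    for s0 in np.asarray(starts, dtype=float):
        i0, i1 = np.searchsorted(t, [s0, s0 + window_s])
        if i1 > i0:
            med = pd.Series(rssi[i0:i1]).groupby(codes[i0:i1]).median()
            summaries = {str(uniques[c]): float(v) for c, v in med.items()}
        else:
            summaries = {}
        a = assign_location(float(s0), summaries, layout)
        rows.append((a.start_time_s, a.raw_location, a.canonical_location, a.room))
    return pd.DataFrame(
        rows, columns=["start_time_s", "raw_location", "canonical_location", "room"]
    )
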