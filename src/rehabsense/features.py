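"""Baseline-day selection and the normalized activity/location feature set.

Per patient-day, window-level results (MAD, activity label, location) are
rolled up into:

* time percentages — minutes in a state or location divided by uptime (the
  total worn minutes that day), x100;
* energy — the windowed MAD (cm/s^2) accumulated over window minutes; a
  state's or location's *energy intensity* divides its energy by the minutes
  spent in that same state/location, and its *energy percentage* divides by
  the day's total energy, x100.

A patient's baseline is the earliest of the first three admission days with
at least 4 h of wear and at least 15 min of therapy-room wear; patients with
no qualifying day are excluded.  Intensities of states that never occur are
reported absent (NaN), and per-feature availability counts are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_UPTIME_MIN = 240.0
MIN_THERAPY_MIN = 15.0
BASELINE_WINDOW_DAYS = 3
INTENSITY_CUTOFF = 90.0  # light vs moderate-to-vigorous, per-minute intensity

STATES = ("active", "walking", "standing", "sitting", "laying")
_POSTURE_STATE = {"stand": "standing", "sit": "sitting", "lay": "laying"}


def compute_uptime(wear_segments: list[tuple[float, float]]) -> float:
    """Total worn minutes of a day; non-worn hours are excluded."""
    return sum(max(0.0, b - a) for a, b in wear_segments) / 60.0


@dataclass
class BaselineSelection:
    patient_id: str
    chosen_day: int | None
    excluded: bool
    wear_min: dict[int, float]
    therapy_min: dict[int, float]


def select_baseline_day(
    patient_id: str,
    day_stats: pd.DataFrame,
    min_uptime_min: float = MIN_UPTIME_MIN,
    min_therapy_min: float = MIN_THERAPY_MIN,
    window_days: int = BASELINE_WINDOW_DAYS,
) -> BaselineSelection:
    """Earliest day within the first ``window_days`` admission days with
    uptime >= 4 h and therapy wear >= 15 min; otherwise excluded.

    ``day_stats`` needs columns day, uptime_min, therapy_min.
    """
    stats = day_stats.sort_values("day")
    wear = dict(zip(stats["day"].astype(int), stats["uptime_min"].astype(float)))
    therapy = dict(zip(stats["day"].astype(int), stats["therapy_min"].astype(float)))
    chosen = None
    for _, row in stats.iterrows():
        if int(row["day"]) > window_days:
            break
        if row["uptime_min"] >= min_uptime_min and row["therapy_min"] >= min_therapy_min:
            chosen = int(row["day"])
            break
    return BaselineSelection(
        patient_id=patient_id,
        chosen_day=chosen,
        excluded=chosen is None,
        wear_min=wear,
        therapy_min=therapy,
    )


def time_percent(minutes_in_state: float, uptime_min: float) -> float:
    if uptime_min <= 0:
        raise ValueError("uptime must be positive (day should have been excluded)")
    if not 0 <= minutes_in_state <= uptime_min + 1e-9:
        raise ValueError("minutes in state must lie within [0, uptime]")
    return 100.0 * minutes_in_state / uptime_min

def window_energy(mad_ms2, credit_s) -> np.ndarray | float:
    """Energy contribution of a window: MAD on the cm/s^2 scale times the
    window's time credit in minutes.  Additive over windows."""
    return np.asarray(mad_ms2, dtype=float) * 100.0 * np.asarray(credit_s, dtype=float) / 60.0


def energy_intensity(total_energy: float, minutes: float) -> float:
    """Energy per minute spent in the same state/location; states with zero
    minutes are *absent* (NaN), not zero."""
    if minutes <= 0:
        return float("nan")
    return total_energy / minutes


def energy_percent(state_energy: float, total_daily_energy: float) -> float:
    if total_daily_energy <= 0:
        raise ValueError("total daily energy must be positive")
    return 100.0 * state_energy / total_daily_energy


def intensity_band(intensity: float, cutoff: float = INTENSITY_CUTOFF) -> str:
    """'light' below the cutoff, 'moderate_to_vigorous' at or above it."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    return "light" if intensity < cutoff else "moderate_to_vigorous"


def _state_masks(win: pd.DataFrame, mad_threshold: float) -> dict[str, np.ndarray]:
    loco = win["locomotion"].to_numpy(dtype=object)
    posture = win["posture"].to_numpy(dtype=object)
    mad = win["mad_ms2"].to_numpy(dtype=float)
    walking = loco == "walking"
    masks = {"walking": walking, "active": walking | (mad >= mad_threshold)}
    for p, state in _POSTURE_STATE.items():
        masks[state] = (loco == "stationary") & (posture == p)
    return masks


def _location_key(room: str, canonical: str) -> str:
    if canonical == "unknown":
        return "unknown"
    if canonical.startswith(room):
        return canonical
    return f"{room}_{canonical}"


def patient_day_features(
    win: pd.DataFrame,
    uptime_min: float,
    mad_threshold: float = 0.02,
) -> dict[str, float]:
    """Feature vector of one patient-day.

    ``win`` has one row per window with columns mad_ms2, credit_s,
    locomotion, posture, canonical_location, room.
    """
    feats: dict[str, float] = {"uptime_min": uptime_min}
    credit_min = win["credit_s"].to_numpy(dtype=float) / 60.0
    energy = np.asarray(window_energy(win["mad_ms2"].to_numpy(), win["credit_s"].to_numpy()))
    total_energy = float(energy.sum())
    feats["total_energy"] = total_energy
    feats["ei_total"] = energy_intensity(total_energy, float(credit_min.sum()))

    for state, mask in _state_masks(win, mad_threshold).items():
        minutes = float(credit_min[mask].sum())
        e = float(energy[mask].sum())
        feats[f"time_pct_{state}"] = time_percent(minutes, uptime_min)
        feats[f"ei_{state}"] = energy_intensity(e, minutes)
        feats[f"epct_{state}"] = energy_percent(e, total_energy) if total_energy > 0 else np.nan

    room = win["room"].to_numpy(dtype=object)
    canon = win["canonical_location"].to_numpy(dtype=object)
    loc_keys = np.array([_location_key(r, c) for r, c in zip(room, canon)], dtype=object)
    for key in pd.unique(loc_keys):
        mask = loc_keys == key
        minutes = float(credit_min[mask].sum())
        e = float(energy[mask].sum())
        feats[f"time_pct_{key}"] = time_percent(minutes, uptime_min)
        feats[f"ei_{key}"] = energy_intensity(e, minutes)
    for rm in ("resident", "therapy"):
        mask = room == rm
        minutes = float(credit_min[mask].sum())
        e = float(energy[mask].sum())
        feats[f"time_pct_{rm}_room"] = time_percent(minutes, uptime_min)
        feats[f"ei_{rm}_room"] = energy_intensity(e, minutes)
    return feats


def build_feature_table(
    window_tables: dict[tuple[str, int], pd.DataFrame],
    day_stats: pd.DataFrame,
    outcomes: dict[str, str] | None = None,
    mad_threshold: float = 0.02,
    min_uptime_min: float = MIN_UPTIME_MIN,
    min_therapy_min: float = MIN_THERAPY_MIN,
    window_days: int = BASELINE_WINDOW_DAYS,
) -> pd.DataFrame:
    """One baseline-day feature row per included patient.

    ``window_tables`` maps (patient_id, day) to the per-window frame of that
    day; ``day_stats`` has columns patient_id, day, uptime_min, therapy_min.
    Patients whose days all fail the inclusion criteria are dropped; absent
    cells are NaN so availability counts can be read off the table.
    """
    rows = []
    for pid, stats in day_stats.groupby("patient_id", sort=True):
        sel = select_baseline_day(
            str(pid), stats, min_uptime_min, min_therapy_min, window_days
        )
        if sel.excluded:
            continue
        key = (str(pid), sel.chosen_day)
        win = window_tables[key]
        feats = patient_day_features(
            win, uptime_min=sel.wear_min[sel.chosen_day], mad_threshold=mad_threshold
        )
        feats["patient_id"] = str(pid)
        feats["baseline_day"] = sel.chosen_day
        if outcomes:
            feats["outcome"] = outcomes[str(pid)]
        rows.append(feats)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    lead = [c for c in ("patient_id", "outcome", "baseline_day", "uptime_min") if c in df]
    return df[lead + [c for c in df.columns if c not in lead]]


def feature_availability(table: pd.DataFrame, outcome_col: str = "outcome") -> pd.DataFrame:
    """Per-feature availability counts (non-NaN rows) per outcome group."""
    numeric = table.select_dtypes(include=[float, int])
    groups = table[outcome_col] if outcome_col in table else pd.Series("all", index=table.index)
    return numeric.notna().groupby(groups).sum().T


def inclusion_summary(n_consented: int, n_excluded: int, n_community: int) -> dict[str, float]:
    """Cohort bookkeeping: included count and the community share (%) of the
    included sample."""
    if n_excluded > n_consented:
        raise ValueError("cannot exclude more patients than consented")
    included = n_consented - n_excluded
    if not 0 <= n_community <= included:
        raise ValueError("community count must lie within the included sample")
    return {
        "n_included": included,
        "community_pct": 100.0 * n_community / included if included else float("nan"),
    }
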