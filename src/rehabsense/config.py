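"""Pipeline configuration: every tunable constant of the analysis protocol,
with the study defaults, serializable to/from YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import DEFAULT_GROUP_EFFECT_MAP, CohortConfig


@dataclass
class PipelineConfig:
    seed: int = 40
    # sensing protocol
    sample_rate_hz: float = 16.0
    window_s: float = 10.0
    overlap_s: float = 1.0
    filter_order: int = 5
    filter_band_hz: tuple[float, float] = (0.5, 8.0)
    mad_threshold_ms2: float = 0.02
    rssi_clip_dbm: tuple[float, float] = (-100.0, -50.0)
    advert_interval_s: float = 0.25
    tx_power_dbm: float = -12.0
    # inclusion / feature rules
    min_uptime_min: float = 240.0
    min_therapy_min: float = 15.0
    baseline_window_days: int = 3
    intensity_cutoff: float = 90.0
    # synthetic cohort
    n_community: int = 10
    n_hospital: int = 5
    n_days: int = 3
    n_calibration_days: int = 3
    rssi_noise_sd: float = 4.0
    p_remove_early: float = 0.5
    group_effect_map: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECT_MAP)
    )

    def validate(self) -> "PipelineConfig":
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError("need 0 <= overlap_s < window_s")
        low, high = self.filter_band_hz
        if not 0 < low < high <= self.sample_rate_hz / 2:
            raise ValueError("filter band incompatible with sample rate")
        lo, hi = self.rssi_clip_dbm
        if lo >= hi:
            raise ValueError("rssi_clip_dbm must be (low, high)")
        for name in ("mad_threshold_ms2", "min_uptime_min", "min_therapy_min",
                     "intensity_cutoff", "advert_interval_s"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive number")
        if self.n_community < 0 or self.n_hospital < 0 or self.n_days < 1:
            raise ValueError("invalid cohort sizes")
        return self

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_community=self.n_community,
            n_hospital=self.n_hospital,
            seed=self.seed,
            n_days=self.n_days,
            group_effect_map=dict(self.group_effect_map),
            rssi_noise_sd=self.rssi_noise_sd,
            advert_interval=self.advert_interval_s,
            sample_rate=self.sample_rate_hz,
            p_remove_early=self.p_remove_early,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter_band_hz"] = list(self.filter_band_hz)
        d["rssi_clip_dbm"] = list(self.rssi_clip_dbm)
        d["group_effect_map"] = {k: list(v) for k, v in self.group_effect_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise ValueError(f"missing config keys: {sorted(missing)}")
        d = dict(d)
        d["filter_band_hz"] = tuple(d["filter_band_hz"])
        d["rssi_clip_dbm"] = tuple(d["rssi_clip_dbm"])
        d["group_effect_map"] = {k: tuple(v) for k, v in d["group_effect_map"].items()}
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
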