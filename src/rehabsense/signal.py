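"""Accelerometer signal processing.

The processing chain mirrors a wrist-worn actigraphy pipeline for frail,
largely stationary populations: the per-sample Euclidean signal magnitude (SM)
of the three acceleration axes is band-pass filtered (5th-order Butterworth,
0.5-8 Hz) in 10-second batches of 160 samples, and each window is summarised
by the mean absolute deviation (MAD) of the filtered magnitude in m/s^2.
A window is "active" when its MAD reaches 0.02 m/s^2 (2 cm/s^2) and "idle"
otherwise; under constant acceleration at that threshold a hand starting at
rest would travel 1 m over the 10-second window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

GRAVITY_MS2 = 9.81  # g -> m/s^2 conversion used throughout
MAD_THRESHOLD_MS2 = 0.02  # active/idle split on windowed MAD

__all__ = [
    "GRAVITY_MS2",
    "MAD_THRESHOLD_MS2",
    "AccelStream",
    "FilterSpec",
    "WindowGrid",
    "WindowRecord",
    "compute_signal_magnitude",
    "bandpass_filter",
    "frequency_response",
    "applied_gain",
    "segment_windows",
    "window_matrix",
    "compute_mad",
    "classify_motion_state",
    "displacement_from_acceleration",
    "analyze_stream",
]


@dataclass
class AccelStream:
    """Timestamped triaxial acceleration, in g (gravity included), for one
    patient-day.  Timestamps are seconds since midnight and must be strictly
    increasing; values are clipped by the sensor to +/- 2 g."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    patient_id: str = ""
    day: int = 1
    sample_rate_hz: float = 16.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise ValueError("accelerometer axes and timestamps must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, a in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if a.size and np.nanmax(np.abs(a)) > 2.0 + 1e-9:
                raise ValueError(f"{name} exceeds the +/-2 g sensor range")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter design: 5th-order Butterworth, 0.5-8 Hz at 16 Hz.

    The upper band edge of the study protocol coincides with the Nyquist
    frequency; a digital band-pass cannot place a cutoff exactly at Nyquist,
    so the design clamps the upper edge to 99.5% of Nyquist.  The clamped
    value is exposed as ``effective_band_hz``.
    """

    order: int = 5
    band_hz: tuple[float, float] = (0.5, 8.0)
    sample_rate_hz: float = 16.0

    def __post_init__(self) -> None:
        low, high = self.band_hz
        nyq = self.sample_rate_hz / 2.0
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0.0 < low < high <= nyq):
            raise ValueError(
                f"band {self.band_hz} incompatible with sample rate "
                f"{self.sample_rate_hz} Hz (need 0 < low < high <= Nyquist)"
            )

    @property
    def effective_band_hz(self) -> tuple[float, float]:
        nyq = self.sample_rate_hz / 2.0
        low, high = self.band_hz
        return (low, min(high, 0.995 * nyq))

    def sos(self) -> np.ndarray:
        low, high = self.effective_band_hz
        return sps.butter(
            self.order, [low, high], btype="bandpass", fs=self.sample_rate_hz, output="sos"
        )


def compute_signal_magnitude(ax, ay, az) -> np.ndarray:
    """Elementwise Euclidean magnitude sqrt(ax^2 + ay^2 + az^2), in g."""
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("axis series must have equal length")
    return np.sqrt(ax * ax + ay * ay + az * az)


def _min_length(spec: FilterSpec) -> int:
    # sosfiltfilt needs more than its default pad length of samples
    n_sections = spec.sos().shape[0]
    return 3 * (2 * n_sections + 1)


def bandpass_filter(sm: np.ndarray, spec: FilterSpec | None = None, axis: int = -1) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass of a magnitude
    series.  Removes the DC (gravity) component; output is in the input's
    units."""
    spec = spec or FilterSpec()
    sm = np.asarray(sm, dtype=float)
    if sm.shape[axis] <= _min_length(spec):
        raise ValueError(
            f"series of length {sm.shape[axis]} is shorter than the filter warm-up "
            f"({_min_length(spec)} samples)"
        )
    return sps.sosfiltfilt(spec.sos(), sm, axis=axis)


def frequency_response(spec: FilterSpec, freqs_hz) -> np.ndarray:
    """Single-pass magnitude response |H(f)| of the designed filter."""
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    w = 2.0 * np.pi * freqs_hz / spec.sample_rate_hz
    _, h = sps.sosfreqz(spec.sos(), worN=w)
    return np.abs(h)


def applied_gain(spec: FilterSpec, freqs_hz) -> np.ndarray:
    """Steady-state gain of the zero-phase application, |H(f)|^2."""
    return frequency_response(spec, freqs_hz) ** 2


@dataclass
class WindowGrid:
    """Start indices/times and time credits of the 10-second analysis windows
    of one stream.  Windows are anchored to contiguous wear runs (a window
    never spans a gap in the samples); consecutive windows share ``overlap_s``
    seconds, i.e. the stride is ``window_s - overlap_s``.  Each window is
    credited with the stride, except the last window of a run which is
    credited its full span, so credits tile the covered time exactly."""

    start_idx: np.ndarray
    start_time: np.ndarray
    credit_s: np.ndarray
    n_samples: int
    run_id: np.ndarray

    def __len__(self) -> int:
        return int(self.start_idx.size)


def _contiguous_runs(t: np.ndarray, fs: float, gap_tol: float = 1.5) -> list[tuple[int, int]]:
    """[start, stop) index ranges between sampling gaps larger than
    gap_tol/fs seconds."""
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > gap_tol / fs)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [t.size]))
    return list(zip(starts.tolist(), stops.tolist()))


def segment_windows(
    t: np.ndarray,
    sample_rate_hz: float = 16.0,
    window_s: float = 10.0,
    overlap_s: float = 1.0,
    gap_tol: float = 1.5,
) -> WindowGrid:
    """Slice a (possibly gappy) timestamp series into overlapping analysis
    windows.  Trailing partial windows are discarded; wear gaps are never
    bridged."""
    t = np.asarray(t, dtype=float)
    if not 0.0 <= overlap_s < window_s:
        raise ValueError("need 0 <= overlap_s < window_s")
    n_win = int(round(window_s * sample_rate_hz))
    n_stride = int(round((window_s - overlap_s) * sample_rate_hz))
    starts: list[int] = []
    credits: list[float] = []
    runs: list[int] = []
    for run, (i0, i1) in enumerate(_contiguous_runs(t, sample_rate_hz, gap_tol)):
        pos = i0
        first_of_run = len(starts)
        while pos + n_win <= i1:
            starts.append(pos)
            credits.append(window_s - overlap_s)
            runs.append(run)
            pos += n_stride
        if len(starts) > first_of_run:
            credits[-1] = window_s  # last window of the run keeps its full span
    start_idx = np.asarray(starts, dtype=int)
    return WindowGrid(
        start_idx=start_idx,
        start_time=t[start_idx] if start_idx.size else np.empty(0),
        credit_s=np.asarray(credits, dtype=float),
        n_samples=n_win,
        run_id=np.asarray(runs, dtype=int),
    )


def window_matrix(values: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """(n_windows, n_samples) matrix of raw window contents."""
    values = np.asarray(values, dtype=float)
    if len(grid) == 0:
        return np.empty((0, grid.n_samples))
    idx = grid.start_idx[:, None] + np.arange(grid.n_samples)[None, :]
    return values[idx]


def compute_mad(x: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Mean absolute deviation around the window mean, (1/n) * sum|x_i - x_ave|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute MAD of an empty window")
    mean = np.mean(x, axis=axis, keepdims=axis is not None)
    out = np.mean(np.abs(x - mean), axis=axis)
    return out


def classify_motion_state(mad, threshold: float = MAD_THRESHOLD_MS2):
    """'active' iff MAD >= threshold (in m/s^2), else 'idle'."""
    arr = np.asarray(mad, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MAD must be non-negative")
    states = np.where(arr >= threshold, "active", "idle")
    if np.isscalar(mad) or arr.ndim == 0:
        return str(states)
    return states


def displacement_from_acceleration(a: float, t: float) -> float:
    """Displacement 0.5*a*t^2 of a point starting at rest under constant
    acceleration ``a`` (m/s^2) over ``t`` seconds."""
    if a < 0:
        raise ValueError("acceleration must be non-negative")
    if t < 0:
        raise ValueError("time must be non-negative")
    return 0.5 * a * t * t


@dataclass
class WindowRecord:
    """One analysed 10-second window."""

    start_time: float
    sm_filtered: np.ndarray  # m/s^2
    mad: float  # m/s^2
    motion_state: str
    credit_s: float = 9.0
    patient_id: str = ""
    day: int = 1


@dataclass
class WindowTable:
    """Vectorised per-window results of :func:`analyze_stream`."""

    grid: WindowGrid
    sm_filtered_ms2: np.ndarray  # (n_windows, 160)
    mad_ms2: np.ndarray
    motion_state: np.ndarray
    patient_id: str = ""
    day: int = 1

    def __len__(self) -> int:
        return len(self.grid)

    def records(self) -> list[WindowRecord]:
        return [
            WindowRecord(
                start_time=float(self.grid.start_time[i]),
                sm_filtered=self.sm_filtered_ms2[i],
                mad=float(self.mad_ms2[i]),
                motion_state=str(self.motion_state[i]),
                credit_s=float(self.grid.credit_s[i]),
                patient_id=self.patient_id,
                day=self.day,
            )
            for i in range(len(self))
        ]


def analyze_stream(
    stream: AccelStream,
    spec: FilterSpec | None = None,
    mad_threshold: float = MAD_THRESHOLD_MS2,
    window_s: float = 10.0,
    overlap_s: float = 1.0,
) -> WindowTable:
    """Full per-window chain: SM -> batch band-pass -> m/s^2 -> MAD ->
    active/idle.  Filtering is applied per 160-sample batch (zero-phase)."""
    spec = spec or FilterSpec(sample_rate_hz=stream.sample_rate_hz)
    sm = compute_signal_magnitude(stream.ax, stream.ay, stream.az)
    grid = segment_windows(
        stream.t, sample_rate_hz=stream.sample_rate_hz, window_s=window_s, overlap_s=overlap_s
    )
    raw = window_matrix(sm, grid)
    if raw.shape[0]:
        filt = bandpass_filter(raw, spec, axis=-1) * GRAVITY_MS2
        mad = np.asarray(compute_mad(filt, axis=1), dtype=float)
        motion = classify_motion_state(mad, mad_threshold)
    else:
        filt = np.empty((0, grid.n_samples))
        mad = np.empty(0)
        motion = np.empty(0, dtype=object)
    return WindowTable(
        grid=grid,
        sm_filtered_ms2=filt,
        mad_ms2=mad,
        motion_state=motion,
        patient_id=stream.patient_id,
        day=stream.day,
    )
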