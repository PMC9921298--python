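"""Raw recording + foot-contact events -> fixed-length magnitude strides.

The pipeline follows the order: segment gait cycles (foot-strike to
foot-strike of the sensor side), resample each axis onto a fixed normalized
length L, then collapse to the angular-velocity magnitude
|v| = sqrt(vx^2 + vy^2 + vz^2) per normalized sample. Resampling the three
axes before taking magnitudes differs from the reverse order only by
O(interpolation error), but the order here is fixed so results are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .signal_io import Condition, DataError, EventType, GaitEventTable, GyroRecording, Side

__all__ = [
    "Stride",
    "NormalizedStride",
    "StrideSet",
    "DEFAULT_NORMALIZED_LENGTH",
    "segment_strides",
    "stride_magnitude",
    "time_normalize",
    "build_stride_set",
]

#: 0-100% of the gait cycle in 1% steps.
DEFAULT_NORMALIZED_LENGTH = 101

# Guard against float round-off when mapping event times to sample indices:
# a strike at k/rate must map to index k even if t*rate lands at k - 1e-13.
_INDEX_EPS = 1e-9


class BoundaryError(ValueError):
    """A gait event falls outside the recording's time span."""


@dataclass(frozen=True)
class Stride:
    """One gait cycle (foot-strike to next same-side foot-strike), raw samples."""

    start_time: float
    end_time: float
    raw_samples: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise DataError("stride end_time must exceed start_time")
        samples = np.asarray(self.raw_samples, dtype=float)
        if samples.shape[0] == 0:
            raise DataError("stride has no samples")
        object.__setattr__(self, "raw_samples", samples)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class NormalizedStride:
    """Angular-velocity magnitude over one cycle, resampled to fixed length."""

    values: np.ndarray  # (L,), deg/s, >= 0
    source_duration: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise DataError("normalized stride contains non-finite values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StrideSet:
    """A condition's worth of normalized strides, all sharing length L."""

    strides: list[NormalizedStride]
    condition: Condition
    L: int

    def __post_init__(self) -> None:
        for s in self.strides:
            if len(s) != self.L:
                raise DataError("all strides in a StrideSet must share length L")

    def __len__(self) -> int:
        return len(self.strides)

    def to_matrix(self) -> np.ndarray:
        """Stack strides into an (n, L) array."""
        return np.vstack([s.values for s in self.strides])

    def durations(self) -> np.ndarray:
        return np.array([s.source_duration for s in self.strides])


def _time_to_index(t: float, recording: GyroRecording) -> int:
    return int(np.floor((t - recording.start_time) * recording.sample_rate + _INDEX_EPS))


def segment_strides(
    recording: GyroRecording, events: GaitEventTable, side: Side = Side.PRO
) -> list[Stride]:
    """Partition a recording into gait cycles at consecutive foot strikes.

    Stride k spans the half-open window [strike_k, strike_{k+1}), mapped to
    sample indices by floor(t * sample_rate). Fewer than two strikes yield an
    empty list; a strike outside the recording span is an error.
    """
    strikes = events.strikes(side)
    if len(strikes) < 2:
        return []
    if strikes[0] < recording.start_time - _INDEX_EPS or strikes[-1] > recording.end_time + _INDEX_EPS:
        raise BoundaryError(
            f"foot strikes span [{strikes[0]}, {strikes[-1]}] s but the recording "
            f"covers [{recording.start_time}, {recording.end_time}] s"
        )
    strides = []
    for t0, t1 in zip(strikes[:-1], strikes[1:]):
        i0 = _time_to_index(t0, recording)
        i1 = _time_to_index(t1, recording)
        i1 = min(i1, recording.n_samples)
        if i1 <= i0:
            continue  # degenerate cycle shorter than one sample
        strides.append(
            Stride(start_time=float(t0), end_time=float(t1), raw_samples=recording.samples[i0:i1])
        )
    return strides


def stride_magnitude(stride: Stride) -> np.ndarray:
    """Per-sample angular-velocity magnitude sqrt(vx^2 + vy^2 + vz^2)."""
    samples = stride.raw_samples
    if not np.all(np.isfinite(samples)):
        raise DataError("stride contains non-finite components")
    return np.sqrt(np.einsum("ij,ij->i", samples, samples))


def _resample(values: np.ndarray, L: int, kind: str) -> np.ndarray:
    n = len(values)
    u_in = np.linspace(0.0, 1.0, n)
    u_out = np.linspace(0.0, 1.0, L)
    if kind == "linear":
        return np.interp(u_out, u_in, values)
    if kind == "cubic":
        return CubicSpline(u_in, values)(u_out)
    raise ValueError(f"unknown resampling kind {kind!r}")


def time_normalize(values, L: int = DEFAULT_NORMALIZED_LENGTH, *, kind: str = "linear") -> NormalizedStride:
    """Resample a magnitude sequence onto L points spanning 0-100% of the cycle.

    Linear interpolation by default; endpoints are preserved exactly. The
    operation is idempotent at length L.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise DataError("time_normalize needs a 1-d sequence of length >= 2")
    if L < 2:
        raise DataError("normalized length L must be >= 2")
    return NormalizedStride(values=_resample(values, L, kind), source_duration=float("nan"))


def build_stride_set(
    recording: GyroRecording,
    events: GaitEventTable,
    side: Side = Side.PRO,
    L: int = DEFAULT_NORMALIZED_LENGTH,
    *,
    kind: str = "linear",
    max_duration_ratio: float | None = None,
) -> StrideSet:
    """Segment, resample each axis to L, then take the magnitude per sample.

    ``max_duration_ratio`` optionally drops strides whose duration exceeds
    that multiple of the median stride duration (no rejection by default).
    """
    strides = segment_strides(recording, events, side)
    if max_duration_ratio is not None and strides:
        med = float(np.median([s.duration for s in strides]))
        strides = [s for s in strides if s.duration <= max_duration_ratio * med]
    normalized = []
    for stride in strides:
        if stride.raw_samples.shape[0] < 2:
            continue
        axes = np.column_stack(
            [_resample(stride.raw_samples[:, a], L, kind) for a in range(3)]
        )
        mag = np.sqrt(np.einsum("ij,ij->i", axes, axes))
        normalized.append(NormalizedStride(values=mag, source_duration=stride.duration))
    return StrideSet(strides=normalized, condition=recording.condition, L=L)
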