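"""File formats and typed session containers.

All interchange files are plain CSV (comma-separated, dot decimal, UTF-8,
mandatory header row; parsing is header-driven, never positional). Times are
seconds from trial start; angular velocity is deg/s. Classification results
round-trip through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Side",
    "EventType",
    "Joint",
    "FormatError",
    "DataError",
    "SampleRateError",
    "GyroRecording",
    "GaitEventTable",
    "AngleTrace",
    "FootPositionTrace",
    "read_gyro_csv",
    "write_gyro_csv",
    "read_events_csv",
    "write_events_csv",
    "read_angles_csv",
    "write_angles_csv",
    "read_positions_csv",
    "write_positions_csv",
    "write_result_json",
    "read_result_json",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits for lossless-enough round trips


class Condition(str, Enum):
    """The four walking trials of one gait-training session.

    PRE_NP: before training, no prompting. MID_P: mid-training, with verbal
    prompting. POST_P: immediately after training, with prompting. POST_NP:
    after a rest period, no prompting.
    """

    PRE_NP = "PRE_NP"
    MID_P = "MID_P"
    POST_P = "POST_P"
    POST_NP = "POST_NP"

    __str__ = str.__str__  # StrEnum semantics: str(c) == c.value


class Side(str, Enum):
    PRO = "pro"  # prosthetic (sensor) side
    NONPRO = "nonpro"

    __str__ = str.__str__


class EventType(str, Enum):
    FOOT_STRIKE = "foot_strike"
    FOOT_OFF = "foot_off"

    __str__ = str.__str__


class Joint(str, Enum):
    HIP_PRO = "hip_pro"
    HIP_NONPRO = "hip_nonpro"
    KNEE_PRO = "knee_pro"
    KNEE_NONPRO = "knee_nonpro"

    __str__ = str.__str__


class FormatError(ValueError):
    """File does not match the expected CSV dialect (e.g. missing columns)."""


class DataError(ValueError):
    """File parses but its content violates a data invariant."""


class SampleRateError(ValueError):
    """Declared sample rate disagrees with the file's time column."""


@dataclass(frozen=True)
class GyroRecording:
    """Uniformly sampled tri-axial angular velocity for one walking trial.

    ``samples`` is an (n, 3) float array of (vx, vy, vz) in deg/s, implicitly
    spaced 1/sample_rate apart starting at ``start_time`` seconds.
    """

    participant_id: str
    condition: Condition
    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise DataError("gyro samples must be an (n, 3) array")
        if samples.shape[0] == 0:
            raise DataError("gyro recording is empty")
        if not np.all(np.isfinite(samples)):
            raise DataError("gyro samples contain non-finite values")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class GaitEventTable:
    """Foot-contact events: rows of (time_s, side, event).

    Within each side, times are strictly increasing and FOOT_STRIKE /
    FOOT_OFF strictly alternate (either may come first).
    """

    rows: pd.DataFrame  # columns: time_s (float), side (Side), event (EventType)

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        required = {"time_s", "side", "event"}
        if not required.issubset(df.columns):
            raise FormatError(f"event table needs columns {sorted(required)}")
        df["time_s"] = df["time_s"].astype(float)
        df["side"] = df["side"].map(Side)
        df["event"] = df["event"].map(EventType)
        for side in Side:
            sub = df[df["side"] == side]
            t = sub["time_s"].to_numpy()
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                bad = sub.index[1:][~(np.diff(t) > 0)][0]
                raise DataError(f"non-increasing {side.value} event time at row {bad}")
            ev = sub["event"].tolist()
            for i in range(1, len(ev)):
                if ev[i] == ev[i - 1]:
                    raise DataError(
                        f"two consecutive {side.value} {ev[i].value} events "
                        f"(row {sub.index[i]}): strike/off must alternate"
                    )
        object.__setattr__(self, "rows", df)

    def __len__(self) -> int:
        return len(self.rows)

    def times(self, side: Side, event: EventType) -> np.ndarray:
        mask = (self.rows["side"] == side) & (self.rows["event"] == event)
        return self.rows.loc[mask, "time_s"].to_numpy()

    def strikes(self, side: Side) -> np.ndarray:
        return self.times(side, EventType.FOOT_STRIKE)

    def offs(self, side: Side) -> np.ndarray:
        return self.times(side, EventType.FOOT_OFF)


@dataclass(frozen=True)
class AngleTrace:
    """Joint flexion/extension angle in degrees, uniformly sampled."""

    joint: Joint
    sample_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise DataError("angle trace contains non-finite values")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")
        object.__setattr__(self, "values", values)

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sample_rate


@dataclass(frozen=True)
class FootPositionTrace:
    """Forward-axis foot displacement in meters, uniformly sampled."""

    side: Side
    sample_rate: float
    positions: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(positions)):
            raise DataError("position trace contains non-finite values")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")
        object.__setattr__(self, "positions", positions)

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.positions)) / self.sample_rate


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gyro_csv(
    path,
    participant_id: str,
    condition: Condition,
    sample_rate: float,
) -> GyroRecording:
    """Read a `time_s,gyro_x,gyro_y,gyro_z` file into a GyroRecording.

    The declared ``sample_rate`` is verified against the median inter-sample
    interval (must agree within 1%); a mismatch raises SampleRateError rather
    than silently resampling.
    """
    df = _read_csv(path, {"time_s", "gyro_x", "gyro_y", "gyro_z"})
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise DataError(f"{path}: time_s is not strictly increasing")
        median_dt = float(np.median(dt))
        if abs(median_dt - 1.0 / sample_rate) > 0.01 / sample_rate:
            raise SampleRateError(
                f"{path}: median interval {median_dt:.6g} s does not match "
                f"declared rate {sample_rate} Hz within 1%"
            )
    samples = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float)
    return GyroRecording(
        participant_id=participant_id,
        condition=Condition(condition),
        sample_rate=sample_rate,
        samples=samples,
        start_time=float(t[0]) if len(t) else 0.0,
    )


def write_gyro_csv(recording: GyroRecording, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": recording.times(),
            "gyro_x": recording.samples[:, 0],
            "gyro_y": recording.samples[:, 1],
            "gyro_z": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path) -> GaitEventTable:
    """Read a `time_s,side,event` file into a validated GaitEventTable."""
    df = _read_csv(path, {"time_s", "side", "event"})
    try:
        return GaitEventTable(df[["time_s", "side", "event"]])
    except ValueError as exc:
        if isinstance(exc, (DataError, FormatError)):
            raise
        raise DataError(f"{path}: {exc}") from exc


def write_events_csv(events: GaitEventTable, path) -> None:
    out = events.rows.copy()
    out["side"] = out["side"].map(lambda s: s.value)
    out["event"] = out["event"].map(lambda e: e.value)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_angles_csv(path) -> dict[Joint, AngleTrace]:
    """Read long-format `time_s,joint,angle_deg` into per-joint AngleTraces."""
    df = _read_csv(path, {"time_s", "joint", "angle_deg"})
    traces: dict[Joint, AngleTrace] = {}
    for name, sub in df.groupby("joint", sort=False):
        joint = Joint(name)
        t = sub["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise DataError(f"{path}: joint {name} has fewer than 2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        traces[joint] = AngleTrace(
            joint=joint,
            sample_rate=rate,
            values=sub["angle_deg"].to_numpy(dtype=float),
            start_time=float(t[0]),
        )
    return traces


def write_angles_csv(traces: Mapping[Joint, AngleTrace], path) -> None:
    frames = []
    for joint, trace in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": trace.times(),
                    "joint": joint.value,
                    "angle_deg": trace.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_positions_csv(path) -> dict[Side, FootPositionTrace]:
    """Read long-format `time_s,side,pos_m` into per-side position traces."""
    df = _read_csv(path, {"time_s", "side", "pos_m"})
    traces: dict[Side, FootPositionTrace] = {}
    for name, sub in df.groupby("side", sort=False):
        side = Side(name)
        t = sub["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise DataError(f"{path}: side {name} has fewer than 2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        traces[side] = FootPositionTrace(
            side=side,
            sample_rate=rate,
            positions=sub["pos_m"].to_numpy(dtype=float),
            start_time=float(t[0]),
        )
    return traces


def write_positions_csv(traces: Mapping[Side, FootPositionTrace], path) -> None:
    frames = []
    for side, trace in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": trace.times(),
                    "side": side.value,
                    "pos_m": trace.positions,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Classification result JSON
# ---------------------------------------------------------------------------

def write_result_json(result, path) -> None:
    """Serialize a ClassificationResult (lossless round trip with the reader)."""
    payload = result.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_result_json(path):
    from .gait_classifier import ClassificationResult

    payload = json.loads(Path(path).read_text())
    return ClassificationResult.from_dict(payload)
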