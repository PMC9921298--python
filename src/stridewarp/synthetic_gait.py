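"""Synthetic four-condition gait sessions (gyro, events, angles, positions).

The generator emulates a single-participant gait-training session: four
walking trials (PRE_NP, MID_P, POST_P, POST_NP) of 100-125 strides each,
recorded at 100 Hz by a thigh-mounted gyroscope. Each stride's magnitude
waveform is a baseline plus a sum of Gaussian bumps in normalized stride time
(two bumps by default: a stance peak and a larger swing peak, the typical
thigh angular-velocity profile). Gait change is modeled as per-bump amplitude
and timing offsets applied fully to the POST_P waveform and scaled by a blend
lambda in [0, 1] for the intermediate conditions (PRE_NP: 0, MID_P: lambda_mid,
POST_NP: lambda_postnp). Stride-to-stride variability comes from per-stride
jitter of the bump parameters plus isotropic additive sensor noise; a
variance-ratio knob scales the POST-class variability to emulate unequal
stride dispersion between trials.

The waveform is decomposed onto three fixed unit direction cosines so the
angular-velocity magnitude recovers it exactly before noise. Stride
boundaries (and all emitted events) are quantized to the sample grid, which
makes segmentation, stance times, and nearest-sample position lookups exact;
ground truth for every generated quantity is returned alongside the data.

All randomness flows from one root seed through named substreams, so
individual components (durations, shape jitter, noise, kinematics) are
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .signal_io import (
    AngleTrace,
    Condition,
    EventType,
    FootPositionTrace,
    GaitEventTable,
    GyroRecording,
    Joint,
    Side,
)

__all__ = [
    "SynthSessionConfig",
    "SynthSession",
    "ConfigError",
    "generate_session",
    "generate_no_change_session",
]

import pandas as pd


class ConfigError(ValueError):
    """Inconsistent synthetic-session configuration."""


# Fixed unit direction cosines for the tri-axial decomposition: the magnitude
# of w * _DIRCOS is exactly w before additive noise.
_DIRCOS = np.array([0.8, 0.5, 0.33])
_DIRCOS = _DIRCOS / np.linalg.norm(_DIRCOS)

# Baseline angle offsets (deg); arbitrary, ROM is offset-invariant.
_ANGLE_OFFSET = {
    Joint.HIP_PRO: 10.0,
    Joint.HIP_NONPRO: 10.0,
    Joint.KNEE_PRO: 25.0,
    Joint.KNEE_NONPRO: 25.0,
}

_BLEND_ORDER = (Condition.PRE_NP, Condition.MID_P, Condition.POST_P, Condition.POST_NP)


def _default_rom_means() -> dict[Joint, tuple[float, float]]:
    # (PRE_NP mean, POST_P mean) degrees; training typically increases
    # prosthetic-side hip/knee excursion.
    return {
        Joint.HIP_PRO: (38.0, 44.0),
        Joint.HIP_NONPRO: (40.0, 42.0),
        Joint.KNEE_PRO: (55.0, 60.0),
        Joint.KNEE_NONPRO: (58.0, 59.0),
    }


def _default_step_means() -> dict[Side, tuple[float, float]]:
    return {Side.PRO: (0.58, 0.63), Side.NONPRO: (0.62, 0.63)}


@dataclass(frozen=True)
class SynthSessionConfig:
    """Full parameterization of a simulated four-condition session.

    ``bumps`` are (center, width, amplitude) triples in normalized stride time
    (center in [0, 1), width as Gaussian sigma, amplitude in deg/s);
    ``class_shift`` gives the POST_P offset (d_amplitude, d_center) per bump.
    ``variance_ratio`` multiplies both the shape jitter and the additive noise
    of the fully-shifted class (scaled by the blend for intermediates), so the
    mean per-timepoint stride SD of POST_P is about that multiple of PRE_NP's.
    """

    n_strides_per_condition: int | None = None  # None: drawn uniformly in [100, 125]
    sample_rate: float = 100.0
    stride_duration_mean: float = 1.1  # s
    stride_duration_sd: float = 0.05  # s
    baseline: float = 25.0  # deg/s floor of the magnitude profile
    bumps: tuple[tuple[float, float, float], ...] = (
        (0.28, 0.10, 130.0),
        (0.72, 0.07, 260.0),
    )
    class_shift: tuple[tuple[float, float], ...] = ((20.0, 0.0), (45.0, 0.02))
    amplitude_jitter_sd: float = 10.0  # deg/s, per bump per stride
    center_jitter_sd: float = 0.012  # normalized time
    width_jitter_sd: float = 0.006
    additive_noise_sd: float = 6.0  # deg/s per axis
    variance_ratio: float = 1.0
    mid_blend: float = 0.5
    postnp_blend: float = 0.8
    stance_fraction: float = 0.62  # fraction of the cycle each foot is down
    inter_side_phase: float = 0.5  # contralateral strike offset, cycle fraction
    rom_means: dict[Joint, tuple[float, float]] = field(default_factory=_default_rom_means)
    rom_jitter_sd: float = 1.5  # deg
    step_length_means: dict[Side, tuple[float, float]] = field(
        default_factory=_default_step_means
    )
    step_jitter_sd: float = 0.015  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_shift) != len(self.bumps):
            raise ConfigError("class_shift must give one (d_amp, d_center) per bump")
        if not 0 < self.stance_fraction < 1:
            raise ConfigError("stance_fraction must be in (0, 1)")
        if not 0 < self.inter_side_phase < 1:
            raise ConfigError("inter_side_phase must be in (0, 1)")
        if self.inter_side_phase + self.stance_fraction <= 1.0:
            raise ConfigError(
                "inter_side_phase + stance_fraction must exceed 1 for walking "
                "(otherwise there is flight, not double support)"
            )
        for name in (
            "stride_duration_sd",
            "amplitude_jitter_sd",
            "center_jitter_sd",
            "width_jitter_sd",
            "additive_noise_sd",
            "rom_jitter_sd",
            "step_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("mid_blend", "postnp_blend"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.stride_duration_mean <= 0.3:
            raise ConfigError("stride_duration_mean must exceed 0.3 s")
        if self.variance_ratio <= 0:
            raise ConfigError("variance_ratio must be positive")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")

    def blends(self) -> dict[Condition, float]:
        return {
            Condition.PRE_NP: 0.0,
            Condition.MID_P: self.mid_blend,
            Condition.POST_P: 1.0,
            Condition.POST_NP: self.postnp_blend,
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bumps"] = [list(b) for b in self.bumps]
        d["class_shift"] = [list(s) for s in self.class_shift]
        d["rom_means"] = {j.value: list(v) for j, v in self.rom_means.items()}
        d["step_length_means"] = {
            s.value: list(v) for s, v in self.step_length_means.items()
        }
        return d

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SynthSessionConfig":
        d = dict(payload)
        if "bumps" in d:
            d["bumps"] = tuple(tuple(b) for b in d["bumps"])
        if "class_shift" in d:
            d["class_shift"] = tuple(tuple(s) for s in d["class_shift"])
        if "rom_means" in d:
            d["rom_means"] = {Joint(k): tuple(v) for k, v in d["rom_means"].items()}
        if "step_length_means" in d:
            d["step_length_means"] = {
                Side(k): tuple(v) for k, v in d["step_length_means"].items()
            }
        return cls(**d)


@dataclass
class SynthSession:
    """Generated data plus complete ground truth, one entry per condition."""

    config: SynthSessionConfig
    recordings: dict[Condition, GyroRecording]
    events: dict[Condition, GaitEventTable]
    angles: dict[Condition, dict[Joint, AngleTrace]]
    positions: dict[Condition, dict[Side, FootPositionTrace]]
    truth: dict[Condition, dict]


def _waveform(u: np.ndarray, baseline: float, params: np.ndarray) -> np.ndarray:
    """baseline + sum of Gaussian bumps; params rows are (center, width, amp)."""
    w = np.full_like(u, baseline)
    for c, s, a in params:
        w += a * np.exp(-0.5 * ((u - c) / s) ** 2)
    return w


def _draw_durations(rng, n: int, mean: float, sd: float, rate: float) -> np.ndarray:
    """Stride durations ~ Normal(mean, sd) truncated above 0.3 s, quantized to
    whole samples."""
    out = np.empty(n)
    for i in range(n):
        d = rng.normal(mean, sd)
        while d <= 0.3:
            d = rng.normal(mean, sd)
        out[i] = d
    return np.maximum(np.round(out * rate), 2) / rate


def _generate_condition(
    config: SynthSessionConfig,
    condition: Condition,
    blend: float,
    n_strides: int,
    rngs: dict[str, np.random.Generator],
):
    rate = config.sample_rate
    jitter_scale = 1.0 + blend * (config.variance_ratio - 1.0)

    # n_strides real cycles plus one tail pseudo-stride so both sides' final
    # stance phases close with a foot-off inside the recording.
    durations = _draw_durations(
        rngs["durations"],
        n_strides + 1,
        config.stride_duration_mean,
        config.stride_duration_sd,
        rate,
    )
    n_samp = np.round(durations * rate).astype(int)
    # sample index of strike k, for k = 0..n_strides
    starts = np.concatenate([[0], np.cumsum(n_samp[:n_strides])]).astype(int)

    base = np.array(config.bumps, dtype=float)  # (n_bumps, 3): center, width, amp
    shift = np.array(config.class_shift, dtype=float)  # (n_bumps, 2): d_amp, d_center

    # --- gyroscope signal -------------------------------------------------
    # the tail pseudo-stride must reach past its own nonpro foot-off at
    # (phase + stance_fraction) of the tail cycle
    tail_frac = max(1.2, config.inter_side_phase + config.stance_fraction + 0.05)
    tail_extra = int(np.round(tail_frac * n_samp[-1])) + 1
    total = int(starts[-1]) + tail_extra
    signal = np.empty((total, 3))
    bump_truth = []
    for k in range(n_strides + 1):
        params = base.copy()
        params[:, 2] += blend * shift[:, 0]  # amplitude shift
        params[:, 0] += blend * shift[:, 1]  # center shift
        params[:, 2] += jitter_scale * rngs["shape"].normal(
            0.0, config.amplitude_jitter_sd, len(params)
        )
        params[:, 0] += jitter_scale * rngs["shape"].normal(
            0.0, config.center_jitter_sd, len(params)
        )
        params[:, 1] = np.maximum(
            params[:, 1]
            + jitter_scale * rngs["shape"].normal(0.0, config.width_jitter_sd, len(params)),
            0.02,
        )
        m = n_samp[k] if k < n_strides else tail_extra
        u = np.arange(m) / n_samp[k]
        w = np.maximum(_waveform(u, config.baseline, params), 0.0)
        seg = w[:, None] * _DIRCOS[None, :]
        seg += rngs["noise"].normal(
            0.0, config.additive_noise_sd * jitter_scale, seg.shape
        )
        signal[starts[k] : starts[k] + m] = seg
        if k < n_strides:
            bump_truth.append(params)

    recording = GyroRecording(
        participant_id="synthetic",
        condition=condition,
        sample_rate=rate,
        samples=signal,
    )

    # --- foot-contact events (all on the sample grid) ---------------------
    stance_samp = np.round(config.stance_fraction * n_samp).astype(int)
    phase_samp = np.round(config.inter_side_phase * n_samp).astype(int)
    nonpro_off_samp = np.round(
        (config.inter_side_phase + config.stance_fraction) * n_samp
    ).astype(int)

    rows = []
    for k in range(n_strides + 1):
        s = starts[k]
        rows.append((s / rate, Side.PRO.value, EventType.FOOT_STRIKE.value))
        rows.append(((s + stance_samp[k]) / rate, Side.PRO.value, EventType.FOOT_OFF.value))
        rows.append(((s + phase_samp[k]) / rate, Side.NONPRO.value, EventType.FOOT_STRIKE.value))
        rows.append(
            ((s + nonpro_off_samp[k]) / rate, Side.NONPRO.value, EventType.FOOT_OFF.value)
        )
    events = GaitEventTable(
        pd.DataFrame(rows, columns=["time_s", "side", "event"]).sort_values(
            "time_s", kind="stable"
        )
    )

    # --- joint angle traces ------------------------------------------------
    angles: dict[Joint, AngleTrace] = {}
    rom_truth: dict[Joint, np.ndarray] = {}
    for joint, (rom_pre, rom_post) in config.rom_means.items():
        rom_mean = rom_pre + blend * (rom_post - rom_pre)
        roms = np.maximum(
            rom_mean + rngs["kinematics"].normal(0.0, config.rom_jitter_sd, n_strides + 1),
            1.0,
        )
        vals = np.empty(total)
        for k in range(n_strides + 1):
            m = n_samp[k] if k < n_strides else tail_extra
            u = np.arange(m) / n_samp[k]
            vals[starts[k] : starts[k] + m] = _ANGLE_OFFSET[joint] - 0.5 * roms[k] * np.cos(
                2 * np.pi * u
            )
        angles[joint] = AngleTrace(joint=joint, sample_rate=rate, values=vals)
        rom_truth[joint] = roms[:n_strides]

    # --- forward foot positions ---------------------------------------------
    step_truth: dict[Side, np.ndarray] = {}
    steps: dict[Side, np.ndarray] = {}
    for side in Side:
        lo, hi = config.step_length_means[side]
        mean = lo + blend * (hi - lo)
        steps[side] = mean + rngs["kinematics"].normal(
            0.0, config.step_jitter_sd, n_strides + 1
        )
        step_truth[side] = steps[side][:n_strides]

    grid = np.arange(total) / rate
    pro_land = np.empty(n_strides + 1)
    non_land = np.empty(n_strides + 1)
    prev_non = 0.0  # nonpro foot starts at the origin
    for k in range(n_strides + 1):
        pro_land[k] = prev_non + steps[Side.PRO][k]
        non_land[k] = pro_land[k] + steps[Side.NONPRO][k]
        prev_non = non_land[k]

    def trace(knot_idx: np.ndarray, knot_pos: np.ndarray, initial: float) -> np.ndarray:
        kt = np.concatenate([[0.0], knot_idx / rate])
        kp = np.concatenate([[initial], knot_pos])
        return np.interp(grid, kt, kp)

    # each foot holds its landing position through stance (strike..off), then
    # moves linearly to the next landing
    pro_idx, pro_pos = [], []
    non_idx, non_pos = [], []
    for k in range(n_strides + 1):
        s = starts[k]
        pro_idx += [s, s + stance_samp[k]]
        pro_pos += [pro_land[k], pro_land[k]]
        non_idx += [s + phase_samp[k], s + nonpro_off_samp[k]]
        non_pos += [non_land[k], non_land[k]]
    positions = {
        Side.PRO: FootPositionTrace(
            side=Side.PRO,
            sample_rate=rate,
            positions=trace(np.array(pro_idx), np.array(pro_pos), pro_land[0]),
        ),
        Side.NONPRO: FootPositionTrace(
            side=Side.NONPRO,
            sample_rate=rate,
            positions=trace(np.array(non_idx), np.array(non_pos), 0.0),
        ),
    }

    truth = {
        "blend": blend,
        "blends": np.full(n_strides, blend),
        "n_strides": n_strides,
        "durations": n_samp[:n_strides] / rate,
        "stance_time_pro": stance_samp[:n_strides] / rate,
        "stance_time_nonpro": (nonpro_off_samp - phase_samp)[:n_strides] / rate,
        "step_length_pro": step_truth[Side.PRO],
        "step_length_nonpro": step_truth[Side.NONPRO],
        "rom": {j.value: r for j, r in rom_truth.items()},
        "bump_params": bump_truth,
        "rom_means": {
            j.value: v[0] + blend * (v[1] - v[0]) for j, v in config.rom_means.items()
        },
        "step_means": {
            s.value: v[0] + blend * (v[1] - v[0])
            for s, v in config.step_length_means.items()
        },
    }
    return recording, events, angles, positions, truth


def generate_session(config: SynthSessionConfig) -> SynthSession:
    """Generate a full four-condition session; deterministic for a fixed seed."""
    root = np.random.SeedSequence(config.seed)
    count_rng = np.random.default_rng(root.spawn(1)[0])
    blends = config.blends()

    recordings, events, angles, positions, truth = {}, {}, {}, {}, {}
    for condition in _BLEND_ORDER:
        n = (
            config.n_strides_per_condition
            if config.n_strides_per_condition is not None
            else int(count_rng.integers(100, 126))
        )
        streams = root.spawn(4)
        rngs = {
            name: np.random.default_rng(ss)
            for name, ss in zip(("durations", "shape", "noise", "kinematics"), streams)
        }
        rec, ev, ang, pos, tr = _generate_condition(
            config, condition, blends[condition], n, rngs
        )
        recordings[condition] = rec
        events[condition] = ev
        angles[condition] = ang
        positions[condition] = pos
        truth[condition] = tr
    return SynthSession(
        config=config,
        recordings=recordings,
        events=events,
        angles=angles,
        positions=positions,
        truth=truth,
    )


def generate_no_change_session(config: SynthSessionConfig) -> SynthSession:
    """Control scenario: no gait change (zero class shift, equal variance).

    Emulates an able-bodied session with no intervention: all four conditions
    are drawn from one distribution, so classification should sit at chance.
    """
    null_config = dataclasses.replace(
        config,
        class_shift=tuple((0.0, 0.0) for _ in config.bumps),
        variance_ratio=1.0,
        mid_blend=0.0,
        postnp_blend=0.0,
        rom_means={j: (v[0], v[0]) for j, v in config.rom_means.items()},
        step_length_means={s: (v[0], v[0]) for s, v in config.step_length_means.items()},
    )
    session = generate_session(null_config)
    # with a zero shift and equalized means the blend has no effect: the
    # effective ground-truth blend of every condition is 0
    for truth in session.truth.values():
        truth["blend"] = 0.0
        truth["blends"] = np.zeros_like(truth["blends"])
    return session
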