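"""Spatiotemporal and kinematic gait parameters plus significance testing.

Ten common parameters are computed per stride from foot-contact events, joint
angle traces, and forward foot-position traces: stance time (each side),
stance-time symmetry ratio (prosthetic / non-prosthetic), double-support
percentage of the gait cycle, step length (each side), and knee/hip
flexion-extension range of motion (each side).

Whether a participant's gait "changed" between the pre- and post-training
trials is decided per parameter by a one-way ANOVA across the four conditions
(strides as observations) followed, when the omnibus test is significant, by
Tukey-HSD pairwise comparisons; the parameter is flagged changed when the
PRE_NP-vs-POST_P adjusted p-value falls below alpha. Overall gait change is
declared when at least 50% of the testable parameters are flagged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .signal_io import (
    AngleTrace,
    Condition,
    EventType,
    FootPositionTrace,
    GaitEventTable,
    Joint,
    Side,
)

__all__ = [
    "Parameter",
    "ParameterTest",
    "SignificanceReport",
    "stance_time",
    "stance_symmetry_ratio",
    "double_support_pct",
    "step_length",
    "range_of_motion",
    "compute_gait_parameters",
    "significance_report",
]

DEFAULT_ALPHA = 0.05


class Parameter(str, Enum):
    STANCE_TIME_PRO = "stance_time_pro"
    STANCE_TIME_NONPRO = "stance_time_nonpro"
    STANCE_SYMMETRY_RATIO = "stance_symmetry_ratio"
    DOUBLE_SUPPORT_PCT = "double_support_pct"
    STEP_LENGTH_PRO = "step_length_pro"
    STEP_LENGTH_NONPRO = "step_length_nonpro"
    KNEE_ROM_PRO = "knee_rom_pro"
    KNEE_ROM_NONPRO = "knee_rom_nonpro"
    HIP_ROM_PRO = "hip_rom_pro"
    HIP_ROM_NONPRO = "hip_rom_nonpro"


_JOINT_PARAM = {
    Joint.KNEE_PRO: Parameter.KNEE_ROM_PRO,
    Joint.KNEE_NONPRO: Parameter.KNEE_ROM_NONPRO,
    Joint.HIP_PRO: Parameter.HIP_ROM_PRO,
    Joint.HIP_NONPRO: Parameter.HIP_ROM_NONPRO,
}


def _stance_intervals(events: GaitEventTable, side: Side) -> list[tuple[float, float]]:
    """(strike, off) stance intervals for one side, in time order.

    An off preceding the first strike is ignored; a trailing strike without a
    matching off is dropped with a warning.
    """
    sub = events.rows[events.rows["side"] == side]
    intervals = []
    pending: float | None = None
    for _, row in sub.iterrows():
        if row["event"] == EventType.FOOT_STRIKE:
            pending = row["time_s"]
        elif pending is not None:
            intervals.append((pending, row["time_s"]))
            pending = None
    if pending is not None:
        warnings.warn(
            f"trailing {side.value} foot strike at {pending} s has no foot off; "
            "cycle skipped",
            stacklevel=3,
        )
    return intervals


def stance_time(events: GaitEventTable, side: Side) -> np.ndarray:
    """Per-cycle stance durations (s): each strike to the next same-side off."""
    return np.array([off - strike for strike, off in _stance_intervals(events, side)])


def stance_symmetry_ratio(stance_pro: float, stance_nonpro: float) -> float:
    """Prosthetic over non-prosthetic stance time; 1.0 means symmetric.

    Values below 1 indicate reduced stance on the prosthetic side, the
    clinically typical deficit.
    """
    if stance_pro <= 0 or stance_nonpro <= 0:
        raise ValueError("stance times must be positive")
    return stance_pro / stance_nonpro


def double_support_pct(
    events: GaitEventTable, cycle: tuple[float, float]
) -> float:
    """Percent of the cycle during which both feet are in stance.

    Computed as the total intersection of the two sides' stance intervals,
    clipped to the half-open cycle window, over the cycle duration. Returns
    NaN (with a warning) when the contralateral side has no events touching
    the cycle.
    """
    start, end = cycle
    if not end > start:
        raise ValueError("cycle end must exceed cycle start")
    per_side = {}
    for side in Side:
        ivs = [
            (max(a, start), min(b, end))
            for a, b in _stance_intervals(events, side)
            if b > start and a < end
        ]
        per_side[side] = ivs
    for side, ivs in per_side.items():
        in_cycle = (events.rows["side"] == side) & (
            events.rows["time_s"].between(start, end)
        )
        if not ivs and not in_cycle.any():
            warnings.warn(
                f"no {side.value} events within cycle [{start}, {end}]: "
                "double support undefined",
                stacklevel=2,
            )
            return float("nan")
    overlap = 0.0
    for a0, a1 in per_side[Side.PRO]:
        for b0, b1 in per_side[Side.NONPRO]:
            overlap += max(0.0, min(a1, b1) - max(a0, b0))
    return 100.0 * overlap / (end - start)


def _nearest_value(trace: FootPositionTrace, t: float) -> float:
    idx = int(round((t - trace.start_time) * trace.sample_rate))
    return float(trace.positions[idx])


def step_length(
    positions: Mapping[Side, FootPositionTrace], events: GaitEventTable
) -> dict[Side, np.ndarray]:
    """Per-step lengths (m) for each side.

    The step length of side s at one of its strikes is the forward position of
    foot s minus that of the contralateral foot, both read at the strike
    instant by nearest-sample lookup. Strikes outside either trace's span are
    skipped with a warning.
    """
    out: dict[Side, np.ndarray] = {}
    other = {Side.PRO: Side.NONPRO, Side.NONPRO: Side.PRO}
    for side in Side:
        own, contra = positions[side], positions[other[side]]
        lengths = []
        for t in events.strikes(side):
            in_own = own.start_time <= t <= own.times()[-1]
            in_contra = contra.start_time <= t <= contra.times()[-1]
            if not (in_own and in_contra):
                warnings.warn(
                    f"{side.value} strike at {t} s outside position trace span; skipped",
                    stacklevel=2,
                )
                continue
            lengths.append(_nearest_value(own, t) - _nearest_value(contra, t))
        out[side] = np.array(lengths)
    return out


def range_of_motion(trace: AngleTrace, interval: tuple[float, float]) -> float:
    """Max minus min of the joint angle within the half-open cycle interval."""
    t0, t1 = interval
    times = trace.times()
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise ValueError(f"angle trace has no samples in [{t0}, {t1})")
    vals = trace.values[mask]
    return float(vals.max() - vals.min())


def compute_gait_parameters(
    events: GaitEventTable,
    angles: Mapping[Joint, AngleTrace],
    positions: Mapping[Side, FootPositionTrace],
    condition: Condition,
) -> pd.DataFrame:
    """Per-stride samples of all ten parameters for one condition.

    Gait cycles are delimited by prosthetic-side foot strikes. Returns a long
    DataFrame with columns parameter, value, stride_index, condition.
    """
    rows: list[tuple[str, float, int, str]] = []

    def add(param: Parameter, value: float, idx: int) -> None:
        if np.isfinite(value):
            rows.append((param.value, float(value), idx, condition.value))

    st_pro = stance_time(events, Side.PRO)
    st_non = stance_time(events, Side.NONPRO)
    for i, v in enumerate(st_pro):
        add(Parameter.STANCE_TIME_PRO, v, i)
    for i, v in enumerate(st_non):
        add(Parameter.STANCE_TIME_NONPRO, v, i)
    for i in range(min(len(st_pro), len(st_non))):
        add(Parameter.STANCE_SYMMETRY_RATIO, stance_symmetry_ratio(st_pro[i], st_non[i]), i)

    strikes = events.strikes(Side.PRO)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (t0, t1) in enumerate(zip(strikes[:-1], strikes[1:])):
            add(Parameter.DOUBLE_SUPPORT_PCT, double_support_pct(events, (t0, t1)), i)
            for joint, param in _JOINT_PARAM.items():
                if joint in angles:
                    add(param, range_of_motion(angles[joint], (t0, t1)), i)
        steps = step_length(positions, events)
    for i, v in enumerate(steps[Side.PRO]):
        add(Parameter.STEP_LENGTH_PRO, v, i)
    for i, v in enumerate(steps[Side.NONPRO]):
        add(Parameter.STEP_LENGTH_NONPRO, v, i)

    return pd.DataFrame(rows, columns=["parameter", "value", "stride_index", "condition"])


@dataclass
class ParameterTest:
    """Omnibus and pairwise significance results for one parameter."""

    omnibus_p: float
    pairwise: dict[str, float]  # "COND_A|COND_B" -> Tukey-adjusted p
    changed: bool
    testable: bool


@dataclass
class SignificanceReport:
    """Per-parameter tests and the >=50%-of-parameters overall verdict."""

    parameters: dict[str, ParameterTest]
    n_changed: int
    n_tested: int
    overall_changed: bool
    alpha: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_changed": self.n_changed,
            "n_tested": self.n_tested,
            "overall_changed": self.overall_changed,
            "parameters": {
                name: {
                    "omnibus_p": pt.omnibus_p,
                    "pairwise": pt.pairwise,
                    "changed": pt.changed,
                    "testable": pt.testable,
                }
                for name, pt in self.parameters.items()
            },
        }


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def significance_report(
    samples: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> SignificanceReport:
    """Test each parameter for condition differences and apply the 50% rule.

    Per parameter: one-way ANOVA across conditions with at least 3 stride
    samples; if the omnibus p < alpha, Tukey-HSD gives adjusted pairwise
    p-values, and the parameter is flagged changed when the PRE_NP-vs-POST_P
    pair is significant. Parameters without enough data are marked untestable
    and excluded from the 50%-rule denominator.
    """
    required = {"parameter", "value", "condition"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples need columns {sorted(required)}")
    results: dict[str, ParameterTest] = {}
    n_changed = n_tested = 0
    for param, sub in samples.groupby("parameter", sort=False):
        groups = {
            cond: g["value"].to_numpy(dtype=float)
            for cond, g in sub.groupby("condition", sort=False)
            if len(g) >= 3
        }
        if len(groups) < 2:
            results[str(param)] = ParameterTest(
                omnibus_p=float("nan"), pairwise={}, changed=False, testable=False
            )
            continue
        omnibus_p = float(stats.f_oneway(*groups.values()).pvalue)
        pairwise: dict[str, float] = {}
        changed = False
        if omnibus_p < alpha:
            values = np.concatenate(list(groups.values()))
            conds = np.concatenate(
                [np.full(len(v), c) for c, v in groups.items()]
            )
            tukey = pairwise_tukeyhsd(values, conds, alpha=alpha)
            unique = list(tukey.groupsunique)
            for (i, j), p in zip(
                itertools.combinations(range(len(unique)), 2), tukey.pvalues
            ):
                pairwise[_pair_key(str(unique[i]), str(unique[j]))] = float(p)
            key = _pair_key(Condition.PRE_NP.value, Condition.POST_P.value)
            changed = pairwise.get(key, 1.0) < alpha
        results[str(param)] = ParameterTest(
            omnibus_p=omnibus_p, pairwise=pairwise, changed=changed, testable=True
        )
        n_tested += 1
        n_changed += int(changed)
    overall = n_tested > 0 and (n_changed / n_tested) >= 0.5
    return SignificanceReport(
        parameters=results,
        n_changed=n_changed,
        n_tested=n_tested,
        overall_changed=overall,
        alpha=alpha,
    )
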