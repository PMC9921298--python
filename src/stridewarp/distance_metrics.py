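"""Stride-to-stride distances: normed Euclidean and windowed DTW.

The normed Euclidean distance is the root-mean-square pointwise difference
between two equal-length signals. DTW accumulates *squared* local errors
under the symmetric step pattern

    Theta(i, j) = D(i, j) + min[Theta(i-1, j-1), Theta(i-1, j), Theta(i, j-1)]

with Theta(1, 1) = D(1, 1), and returns the final element Theta(n, m) — the
minimum global error over all monotone, complete warping paths. A fixed
Sakoe-Chiba window restricts matching to |i - j| <= window; cells outside the
band are treated as +inf. The returned DTW value is the raw accumulated cost
(no path-length normalization): any strictly monotone transform of the
distances leaves nearest-neighbor decisions unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .preprocessing import NormalizedStride, StrideSet
from .signal_io import Condition

__all__ = [
    "Metric",
    "DTWConfig",
    "DistanceMatrix",
    "InfeasibleBandError",
    "default_window",
    "euclidean_normed",
    "dtw_distance",
    "pairwise_distances",
]


class Metric(str, Enum):
    EUCLIDEAN = "euclidean"
    DTW = "dtw"


class InfeasibleBandError(ValueError):
    """The warping band is too narrow to connect sequences of these lengths."""


def default_window(L: int) -> int:
    """Default Sakoe-Chiba half-width: 10% of the normalized length."""
    return math.ceil(0.10 * L)


@dataclass(frozen=True)
class DTWConfig:
    """DTW band configuration. ``window=None`` means unconstrained warping."""

    window: int | None = None
    local_metric: str = "squared"

    def __post_init__(self) -> None:
        if self.window is not None and self.window < 0:
            raise ValueError("window must be non-negative")
        if self.local_metric != "squared":
            raise ValueError("only squared local errors are supported")


def _as_array(x) -> np.ndarray:
    if isinstance(x, NormalizedStride):
        return x.values
    return np.asarray(x, dtype=float)


def euclidean_normed(x, y) -> float:
    """Root-mean-square difference sqrt(sum_i (x_i - y_i)^2 / n)."""
    xv, yv = _as_array(x), _as_array(y)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape} vs {yv.shape}")
    d = xv - yv
    return float(np.sqrt(np.mean(d * d)))


def _dtw_batch(X: np.ndarray, Y: np.ndarray, window: int | None) -> np.ndarray:
    """Accumulated DTW cost for P aligned pairs: X is (P, n), Y is (P, m).

    Two rolling rows; the inner loop runs over the band cells of one row with
    vector operations across the P pairs, so large pairwise matrices stay
    cheap without materializing full cost matrices.
    """
    P, n = X.shape
    m = Y.shape[1]
    if window is not None and abs(n - m) > window:
        raise InfeasibleBandError(
            f"|n - m| = {abs(n - m)} exceeds window {window}: no admissible path"
        )
    w = max(n, m) if window is None else int(window)
    prev = np.full((P, m), np.inf)
    cur = np.full((P, m), np.inf)
    for i in range(n):
        lo = max(0, i - w)
        hi = min(m, i + w + 1)
        cur.fill(np.inf)
        local = Y[:, lo:hi] - X[:, i : i + 1]
        local *= local  # squared local errors
        for j in range(lo, hi):
            if i == 0 and j == 0:
                cur[:, 0] = local[:, 0]
                continue
            if j > 0:
                best = np.minimum(prev[:, j], np.minimum(prev[:, j - 1], cur[:, j - 1]))
            else:
                best = prev[:, 0]
            cur[:, j] = local[:, j - lo] + best
        prev, cur = cur, prev
    return prev[:, m - 1].copy()


def dtw_distance(x, y, config: DTWConfig = DTWConfig()) -> float:
    """Windowed DTW cost between two magnitude signals (squared local errors)."""
    xv, yv = _as_array(x), _as_array(y)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    return float(_dtw_batch(xv[None, :], yv[None, :], config.window)[0])


@dataclass
class DistanceMatrix:
    """Test-by-train pairwise distances under one metric."""

    values: np.ndarray  # (n_test, n_train), finite, >= 0
    metric: Metric
    train_labels: np.ndarray  # (n_train,) of Condition

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.train_labels, dtype=object)
        if values.shape[1] != labels.shape[0]:
            raise ValueError("column count must equal train label count")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("distances must be finite and non-negative")
        self.values = values
        self.train_labels = labels


def _stack(strides) -> np.ndarray:
    if isinstance(strides, StrideSet):
        return strides.to_matrix()
    if isinstance(strides, np.ndarray):
        return np.atleast_2d(strides.astype(float))
    return np.vstack([_as_array(s) for s in strides])


def pairwise_distances(
    test,
    train,
    train_labels: Sequence[Condition],
    metric: Metric | str = Metric.EUCLIDEAN,
    config: DTWConfig = DTWConfig(),
) -> DistanceMatrix:
    """Full test-by-train distance matrix under the chosen metric."""
    metric = Metric(metric)
    A = _stack(test)
    B = _stack(train)
    if B.shape[0] == 0:
        raise ValueError("training set is empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("test and train strides must share the normalized length L")
    labels = np.asarray(list(train_labels), dtype=object)
    if metric is Metric.EUCLIDEAN:
        diff = A[:, None, :] - B[None, :, :]
        values = np.sqrt(np.mean(diff * diff, axis=2))
    else:
        n_test, n_train = A.shape[0], B.shape[0]
        X = np.repeat(A, n_train, axis=0)
        Y = np.tile(B, (n_test, 1))
        values = _dtw_batch(X, Y, config.window).reshape(n_test, n_train)
    return DistanceMatrix(values=values, metric=metric, train_labels=labels)
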