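"""Distance-based kNN gait-change classification with five-fold CV.

The classifier is person-specific and two-class: strides from the pre-training
(PRE_NP) and post-training (POST_P) trials are compared by a stride-to-stride
distance (normed Euclidean or windowed DTW), and each held-out stride takes
the majority label of its k nearest training strides — the pairwise distance
is the lone feature. Class sizes are equalized, 20% of each class is held out
per fold, and five-fold cross-validation yields per-class accuracies. The
intermediate trials (MID_P, POST_NP) are then classified against the full
equalized training sets to give per-condition PRE/POST fractions.

A variance summary (mean per-timepoint stride SD per condition, and their
larger/smaller F-ratio) quantifies how stride-to-stride dispersion differs
between the two trials; unequal variance is a known failure mode for kNN on
overlapping classes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .distance_metrics import DTWConfig, DistanceMatrix, Metric, pairwise_distances
from .preprocessing import StrideSet
from .signal_io import Condition

__all__ = [
    "FoldPlan",
    "ClassificationResult",
    "VarianceSummary",
    "UndefinedRecallError",
    "knn_label",
    "make_folds",
    "cross_validate",
    "classify_condition",
    "f1_score",
    "f_ratio",
    "variance_summary",
]

DEFAULT_SEED = 17
DEFAULT_K = 1
DEFAULT_FOLDS = 5


class UndefinedRecallError(ValueError):
    """No positive-class instances in the truth labels: recall is undefined."""


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment: one fold index in {0..n_folds-1} per stride."""

    pre_folds: np.ndarray
    post_folds: np.ndarray
    n_folds: int
    seed: int


def make_folds(n_per_class: int, seed: int, n_folds: int = DEFAULT_FOLDS) -> FoldPlan:
    """Shuffled stratified folds; per class, fold sizes differ by at most one.

    The two classes share one fold permutation (sizes are equalized upstream),
    which keeps the split exactly symmetric under a class-label swap.
    """
    if n_per_class < n_folds:
        raise ValueError(f"need at least {n_folds} strides per class, got {n_per_class}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_per_class)
    folds = np.empty(n_per_class, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return FoldPlan(pre_folds=folds, post_folds=folds.copy(), n_folds=n_folds, seed=seed)


def knn_label(distances_row, train_labels, k: int = DEFAULT_K) -> Condition:
    """Majority label among the k nearest training strides.

    k must be odd (no vote ties in the two-class setting); exact distance ties
    are broken toward the lower train index, so the rule is deterministic.
    """
    row = np.asarray(distances_row, dtype=float)
    labels = np.asarray(train_labels, dtype=object)
    if row.size == 0:
        raise ValueError("empty distance row")
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be a positive odd integer")
    if k > row.size:
        raise ValueError(f"k={k} exceeds number of training strides {row.size}")
    order = np.argsort(row, kind="stable")
    votes = Counter(labels[order[:k]])
    return votes.most_common(1)[0][0]


@dataclass
class ClassificationResult:
    """Cross-validated accuracies, F1, and intermediate-condition fractions."""

    fold_accuracy_pre: list[float]
    fold_accuracy_post: list[float]
    mean_accuracy_pre: float
    sd_accuracy_pre: float
    mean_accuracy_post: float
    sd_accuracy_post: float
    pooled_accuracy: float
    f1: float
    metric: str
    k: int
    window: int | None
    seed: int
    n_per_class: int
    # per evaluated condition name: {"frac_pre": ..., "frac_post": ...}
    fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, fr in self.fractions.items():
            s = fr["frac_pre"] + fr["frac_post"]
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"fractions for {cond} sum to {s}, expected 1")

    def to_dict(self) -> dict:
        return {
            "fold_accuracy_pre": list(map(float, self.fold_accuracy_pre)),
            "fold_accuracy_post": list(map(float, self.fold_accuracy_post)),
            "mean_accuracy_pre": self.mean_accuracy_pre,
            "sd_accuracy_pre": self.sd_accuracy_pre,
            "mean_accuracy_post": self.mean_accuracy_post,
            "sd_accuracy_post": self.sd_accuracy_post,
            "pooled_accuracy": self.pooled_accuracy,
            "f1": self.f1,
            "metric": self.metric,
            "k": self.k,
            "window": self.window,
            "seed": self.seed,
            "n_per_class": self.n_per_class,
            "fractions": self.fractions,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClassificationResult":
        return cls(**payload)


def _predict_rows(
    dm: DistanceMatrix, k: int, rule: str = "knn"
) -> np.ndarray:
    if rule == "knn":
        return np.array(
            [knn_label(row, dm.train_labels, k) for row in dm.values], dtype=object
        )
    if rule == "mean-distance":
        # nearest-centroid-in-distance reading of the "lone feature":
        # assign to the class with the smaller mean distance.
        preds = []
        classes = [Condition.PRE_NP, Condition.POST_P]
        masks = [dm.train_labels == c for c in classes]
        for row in dm.values:
            means = [row[m].mean() for m in masks]
            preds.append(classes[int(np.argmin(means))])
        return np.array(preds, dtype=object)
    raise ValueError(f"unknown decision rule {rule!r}")


def _equalize(pre_m: np.ndarray, post_m: np.ndarray, how: str, seed: int):
    """Equal class sizes: truncate the larger class (keep earliest strides) or
    subsample it at random."""
    n = min(pre_m.shape[0], post_m.shape[0])
    if how == "truncate":
        return pre_m[:n], post_m[:n]
    if how == "random":
        rng = np.random.default_rng(seed)
        pre_idx = np.sort(rng.choice(pre_m.shape[0], n, replace=False))
        post_idx = np.sort(rng.choice(post_m.shape[0], n, replace=False))
        return pre_m[pre_idx], post_m[post_idx]
    raise ValueError(f"unknown equalization {how!r}")


def _warn_on_duplicates(pre_m: np.ndarray, post_m: np.ndarray) -> None:
    pre_keys = {row.tobytes() for row in pre_m}
    if any(row.tobytes() in pre_keys for row in post_m):
        warnings.warn(
            "identical strides appear in both classes: the classes are "
            "indistinguishable and accuracy will hover near chance",
            stacklevel=3,
        )


def cross_validate(
    pre: StrideSet,
    post: StrideSet,
    metric: Metric | str = Metric.EUCLIDEAN,
    dtw_config: DTWConfig = DTWConfig(),
    k: int = DEFAULT_K,
    seed: int = DEFAULT_SEED,
    n_folds: int = DEFAULT_FOLDS,
    *,
    rule: str = "knn",
    equalize: str = "truncate",
) -> ClassificationResult:
    """Five-fold CV of PRE_NP vs POST_P stride classification.

    Returns per-fold and mean±SD per-class accuracies plus the F1 score over
    the pooled held-out predictions (positive class POST_P).
    """
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("both stride sets must be non-empty")
    if pre.L != post.L:
        raise ValueError("stride sets must share the normalized length L")
    metric = Metric(metric)
    pre_m, post_m = _equalize(pre.to_matrix(), post.to_matrix(), equalize, seed)
    _warn_on_duplicates(pre_m, post_m)
    n = pre_m.shape[0]
    plan = make_folds(n, seed, n_folds)

    fold_acc_pre, fold_acc_post = [], []
    pooled_true, pooled_pred = [], []
    for f in range(n_folds):
        te_pre = plan.pre_folds == f
        te_post = plan.post_folds == f
        train = np.vstack([pre_m[~te_pre], post_m[~te_post]])
        labels = np.array(
            [Condition.PRE_NP] * int((~te_pre).sum())
            + [Condition.POST_P] * int((~te_post).sum()),
            dtype=object,
        )
        test = np.vstack([pre_m[te_pre], post_m[te_post]])
        truth = np.array(
            [Condition.PRE_NP] * int(te_pre.sum())
            + [Condition.POST_P] * int(te_post.sum()),
            dtype=object,
        )
        dm = pairwise_distances(test, train, labels, metric, dtw_config)
        preds = _predict_rows(dm, k, rule)
        is_pre = truth == Condition.PRE_NP
        fold_acc_pre.append(float(np.mean(preds[is_pre] == truth[is_pre])))
        fold_acc_post.append(float(np.mean(preds[~is_pre] == truth[~is_pre])))
        pooled_true.extend(truth)
        pooled_pred.extend(preds)

    pooled_true = np.array(pooled_true, dtype=object)
    pooled_pred = np.array(pooled_pred, dtype=object)
    return ClassificationResult(
        fold_accuracy_pre=fold_acc_pre,
        fold_accuracy_post=fold_acc_post,
        mean_accuracy_pre=float(np.mean(fold_acc_pre)),
        sd_accuracy_pre=float(np.std(fold_acc_pre, ddof=1)),
        mean_accuracy_post=float(np.mean(fold_acc_post)),
        sd_accuracy_post=float(np.std(fold_acc_post, ddof=1)),
        pooled_accuracy=float(np.mean(pooled_pred == pooled_true)),
        f1=f1_score(pooled_true, pooled_pred, positive=Condition.POST_P),
        metric=metric.value,
        k=k,
        window=dtw_config.window if metric is Metric.DTW else None,
        seed=seed,
        n_per_class=n,
    )


def classify_condition(
    target: StrideSet,
    pre_train: StrideSet,
    post_train: StrideSet,
    metric: Metric | str = Metric.EUCLIDEAN,
    dtw_config: DTWConfig = DTWConfig(),
    k: int = DEFAULT_K,
    *,
    rule: str = "knn",
    equalize: str = "truncate",
    seed: int = DEFAULT_SEED,
) -> tuple[float, float]:
    """Classify an intermediate condition's strides against the full
    equalized PRE_NP/POST_P training sets.

    Returns (fraction classified PRE_NP, fraction classified POST_P); the two
    fractions sum to 1 exactly.
    """
    if len(target) == 0:
        raise ValueError("target stride set is empty")
    pre_m, post_m = _equalize(
        pre_train.to_matrix(), post_train.to_matrix(), equalize, seed
    )
    train = np.vstack([pre_m, post_m])
    labels = np.array(
        [Condition.PRE_NP] * pre_m.shape[0] + [Condition.POST_P] * post_m.shape[0],
        dtype=object,
    )
    dm = pairwise_distances(target.to_matrix(), train, labels, metric, dtw_config)
    preds = _predict_rows(dm, k, rule)
    frac_pre = float(np.mean(preds == Condition.PRE_NP))
    return frac_pre, 1.0 - frac_pre


def f1_score(true_labels, predicted_labels, positive: Condition = Condition.POST_P) -> float:
    """F1 = 2 * precision * recall / (precision + recall); 0 when both are 0."""
    truth = np.asarray(list(true_labels), dtype=object)
    pred = np.asarray(list(predicted_labels), dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("label sequences must have equal length")
    if not np.any(truth == positive):
        raise UndefinedRecallError(
            f"no {positive} instances in the truth labels: recall undefined"
        )
    tp = float(np.sum((truth == positive) & (pred == positive)))
    fp = float(np.sum((truth != positive) & (pred == positive)))
    fn = float(np.sum((truth == positive) & (pred != positive)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class VarianceSummary:
    """Mean per-timepoint stride SD per condition and their F-ratio.

    The F-value here is a dispersion-change summary (larger mean SD over the
    smaller), not an ANOVA statistic.
    """

    mean_sd_pre: float
    mean_sd_post: float
    f_value: float


def f_ratio(a: float, b: float) -> float:
    """Larger-over-smaller ratio of two positive dispersion summaries."""
    if a <= 0 or b <= 0:
        raise ValueError("dispersion summaries must be positive")
    return max(a, b) / min(a, b)


def variance_summary(pre: StrideSet, post: StrideSet) -> VarianceSummary:
    """Average the per-timepoint stride SDs for each condition; F = max/min."""
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("need at least 2 strides per condition for an SD")
    if pre.L != post.L:
        raise ValueError("stride sets must share the normalized length L")
    mean_sd_pre = float(np.mean(np.std(pre.to_matrix(), axis=0, ddof=1)))
    mean_sd_post = float(np.mean(np.std(post.to_matrix(), axis=0, ddof=1)))
    return VarianceSummary(
        mean_sd_pre=mean_sd_pre,
        mean_sd_post=mean_sd_post,
        f_value=f_ratio(mean_sd_pre, mean_sd_post),
    )
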