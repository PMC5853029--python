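"""Evaluation protocols for focus-quality methods.

Two protocols are implemented.  The *binary* protocol mirrors the classical
benchmark: every image receives a scalar score, a decision threshold is
picked on a small validation split to maximize the F-score (harmonic mean
of precision and recall), and the F-score is then measured on the held-out
remainder.  The *absolute* protocol skips thresholds entirely: the
classifier's 11-level calls are compared with the true defocus levels in a
confusion matrix, summarized by within-k accuracy, optionally across a grid
of photometric perturbations (gain x offset) to probe robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .certainty import WholeImagePrediction
from .fixtures import LabeledPatchSet
from .optics import UINT16_MAX
from .patches_model import TrainedModel, predict_patches

__all__ = [
    "BinaryEvalResult", "ConfusionMatrix", "select_threshold",
    "binary_evaluate", "model_binary_score", "confusion",
    "within_k_accuracy", "robustness_grid", "predict_levels",
]


@dataclass(frozen=True)
class BinaryEvalResult:
    chosen_threshold: float
    precision: float
    recall: float
    f_score: float
    split_seed: int | None = None
    no_positive_calls: bool = False


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[true_level][predicted_level], non-negative integers."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
            raise ValueError("confusion matrix must be square, non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_levels(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _f_score(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> np.ndarray:
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, 2 * tp / denom, 0.0)
    return f


def select_threshold(scores: np.ndarray, labels: np.ndarray,
                     validation_fraction: float = 0.1,
                     seed: int = 0) -> float:
    """Pick the decision threshold maximizing F-score on a validation split.

    A random ``validation_fraction`` of the data forms the validation
    subset; candidate thresholds are the midpoints of consecutive sorted
    validation scores (plus sentinels below the minimum and above the
    maximum).  Images with score >= threshold are called positive
    (out-of-focus).  Ties are broken toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    rng = np.random.default_rng(seed)
    n = len(scores)
    n_val = max(1, int(round(validation_fraction * n)))
    val_idx = rng.permutation(n)[:n_val]
    s, y = scores[val_idx], labels[val_idx]
    if y.all() or not y.any():
        raise ValueError(
            "validation split contains a single class; re-run with a "
            "different seed or larger validation fraction")
    uniq = np.unique(s)
    mids = 0.5 * (uniq[:-1] + uniq[1:]) if len(uniq) > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pred = s[None, :] >= candidates[:, None]          # (n_cand, n_val)
    tp = (pred & y[None, :]).sum(axis=1).astype(float)
    fp = (pred & ~y[None, :]).sum(axis=1).astype(float)
    fn = (~pred & y[None, :]).sum(axis=1).astype(float)
    f = _f_score(tp, fp, fn)
    best = np.flatnonzero(f == f.max())
    return float(candidates[best].min())


def binary_evaluate(scores: np.ndarray, labels: np.ndarray,
                    threshold: float,
                    split_seed: int | None = None) -> BinaryEvalResult:
    """Precision / recall / F-score at a fixed threshold (score >= threshold
    means out-of-focus)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if len(scores) == 0:
        raise ValueError("empty test split")
    pred = scores >= threshold
    tp = float((pred & labels).sum())
    fp = float((pred & ~labels).sum())
    fn = float((~pred & labels).sum())
    no_pos = not pred.any()
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return BinaryEvalResult(chosen_threshold=float(threshold),
                            precision=precision, recall=recall, f_score=f,
                            split_seed=split_seed, no_positive_calls=no_pos)


def model_binary_score(image_pred: WholeImagePrediction,
                       mode: str = "expected_level") -> float:
    """Reduce an 11-class aggregate prediction to a rankable defocus score.

    ``expected_level`` (default) is sum_i i * p_i under the aggregate
    distribution; ``argmax`` is the predicted level; ``one_minus_p0`` is
    the probability of not being in focus.
    """
    p = np.asarray(image_pred.aggregate_distribution, dtype=np.float64)
    if mode == "expected_level":
        return float(np.sum(np.arange(p.size) * p))
    if mode == "argmax":
        return float(image_pred.predicted_level)
    if mode == "one_minus_p0":
        return float(1.0 - p[0])
    raise ValueError(f"unknown score mode {mode!r}")


def confusion(true_levels: np.ndarray, predicted_levels: np.ndarray,
              n_levels: int = 11) -> ConfusionMatrix:
    """Accumulate raw counts for all (true, predicted) level pairs."""
    t = np.asarray(true_levels, dtype=np.int64)
    p = np.asarray(predicted_levels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("sequences must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= n_levels
                   or p.min() < 0 or p.max() >= n_levels):
        raise ValueError("level outside [0, n_levels)")
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def within_k_accuracy(cm: ConfusionMatrix, k: int = 1) -> float:
    """Fraction of mass within |predicted - true| <= k of the diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.n_levels
    band = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) <= k
    return float(cm.counts[band].sum() / cm.total)


def predict_levels(model: TrainedModel, patches: np.ndarray) -> np.ndarray:
    """Argmax defocus level for each patch."""
    return np.argmax(predict_patches(model, patches), axis=1)


def robustness_grid(model: TrainedModel, test_set: LabeledPatchSet,
                    gains: list[float], offsets: list[float]
                    ) -> dict[tuple[float, float], ConfusionMatrix]:
    """Confusion matrix per (gain, offset) photometric perturbation.

    Each cell transforms the test patches as clip(x * gain + offset,
    0, 65535), predicts, and accumulates a confusion matrix.  Include
    gain 1 / offset 0 to get the unperturbed reference cell.
    """
    grid: dict[tuple[float, float], ConfusionMatrix] = {}
    for g in gains:
        for o in offsets:
            perturbed = np.clip(test_set.patches * g + o, 0.0, UINT16_MAX)
            pred = predict_levels(model, perturbed)
            grid[(g, o)] = confusion(test_set.labels, pred,
                                     n_levels=test_set.n_levels)
    return grid
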