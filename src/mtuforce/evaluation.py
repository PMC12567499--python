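"""Model evaluation: Pearson correlation, relative error, splits, CV.

The headline agreement statistic is the Pearson correlation coefficient

    r = Cov(X, Y) / (sigma_X sigma_Y)

computed with sample (n-1) denominators.  Per-sample relative error
|actual - predicted| / actual is reported as a percentage rounded to one
decimal, matching how force-prediction errors are conventionally quoted
(e.g. actual 123 N vs predicted 116 N -> 5.7%).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class EvalReport:
    pcc: float
    mean_relative_error_pct: float
    max_relative_error_pct: float
    mse: float
    n_samples: int
    recall: Optional[float] = None
    f1: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "pcc": self.pcc,
            "mean_relative_error_pct": self.mean_relative_error_pct,
            "max_relative_error_pct": self.max_relative_error_pct,
            "mse": self.mse,
            "n_samples": self.n_samples,
        }
        if self.recall is not None:
            d["recall"] = self.recall
        if self.f1 is not None:
            d["f1"] = self.f1
        return d


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with sample (n-1) covariance and std denominators."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length series with n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    n = x.size
    cov = float(np.sum(xc * yc)) / (n - 1)
    sx = np.sqrt(float(np.sum(xc**2)) / (n - 1))
    sy = np.sqrt(float(np.sum(yc**2)) / (n - 1))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant series (sigma = 0)")
    r = cov / (sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def relative_error_percent(
    actual: np.ndarray, predicted: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-sample relative error in percent, plus its mean and max.

    e_t = |actual_t - predicted_t| / actual_t * 100, rounded to one decimal.
    Samples with actual == 0 are excluded with a warning reporting the count.
    """
    a = np.asarray(actual, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if a.shape != p.shape:
        raise ValueError("series lengths differ")
    nonzero = a != 0
    n_excluded = int(np.sum(~nonzero))
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} sample(s) with zero actual force from "
            "relative error"
        )
    if not np.any(nonzero):
        raise ValueError("no samples with nonzero actual value")
    e = np.round(np.abs(a[nonzero] - p[nonzero]) / a[nonzero] * 100.0, 1)
    return e, float(np.round(np.mean(e), 1)), float(np.round(np.max(e), 1))


def split_train_test(
    n: int, ratio: tuple[float, float] = (0.8, 0.2), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffled train/test split (default 8:2); disjoint, exhaustive."""
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    train_frac = ratio[0] / (ratio[0] + ratio[1])
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def kfold(
    indices: np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k near-equal (fit, validate) partitions of the given index set."""
    idx = np.asarray(indices)
    n = idx.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = idx[np.sort(folds[i])]
        fit = idx[np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))]
        out.append((fit, val))
    return out


def classification_metrics(
    actual: np.ndarray,
    predicted: np.ndarray,
    threshold: float,
) -> tuple[float, float]:
    """Recall and F1 after binarizing both force series at a threshold.

    ``threshold`` is on the force scale of the inputs (e.g. %MVC); a sample
    is *active* when it exceeds the threshold.  Undefined denominators
    (no actual positives, or no predicted positives) yield 0.
    """
    a = np.asarray(actual, float).ravel() > threshold
    p = np.asarray(predicted, float).ravel() > threshold
    if a.shape != p.shape:
        raise ValueError("series lengths differ")
    tp = int(np.sum(a & p))
    fn = int(np.sum(a & ~p))
    fp = int(np.sum(~a & p))
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return float(recall), float(f1)


def evaluate_predictions(
    actual: np.ndarray,
    predicted: np.ndarray,
    active_threshold: float | None = None,
    classification_threshold: float | None = None,
) -> EvalReport:
    """Bundle PCC, relative errors and MSE into one report.

    Relative error is computed over samples whose actual value exceeds
    ``active_threshold`` (default: all nonzero samples): per-sample relative
    error diverges as the denominator approaches zero, so rest intervals are
    excluded when a threshold is given.
    """
    a = np.asarray(actual, float).ravel()
    p = np.asarray(predicted, float).ravel()
    r = pcc(a, p)
    mask = a > (active_threshold if active_threshold is not None else 0)
    if not np.any(mask):
        raise ValueError("no active samples above threshold")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, mean_e, max_e = relative_error_percent(a[mask], p[mask])
    recall = f1 = None
    if classification_threshold is not None:
        recall, f1 = classification_metrics(a, p, classification_threshold)
    return EvalReport(
        pcc=r,
        mean_relative_error_pct=mean_e,
        max_relative_error_pct=max_e,
        mse=float(np.mean((a - p) ** 2)),
        n_samples=int(a.size),
        recall=recall,
        f1=f1,
    )
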