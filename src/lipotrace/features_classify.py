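"""Fluorescence features, condition assignment and condition prediction.

Cells carrying a fluorescent reporter (e.g. GFP marking the hypoxic
population in a co-plating experiment) are characterized by the log10 of
the background-subtracted maximum channel intensity inside the mask; the
95th percentile of the signal in reporter-negative control wells serves as
the positive/negative threshold. Independently, the growth condition can be
predicted from the isotopologue profiles themselves with a regularized
logistic-regression classifier.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, cross_val_predict

__all__ = [
    "FluorescenceFeature",
    "compute_fluorescence_feature",
    "threshold_condition",
    "classify_from_profiles",
    "ClassificationResult",
    "histogram_modes",
    "uptake_correlation",
]


@dataclasses.dataclass(frozen=True)
class FluorescenceFeature:
    cell_id: int
    channel: str
    log_max_intensity: float
    at_floor: bool  # background subtraction bottomed out


def compute_fluorescence_feature(
    image: np.ndarray,
    labels: np.ndarray,
    channel: str = "GFP",
    floor: float = 1.0,
) -> list[FluorescenceFeature]:
    """Per-cell log10 of background-subtracted maximum channel intensity.

    Background is the median intensity outside all cell masks; the
    subtracted maximum is clipped below at ``floor`` before the log so the
    feature is always defined (cells at the floor are flagged).
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and label mask must be congruent")
    outside = image[labels == 0]
    if outside.size == 0:
        raise ValueError("no background pixels (labels cover the whole image)")
    background = float(np.median(outside))
    feats = []
    for cell_id in np.unique(labels[labels > 0]):
        values = image[labels == cell_id] - background
        peak = float(values.max())
        clipped = max(peak, floor)
        feats.append(FluorescenceFeature(
            cell_id=int(cell_id), channel=channel,
            log_max_intensity=float(np.log10(clipped)),
            at_floor=peak <= floor))
    return feats


def threshold_condition(
    features_negative_wells: Sequence[float],
    features_all: Sequence[float],
    quantile: float = 0.95,
) -> tuple[np.ndarray, float]:
    """Label cells positive when strictly above the negative-well quantile.

    Returns ``(is_positive, threshold)`` where the threshold is the
    empirical ``quantile`` (default 95th percentile) of the negative-control
    features.
    """
    neg = np.asarray(list(features_negative_wells), dtype=float)
    if neg.size == 0:
        raise ValueError("negative-control feature set is empty")
    threshold = float(np.quantile(neg, quantile))
    values = np.asarray(list(features_all), dtype=float)
    return values > threshold, threshold


@dataclasses.dataclass
class ClassificationResult:
    predictions: np.ndarray
    accuracy: float
    confusion: pd.DataFrame  # counts, rows = true class
    confusion_rates: pd.DataFrame  # row-normalized
    classes: list


def classify_from_profiles(
    X: np.ndarray,
    y: Sequence,
    n_splits: int = 5,
    seed: int = 0,
    resubstitution: bool = False,
    C: float = 1.0,
) -> ClassificationResult:
    """Predict the growth condition from concatenated isotopologue profiles.

    L2-regularized logistic regression with stratified k-fold
    cross-validated predictions (default), or resubstitution (train = test)
    for auditing apparent accuracy. Requires ≥ 2 classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("classification needs at least 2 classes")
    clf = LogisticRegression(C=C, max_iter=2000)
    if resubstitution:
        clf.fit(X, y)
        pred = clf.predict(X)
    else:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        pred = cross_val_predict(clf, X, y, cv=cv)
    counts = _sk_confusion(y, pred, labels=classes)
    conf = pd.DataFrame(counts, index=classes, columns=classes)
    rates = conf.div(conf.sum(axis=1).replace(0, np.nan), axis=0)
    accuracy = float(np.trace(counts) / counts.sum())
    return ClassificationResult(
        predictions=pred, accuracy=accuracy, confusion=conf,
        confusion_rates=rates, classes=classes)


def histogram_modes(
    values: Sequence[float],
    bin_width: float = 0.025,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> list[float]:
    """Bin centres of the local modes of a fixed-bin-width histogram.

    A mode is a run of equal non-zero counts strictly greater than the
    counts on both sides; used to detect multimodal parameter populations
    (e.g. mixed knockdown efficiencies).
    """
    edges = np.arange(value_range[0], value_range[1] + bin_width / 2, bin_width)
    counts, edges = np.histogram(np.asarray(list(values), float), bins=edges)
    centres = (edges[:-1] + edges[1:]) / 2
    modes: list[float] = []
    i, n = 0, len(counts)
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left = counts[i - 1] if i > 0 else -1
        right = counts[j + 1] if j + 1 < n else -1
        if counts[i] > 0 and counts[i] > left and counts[i] > right:
            modes.append(float(centres[(i + j) // 2]))
        i = j + 1
    return modes


def uptake_correlation(
    uptake_a: Sequence[float],
    uptake_b: Sequence[float],
    identifiable: Sequence[bool] | None = None,
) -> tuple[float, float, float]:
    """OLS fit of uptake(fa_b) on uptake(fa_a) with Pearson correlation.

    Restricted to cells where both estimates exist (and, when given, where
    both fits are identifiable). Returns ``(slope, intercept, r)``.
    """
    a = np.asarray(list(uptake_a), dtype=float)
    b = np.asarray(list(uptake_b), dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    if identifiable is not None:
        keep &= np.asarray(list(identifiable), dtype=bool)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 complete uptake pairs")
    if np.ptp(a) == 0:  # degenerate x: slope undefined, correlation by convention
        return 0.0, float(b.mean()), 1.0 if np.array_equal(a, b) else float("nan")
    res = scipy.stats.linregress(a, b)
    return float(res.slope), float(res.intercept), float(res.rvalue)
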