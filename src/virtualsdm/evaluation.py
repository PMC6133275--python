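"""Thresholding and binary-map evaluation against a known truth.

Continuous suitability surfaces are binarized either at the *balance*
threshold (the value maximizing sensitivity + specificity against the
reference map, i.e. the max-TSS point of the ROC curve) or at the *least
training presence* threshold (the minimum predicted value over the
training presences, guaranteeing zero training omission).  Binarization is
``prediction >= t`` throughout.  Metrics follow the omission/commission
decomposition: UP = FN/(TP+FN) (underprediction, false-negative rate) and
OP = FP/(TP+FP) (overprediction, fraction of predicted presence that is
false), plus TSS = sensitivity + specificity - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rasters import Layer
from .sampling import BackgroundSample, OccurrenceSample
from .virtual_species import OccupancyMap

__all__ = [
    "ConfusionCounts",
    "BinaryMetrics",
    "balance_threshold",
    "sample_balance_threshold",
    "lpt_threshold",
    "confusion",
    "binary_metrics",
    "evaluate_prediction",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class BinaryMetrics:
    sensitivity: float
    specificity: float
    TSS: float
    OP: float  # FP / (TP+FP); NaN when no presence predicted
    UP: float  # FN / (TP+FN)
    OP_fpr: float  # alternative commission measure FP / (FP+TN)
    prevalence: float
    real_range: int
    predicted_range: int
    threshold_value: float
    threshold_rule: str


def _check_aligned(prediction: Layer, truth: OccupancyMap) -> None:
    if prediction.grid != truth.grid or not np.array_equal(prediction.mask, truth.mask):
        raise ValueError("prediction and truth must share grid and mask")


def balance_threshold(prediction: Layer, reference: OccupancyMap) -> float:
    """Threshold maximizing sensitivity + specificity against the reference.

    Candidates are the unique predicted values over masked cells; ties are
    broken by the smallest maximizing threshold (the more inclusive map).
    """
    _check_aligned(prediction, reference)
    p = prediction.masked_values()
    y = reference.occupied[reference.mask]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("reference must contain both presences and absences")
    cand = np.unique(p)
    if len(cand) == 1:
        warnings.warn("constant prediction surface; threshold is degenerate")
        return float(cand[0])
    pos_sorted = np.sort(p[y])
    neg_sorted = np.sort(p[~y])
    # binary map is (p >= t): sens = share of presences >= t, spec = share of absences < t
    sens = 1.0 - np.searchsorted(pos_sorted, cand, side="left") / n_pos
    spec = np.searchsorted(neg_sorted, cand, side="left") / n_neg
    score = sens + spec
    best = score.max()
    return float(cand[np.nonzero(score >= best - 1e-12)[0][0]])


def sample_balance_threshold(
    train_scores: np.ndarray, background_scores: np.ndarray
) -> float:
    """Balance threshold estimated from training data alone.

    Maximizes sensitivity over the training presences plus specificity
    over the background sample — the ROC available to a practitioner (and
    to SDM software) without knowing the true distribution.  Ties break
    toward the smallest maximizing threshold.
    """
    tr = np.asarray(train_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if tr.size == 0 or bg.size == 0:
        raise ValueError("need both training and background scores")
    cand = np.unique(np.concatenate([tr, bg]))
    pos, neg = np.sort(tr), np.sort(bg)
    sens = 1.0 - np.searchsorted(pos, cand, side="left") / len(pos)
    spec = np.searchsorted(neg, cand, side="left") / len(neg)
    score = sens + spec
    return float(cand[np.nonzero(score >= score.max() - 1e-12)[0][0]])


def lpt_threshold(prediction: Layer, training_presences: OccurrenceSample) -> float:
    """Minimum predicted value over the training presence cells."""
    if training_presences.n == 0:
        raise ValueError("empty training sample")
    vals = prediction.values[training_presences.rows, training_presences.cols]
    if np.any(np.isnan(vals)):
        raise ValueError("training presences fall outside the prediction mask")
    return float(vals.min())


def confusion(prediction: Layer, threshold: float, truth: OccupancyMap) -> ConfusionCounts:
    """Cross-tabulate (prediction >= threshold) against truth over masked cells."""
    _check_aligned(prediction, truth)
    pred = prediction.masked_values() >= threshold
    y = truth.occupied[truth.mask]
    return ConfusionCounts(
        TP=int(np.sum(pred & y)),
        FP=int(np.sum(pred & ~y)),
        FN=int(np.sum(~pred & y)),
        TN=int(np.sum(~pred & ~y)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def binary_metrics(
    counts: ConfusionCounts, rule: str = "balance", threshold: float = float("nan")
) -> BinaryMetrics:
    """Confusion-matrix summary; undefined ratios propagate as NaN."""
    sens = _ratio(counts.TP, counts.TP + counts.FN)
    spec = _ratio(counts.TN, counts.TN + counts.FP)
    return BinaryMetrics(
        sensitivity=sens,
        specificity=spec,
        TSS=sens + spec - 1.0,
        OP=_ratio(counts.FP, counts.TP + counts.FP),
        UP=_ratio(counts.FN, counts.TP + counts.FN),
        OP_fpr=_ratio(counts.FP, counts.FP + counts.TN),
        prevalence=_ratio(counts.TP + counts.FN, counts.total),
        real_range=counts.TP + counts.FN,
        predicted_range=counts.TP + counts.FP,
        threshold_value=threshold,
        threshold_rule=rule,
    )


def evaluate_prediction(
    prediction: Layer,
    truth: OccupancyMap,
    rule: str,
    training_presences: OccurrenceSample | None = None,
    background: "BackgroundSample | None" = None,
    threshold_ref: str = "train",
) -> BinaryMetrics:
    """Threshold by the named rule and score against the truth map.

    ``threshold_ref`` controls where the balance threshold's ROC comes
    from: ``"train"`` (default) uses the model's scores at the training
    presences and background cells, matching practitioner workflow and
    the thresholds SDM software reports; ``"truth"`` uses the true
    occupancy map (an omniscient-evaluator variant).
    """
    if rule == "balance":
        if threshold_ref == "truth":
            t = balance_threshold(prediction, truth)
        elif threshold_ref == "train":
            if training_presences is None or background is None:
                raise ValueError(
                    "train-referenced balance threshold requires the training "
                    "presences and a background sample"
                )
            tr = prediction.values[training_presences.rows, training_presences.cols]
            bg = prediction.values[background.rows, background.cols]
            t = sample_balance_threshold(tr, bg)
        else:
            raise ValueError(f"unknown threshold_ref: {threshold_ref}")
    elif rule == "lpt":
        if training_presences is None:
            raise ValueError("lpt rule requires the training presences")
        t = lpt_threshold(prediction, training_presences)
    else:
        raise ValueError(f"unknown threshold rule: {rule}")
    return binary_metrics(confusion(prediction, t, truth), rule=rule, threshold=t)
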