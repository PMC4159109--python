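"""ROC analysis for rupture prediction from band emission levels.

Per-cycle emission levels (dB band SNR) are the test variable; the
pre-rupture / intact-vessel classification is the state variable.  The
decision rule is ``score >= threshold -> positive`` over every unique score
value.  The area under the curve equals the Mann-Whitney pairwise
probability (ties counted half); its standard error uses the Hanley-McNeil
formula, with significance against AUROC = 0.5 from a normal test.  The
operating threshold is the point closest to the perfect-classifier corner
(FPR, TPR) = (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

from .labeling import PRE_RUPTURE, INTACT_VESSEL, label_emissions

__all__ = [
    "ROCResult",
    "ThresholdReport",
    "roc_curve",
    "corner_threshold",
    "window_sweep",
    "pooled_labeled_scores",
]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray  # ascending unique scores
    sensitivity: np.ndarray  # TPR per threshold (rule: score >= threshold)
    specificity: np.ndarray  # TNR per threshold
    auroc: float
    auroc_se: float
    p_value: float  # vs AUROC = 0.5, two-sided normal
    ci95: tuple[float, float]
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def _as_bool_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    if labels.dtype.kind in "iuf":
        return labels.astype(bool)
    return labels == PRE_RUPTURE


def hanley_mcneil_se(auroc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of AUROC (Hanley & McNeil 1982)."""
    a = auroc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve(scores, labels) -> ROCResult:
    """Full ROC curve with AUROC, SE, p-value and 95% CI.

    ``labels`` may be boolean (positive = pre-rupture) or the string labels
    produced by :func:`cavmon.labeling.label_emissions`.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_bool_labels(labels)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to form an ROC curve")

    thresholds = np.unique(scores)
    # score >= threshold -> positive call; vectorized confusion counts via
    # cumulative class counts on the sorted score axis.
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = y[order]
    # number of positives/negatives with score >= each unique threshold
    idx = np.searchsorted(s_sorted, thresholds, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(~y_sorted)])
    tp = n_pos - cum_pos[idx]
    fp = n_neg - cum_neg[idx]
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg

    # AUROC by the Mann-Whitney rank identity (ties credited 1/2).
    ranks = ss.rankdata(scores)
    auroc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    se = hanley_mcneil_se(auroc, n_pos, n_neg)
    if se > 0:
        z = (auroc - 0.5) / se
        p = 2.0 * ss.norm.sf(abs(z))
    else:
        p = 0.0 if auroc != 0.5 else 1.0
    ci = (auroc - 1.959963984540054 * se, auroc + 1.959963984540054 * se)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auroc=float(auroc),
        auroc_se=se,
        p_value=float(p),
        ci95=ci,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def corner_threshold(roc: ROCResult, scores, labels) -> ThresholdReport:
    """Operating point closest to (FPR, TPR) = (0, 1), ties to lower threshold.

    PPV and NPV come from the confusion matrix of the selected threshold on
    the provided sample.
    """
    fpr = 1.0 - roc.specificity
    dist = np.hypot(fpr, 1.0 - roc.sensitivity)
    best = int(np.argmin(dist))  # first minimum = lowest threshold (ascending)
    theta = float(roc.thresholds[best])

    scores = np.asarray(scores, dtype=np.float64)
    y = _as_bool_labels(labels)
    call = scores >= theta
    tp = int(np.sum(call & y))
    fp = int(np.sum(call & ~y))
    fn = int(np.sum(~call & y))
    tn = int(np.sum(~call & ~y))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return ThresholdReport(theta, sens, spec, ppv, npv)


def pooled_labeled_scores(levels_list, annotations, band: str, window: float = 10.0):
    """Pool per-cycle scores and labels across trials for one band.

    Excluded (post-rupture) cycles are dropped.  Returns (scores, labels)
    with boolean labels (positive = pre-rupture).
    """
    scores, labels = [], []
    for levels, ann in zip(levels_list, annotations, strict=True):
        frame = label_emissions(levels, ann, window=window)
        keep = frame["label"] != "excluded"
        scores.append(frame.loc[keep, band].to_numpy())
        labels.append((frame.loc[keep, "label"] == PRE_RUPTURE).to_numpy())
    return np.concatenate(scores), np.concatenate(labels)


def window_sweep(
    levels_list,
    annotations,
    band: str = "subharmonic",
    windows=range(1, 21),
) -> dict[int, float]:
    """AUROC of one band as a function of the pre-rupture window length."""
    if not any(a.ruptured for a in annotations):
        raise ValueError("window sweep needs at least one rupture trial")
    out = {}
    for w in windows:
        scores, labels = pooled_labeled_scores(levels_list, annotations, band, window=float(w))
        out[int(w)] = roc_curve(scores, labels).auroc
    return out
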