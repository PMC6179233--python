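"""ROC analysis and probability-threshold optimization on test sites.

Converting a continuous probability-of-occurrence surface into a
presence/absence map requires a threshold, and the choice matters most
for rare species.  Four optimization rules are implemented, each scanning
the ROC candidate thresholds of an independent test set:

* SES  — sensitivity equals specificity: argmin |sens - spec|;
* MSS  — maximum sensitivity plus specificity (Youden);
* PPOP — predicted prevalence equals observed prevalence;
* max-Kappa — highest chance-corrected classification agreement.

Classification uses the ``pred >= t`` rule, so a site exactly at the
threshold counts as predicted-present; ties between candidate thresholds
break to the lowest threshold (the over-prediction, precautionary side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import GridSurface

__all__ = [
    "RocCurve",
    "ThresholdMetrics",
    "ThresholdSet",
    "roc_curve",
    "auc",
    "auc_trapezoid",
    "confusion_metrics",
    "metrics_from_rates",
    "optimize_thresholds",
    "classify_surface",
]


def _check_binary(obs: np.ndarray) -> None:
    classes = np.unique(obs)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError("observations must be 0/1")
    if len(classes) < 2:
        raise ValueError("both classes must be present")


@dataclass
class RocCurve:
    """Sensitivity/specificity over the candidate thresholds of a test set."""

    thresholds: np.ndarray  # ascending; includes sentinels below min and above max
    sens: np.ndarray
    spec: np.ndarray
    obs_prevalence: float
    n_test: int


@dataclass
class ThresholdMetrics:
    """Confusion-matrix summary of one threshold."""

    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    predicted_prevalence: float


@dataclass
class ThresholdSet:
    """The four optimized thresholds with their metrics."""

    ses: ThresholdMetrics
    mss: ThresholdMetrics
    ppop: ThresholdMetrics
    max_kappa: ThresholdMetrics

    def as_dict(self) -> dict[str, ThresholdMetrics]:
        return {"ses": self.ses, "mss": self.mss, "ppop": self.ppop, "max_kappa": self.max_kappa}


def roc_curve(obs, pred) -> RocCurve:
    """Sens/spec at every candidate threshold (unique predictions + sentinels)."""
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=float)
    _check_binary(obs)
    uniq = np.unique(pred)
    # sentinel below the minimum (everything predicted present -> sens 1)
    # and above the maximum (nothing predicted present -> spec 1)
    lo = min(0.0, uniq[0] - 1.0)
    hi = uniq[-1] + 1.0
    thresholds = np.concatenate([[lo], uniq, [hi]])
    pos = obs == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    # pred >= t rule
    tp = np.array([(pred[pos] >= t).sum() for t in thresholds])
    fp = np.array([(pred[~pos] >= t).sum() for t in thresholds])
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    return RocCurve(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        obs_prevalence=n_pos / len(obs),
        n_test=len(obs),
    )


def auc(obs, pred) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals P(pred at a presence > pred at an absence) + 0.5 P(tie); agrees
    with the trapezoid integral of the ROC curve.
    """
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=float)
    _check_binary(obs)
    pos = obs == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(pred)  # average ranks for ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_trapezoid(obs, pred) -> float:
    """AUC as the trapezoid integral of the empirical ROC curve."""
    roc = roc_curve(obs, pred)
    fpr = 1.0 - roc.spec
    order = np.argsort(roc.thresholds)[::-1]  # fpr ascending
    return float(np.trapezoid(roc.sens[order], fpr[order]))


def _kappa_from_counts(tp: float, fp: float, fn: float, tn: float) -> float:
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pyes = ((tp + fp) / n) * ((tp + fn) / n)
    pno = ((fn + tn) / n) * ((fp + tn) / n)
    pe = pyes + pno
    if pe >= 1.0:
        raise ValueError("kappa undefined: degenerate marginals (Pe = 1)")
    return (po - pe) / (1.0 - pe)


def _metrics_from_counts(threshold: float, tp, fp, fn, tn) -> ThresholdMetrics:
    n = tp + fp + fn + tn
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("kappa undefined: degenerate marginals (single observed class)")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ThresholdMetrics(
        threshold=float(threshold),
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        kappa=_kappa_from_counts(tp, fp, fn, tn),
        predicted_prevalence=(tp + fp) / n,
    )


def confusion_metrics(obs, pred, threshold: float) -> ThresholdMetrics:
    """Accuracy, sensitivity, specificity, Cohen's kappa and predicted
    prevalence for the ``pred >= threshold`` classification."""
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=float)
    _check_binary(obs)
    hat = pred >= threshold
    pos = obs == 1
    tp = float(np.sum(hat & pos))
    fp = float(np.sum(hat & ~pos))
    fn = float(np.sum(~hat & pos))
    tn = float(np.sum(~hat & ~pos))
    return _metrics_from_counts(threshold, tp, fp, fn, tn)


def metrics_from_rates(
    sensitivity: float, specificity: float, prevalence: float, n: int,
    threshold: float = np.nan,
) -> ThresholdMetrics:
    """Metrics from expected (possibly non-integer) confusion counts.

    Reconstructs TP/FP/FN/TN from printed sensitivity/specificity at a
    given prevalence and sample size — the consistency check used against
    published performance tables when raw site data are unavailable.
    """
    n_pos = prevalence * n
    n_neg = (1.0 - prevalence) * n
    tp = sensitivity * n_pos
    fn = n_pos - tp
    tn = specificity * n_neg
    fp = n_neg - tn
    return _metrics_from_counts(threshold, tp, fp, fn, tn)


def optimize_thresholds(obs, pred) -> ThresholdSet:
    """Apply the four ROC threshold-optimization rules.

    Candidates are restricted to the open unit interval; ties break to the
    lowest threshold.
    """
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=float)
    roc = roc_curve(obs, pred)
    in_unit = (roc.thresholds > 0.0) & (roc.thresholds < 1.0)
    cand = roc.thresholds[in_unit]
    if cand.size == 0:
        raise ValueError("no candidate thresholds inside (0, 1)")
    metrics = [confusion_metrics(obs, pred, t) for t in cand]
    sens = np.array([m.sensitivity for m in metrics])
    spec = np.array([m.specificity for m in metrics])
    kappa = np.array([m.kappa for m in metrics])
    pprev = np.array([m.predicted_prevalence for m in metrics])

    def pick(score: np.ndarray, maximize: bool) -> ThresholdMetrics:
        # first occurrence of the optimum = lowest threshold on exact ties
        idx = int(np.argmax(score) if maximize else np.argmin(score))
        return metrics[idx]

    return ThresholdSet(
        ses=pick(np.abs(sens - spec), maximize=False),
        mss=pick(sens + spec, maximize=True),
        ppop=pick(np.abs(pprev - roc.obs_prevalence), maximize=False),
        max_kappa=pick(kappa, maximize=True),
    )


def classify_surface(prob: GridSurface, threshold: float) -> GridSurface:
    """Binary presence map: 1 where prob >= threshold, nodata preserved."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    vals = np.where(prob.values >= threshold, 1.0, 0.0)
    vals[~prob.mask] = np.nan
    return prob.like(vals)
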