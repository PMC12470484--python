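"""Screening-metric evaluation: confusion arithmetic, AUROC, PR-AUC,
calibration, percentile-bootstrap confidence intervals, subgroup rates.

Conventions fixed for reproducibility: AUROC is the Mann-Whitney
concordance probability with ties counted one half; PR-AUC is step-wise
average precision; calibration intercept/slope come from a logistic
recalibration of the outcome on logit(score); bootstrap CIs are percentile
2.5/97.5 with the patient as resampling unit; metrics are reported to
three decimals, rounded half-up.  A metric whose denominator is zero is
returned as NaN (an explicit undefined marker), never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class ConfusionMatrix:
    """2x2 classification counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def round_half_up(x: float, digits: int = 3) -> float:
    """Decimal rounding half-up (the convention of reported tables)."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion(predictions, labels) -> ConfusionMatrix:
    """Count tp/fp/fn/tn from binary prediction and label vectors."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Screening metrics derived from a confusion matrix.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), accuracy = (tp+tn)/total,
    f1 = 2*ppv*sens/(ppv+sens).  Zero denominators give NaN for that
    metric only.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    acc = (cm.tp + cm.tn) / cm.total
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        f1 = 0.0 if sens == 0 or ppv == 0 else np.nan
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "accuracy": acc,
        "f1": f1,
    }


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney, ties count 1/2).

    NaN when only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        return np.nan
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        return np.nan
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def calibration(scores, labels, eps: float = 1e-6) -> tuple[float, float]:
    """Calibration intercept and slope.

    Fits ``label ~ intercept + slope * logit(score)`` by logistic
    regression; perfectly calibrated scores give (0, 1).  Scores at exactly
    0 or 1 are clipped to [eps, 1 - eps] before the logit.  Degenerate
    designs (constant scores, single-class labels) return (NaN, NaN).
    """
    scores = np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)
    labels = np.asarray(labels).astype(int)
    logit = np.log(scores / (1.0 - scores))
    if len(np.unique(labels)) < 2 or np.ptp(logit) < 1e-12:
        return np.nan, np.nan
    X = sm.add_constant(logit)
    try:
        res = sm.GLM(labels, X, family=sm.families.Binomial()).fit()
    except Exception:  # noqa: BLE001 - non-convergence is an undefined marker
        return np.nan, np.nan
    return float(res.params[0]), float(res.params[1])


def bootstrap_ci(
    statistic,
    data: tuple,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI with the patient as the resampling unit.

    ``data`` is a tuple of equal-length arrays resampled jointly (rows =
    patients); ``statistic(*resampled)`` must return a scalar.  Resamples
    on which the statistic is undefined (NaN) are redrawn, up to
    ``max_redraws`` extra draws; deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must share length")
    rng = np.random.default_rng(seed)
    stats = []
    redraws = 0
    while len(stats) < n_boot:
        idx = rng.integers(0, n, size=n)
        val = statistic(*(a[idx] for a in arrays))
        if np.isnan(val):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    "statistic undefined on too many bootstrap resamples"
                )
            continue
        stats.append(float(val))
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def subgroup_metrics(predictions, labels, mask) -> dict:
    """Detection rate (and metrics where defined) within a subgroup.

    The detection rate is the predicted-positive fraction among the masked
    patients with true AF — e.g. the share of prior-stroke AF patients the
    protocol flags.  Empty subgroups give NaN.
    """
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    mask = np.asarray(mask).astype(bool)
    if predictions.shape != labels.shape or labels.shape != mask.shape:
        raise ValueError("predictions, labels and mask must align")
    out: dict = {"n": int(mask.sum())}
    pos = mask & (labels == 1)
    out["n_true_af"] = int(pos.sum())
    out["detection_rate"] = (
        float(np.mean(predictions[pos])) if pos.any() else np.nan
    )
    if mask.any():
        cm = confusion(predictions[mask], labels[mask])
        out["confusion"] = cm
        if cm.total > 0:
            out.update(metrics_from_confusion(cm))
    return out
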