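"""Operating-point selection on validation scores.

Two prespecified rules are used by the staged screening protocol:

* the *serial* stage uses Youden's J (sensitivity + specificity - 1),
  a balanced point that recovers precision at confirmation;
* the *baseline* stage uses a sensitivity-band rule targeting sensitivity
  in [0.85, 0.90] (inclusive), which preserves NPV at entry; among
  candidate thresholds inside the band the most specific one is taken, and
  if the band is unattainable the threshold with sensitivity closest to
  the lower band edge from above is used.

Conventions fixed here: a subject is called positive iff score >=
threshold; candidate thresholds are the unique observed scores plus a +inf
sentinel (the all-negative rule); ties in the selection objective break
toward the larger threshold (higher specificity).  Both selectors must be
given validation data only — passing test scores at selection time is a
protocol violation by construction, not something the code can see, so the
pipeline routes only validation scores here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np


@dataclass
class OperatingPoint:
    """A decision threshold with its validation characteristics."""

    threshold: float
    rule: str  # {"youden", "sensitivity_band"}
    sensitivity: float
    specificity: float
    J: float
    band: tuple | None = None

    def decide(self, scores) -> np.ndarray:
        """Apply the score >= threshold convention."""
        return (np.asarray(scores, dtype=float) >= self.threshold).astype(int)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["band"] = list(self.band) if self.band is not None else None
        Path(path).write_text(json.dumps(d, indent=2))


def _candidate_sweep(scores, labels):
    """Sensitivity/specificity at every candidate threshold.

    Candidates are the unique scores plus +inf, in increasing order.
    Vectorized: with scores sorted, the number of positives/negatives at or
    above each candidate follows from cumulative counts.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to select a threshold")

    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    uniq, first_idx = np.unique(s_sorted, return_index=True)
    # positives with score >= threshold t: total positives minus positives
    # strictly below t
    cum_pos = np.concatenate([[0], np.cumsum(l_sorted)])
    pos_below = cum_pos[first_idx]
    neg_below = first_idx - pos_below
    thresholds = np.concatenate([uniq, [np.inf]])
    tp = np.concatenate([n_pos - pos_below, [0]])
    fp = np.concatenate([n_neg - neg_below, [0]])
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    return thresholds, sens, spec


def youden_threshold(scores, labels) -> OperatingPoint:
    """Threshold maximizing Youden's J over all candidate thresholds.

    Ties break toward the larger threshold (higher specificity).
    """
    thresholds, sens, spec = _candidate_sweep(scores, labels)
    J = sens + spec - 1.0
    best = np.flatnonzero(J >= J.max() - 1e-12)[-1]
    return OperatingPoint(
        threshold=float(thresholds[best]),
        rule="youden",
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        J=float(J[best]),
    )


def sensitivity_band_threshold(
    scores, labels, band: tuple = (0.85, 0.90)
) -> OperatingPoint:
    """Screening threshold with validation sensitivity in ``band``.

    Among candidates whose sensitivity falls inside the (inclusive) band,
    the one maximizing specificity is chosen (ties toward the larger
    threshold).  If no candidate lands in the band, the fallback is the
    candidate with sensitivity closest to the lower edge from above —
    i.e. the highest threshold with sensitivity >= band[0].
    """
    lo, hi = band
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"invalid sensitivity band {band}")
    thresholds, sens, spec = _candidate_sweep(scores, labels)
    in_band = (sens >= lo - 1e-12) & (sens <= hi + 1e-12)
    if in_band.any():
        idx = np.flatnonzero(in_band)
        best_spec = spec[idx].max()
        best = idx[np.flatnonzero(spec[idx] >= best_spec - 1e-12)[-1]]
    else:
        above = np.flatnonzero(sens >= lo - 1e-12)
        # sensitivity is non-increasing in the threshold, so the candidate
        # with sensitivity closest to the band floor from above is the one
        # with the largest threshold among those still above the floor
        best = above[-1]
    return OperatingPoint(
        threshold=float(thresholds[best]),
        rule="sensitivity_band",
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        J=float(sens[best] + spec[best] - 1.0),
        band=(float(lo), float(hi)),
    )
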