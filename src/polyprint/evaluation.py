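"""Verification metrics and the FMR/FNMR-versus-threshold sweep.

Decisions are compared against genuine/impostor labels to produce
confusion counts, precision/recall/F1 and the two biometric error rates
(false match rate, false non-match rate). ``sweep_tmc`` scans the
match-count threshold over a half-integer grid and locates the equal
error rate by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GENUINE = "genuine"
IMPOSTOR = "impostor"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Rates as fractions in [0, 1]; None marks a zero-denominator metric."""

    precision: float | None
    recall: float | None
    f1: float | None
    fmr: float | None
    fnmr: float | None


@dataclass
class SweepCurve:
    thresholds: np.ndarray
    fmr: np.ndarray
    fnmr: np.ndarray
    eer: float
    eer_threshold: float


def confusion(decisions, labels) -> ConfusionCounts:
    """Count tp/fp/tn/fn from match decisions and genuine/impostor labels."""
    decisions = list(decisions)
    labels = list(labels)
    if len(decisions) != len(labels):
        raise ValueError("decisions and labels differ in length")
    tp = fp = tn = fn = 0
    for d, lab in zip(decisions, labels):
        if lab not in (GENUINE, IMPOSTOR):
            raise ValueError(f"label must be genuine/impostor, got {lab!r}")
        genuine = lab == GENUINE
        if genuine and d:
            tp += 1
        elif genuine:
            fn += 1
        elif d:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts, *, literal_recall: bool = False) -> MetricReport:
    """Precision, recall, F1, FMR, FNMR from confusion counts.

    ``literal_recall=True`` reproduces the tp/(tp+tn) variant some
    write-ups print; the default tp/(tp+fn) is the standard definition.
    """
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.tn) if literal_recall else _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    fmr = _ratio(c.fp, c.fp + c.tn)
    fnmr = _ratio(c.fn, c.fn + c.tp)
    return MetricReport(precision=precision, recall=recall, f1=f1, fmr=fmr, fnmr=fnmr)


def sweep_tmc(genuine_counts, impostor_counts) -> SweepCurve:
    """FMR/FNMR step curves over a half-integer threshold grid, plus EER.

    At threshold t the decision is match iff count >= t, so
    fnmr(t) = fraction of genuine counts below t and fmr(t) = fraction
    of impostor counts at or above t. The EER sits where the curves
    cross, linearly interpolated between adjacent grid points.
    """
    g = np.asarray(list(genuine_counts), dtype=float)
    i = np.asarray(list(impostor_counts), dtype=float)
    if g.size == 0 or i.size == 0:
        raise ValueError("both count lists must be non-empty")
    lo = min(g.min(), i.min()) - 1.0
    hi = max(g.max(), i.max()) + 1.0
    thresholds = np.arange(np.floor(2 * lo), np.ceil(2 * hi) + 1) / 2.0
    fnmr = np.array([(g < t).mean() for t in thresholds])
    fmr = np.array([(i >= t).mean() for t in thresholds])

    diff = fmr - fnmr
    eer = eer_t = None
    for k in range(len(thresholds) - 1):
        if diff[k] == 0.0:
            eer, eer_t = float(fmr[k]), float(thresholds[k])
            break
        if diff[k] > 0.0 >= diff[k + 1]:
            alpha = diff[k] / (diff[k] - diff[k + 1])
            eer_t = float(thresholds[k] + alpha * (thresholds[k + 1] - thresholds[k]))
            fmr_x = fmr[k] + alpha * (fmr[k + 1] - fmr[k])
            fnmr_x = fnmr[k] + alpha * (fnmr[k + 1] - fnmr[k])
            eer = float((fmr_x + fnmr_x) / 2.0)
            break
    if eer is None:  # no crossing inside the grid
        k = int(np.argmin(np.abs(diff)))
        eer, eer_t = float((fmr[k] + fnmr[k]) / 2.0), float(thresholds[k])
    return SweepCurve(thresholds=thresholds, fmr=fmr, fnmr=fnmr, eer=eer, eer_threshold=eer_t)
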