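"""Lesion-wise detection scoring and patient-level agreement statistics.

Detection follows an overlap rule: a reference node counts as detected as
soon as any predicted voxel overlaps it.  One predicted component spanning
k reference nodes detects all k (and is not a false positive); one
reference node hit by several predicted components is a single true
positive.  Patient-level N-staging performance is summarized by
sensitivity, specificity and the single-operating-point AUC of a hard
binary classifier (the balanced accuracy).  Cohen's kappa, Pearson
correlation and Bland-Altman limits of agreement quantify consistency
between automated and manual readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .lesions import LesionSet

__all__ = [
    "DetectionResult",
    "PatientOutcome",
    "AgreementResult",
    "BlandAltmanResult",
    "match_lesions",
    "detection_scores",
    "patient_level_scores",
    "cohens_kappa",
    "pearson_r",
    "bland_altman",
]


@dataclass
class DetectionResult:
    """Lesion-level confusion between predicted and reference lesion sets."""

    matches: List[Tuple[int, int, int]]  # (pred id, ref id, overlap voxels)
    tp: int
    fp: int
    fn: int
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    degenerate: bool = False  # True when F1 was forced to 0 by an
    # undefined precision or recall


@dataclass(frozen=True)
class PatientOutcome:
    """One patient's true status and predicted N-stage."""

    truth_positive: bool   # has at least one suspicious node
    predicted_n1: bool     # model staged the patient N1


@dataclass(frozen=True)
class AgreementResult:
    kappa: Optional[float]
    observed_agreement: float
    expected_agreement: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    lower_limit: float
    upper_limit: float
    means: np.ndarray
    differences: np.ndarray


def match_lesions(pred: LesionSet, ref: LesionSet) -> DetectionResult:
    """Overlap-match two lesion sets on the same grid.

    Any shared voxel counts as a match; no minimum-IoU threshold is
    applied.
    """
    if pred.labels.shape != ref.labels.shape:
        raise ValueError(
            f"grid mismatch: {pred.labels.shape} vs {ref.labels.shape}"
        )
    both = (pred.labels > 0) & (ref.labels > 0)
    pairs = np.stack([pred.labels[both], ref.labels[both]], axis=1)
    if len(pairs):
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        matches = [(int(p), int(r), int(c)) for (p, r), c in zip(uniq, counts)]
    else:
        matches = []
    matched_pred = {m[0] for m in matches}
    matched_ref = {m[1] for m in matches}
    tp = len(matched_ref)
    fp = sum(1 for l in pred.lesions if l.label_id not in matched_pred)
    fn = sum(1 for l in ref.lesions if l.label_id not in matched_ref)
    result = DetectionResult(matches=matches, tp=tp, fp=fp, fn=fn)
    return detection_scores(result)


def detection_scores(r: DetectionResult) -> DetectionResult:
    """Fill precision = TP/(TP+FP), recall = TP/(TP+FN) and their harmonic
    mean F1 on a detection result; undefined ratios stay None and force
    F1 to 0 with ``degenerate=True``."""
    r.precision = r.tp / (r.tp + r.fp) if (r.tp + r.fp) > 0 else None
    r.recall = r.tp / (r.tp + r.fn) if (r.tp + r.fn) > 0 else None
    if r.precision is None or r.recall is None or (r.precision + r.recall) == 0:
        r.f1 = 0.0
        r.degenerate = True
    else:
        r.f1 = 2 * r.precision * r.recall / (r.precision + r.recall)
        r.degenerate = False
    return r


def patient_level_scores(
    outcomes: Sequence[PatientOutcome],
) -> Tuple[float, float, float]:
    """(sensitivity, specificity, AUC) of the N0/N1 call over patients.

    For a hard binary classifier the ROC has a single operating point, so
    its trapezoidal AUC equals (sensitivity + specificity) / 2.
    """
    truths = np.array([o.truth_positive for o in outcomes], dtype=bool)
    preds = np.array([o.predicted_n1 for o in outcomes], dtype=bool)
    n_pos = int(truths.sum())
    n_neg = len(truths) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative patient")
    sens = float((preds & truths).sum() / n_pos)
    spec = float((~preds & ~truths).sum() / n_neg)
    return sens, spec, (sens + spec) / 2.0


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Cohen's kappa (po - pe) / (1 - pe) for two raters' category lists."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists must have equal length")
    if len(labels_a) == 0:
        raise ValueError("label lists must be non-empty")
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    po = float(np.mean(a == b))
    cats = np.unique(np.concatenate([a, b]))
    pe = float(
        sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats)
    )
    kappa = None if pe >= 1.0 - 1e-12 else (po - pe) / (1.0 - pe)
    return AgreementResult(kappa=kappa, observed_agreement=po,
                           expected_agreement=pe)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Pearson product-moment correlation; None for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    bias = mean(x - y); limits of agreement = bias +/- 1.96 * sd(x - y)
    (sample sd, n-1); per-pair means and differences are returned for
    plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
        means=(x + y) / 2.0,
        differences=diff,
    )
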