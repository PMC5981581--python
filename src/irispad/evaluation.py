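"""Presentation-attack detection error rates and DET curves.

Follows the ISO/IEC 30107-3 definitions: APCER is the percentage of
attack presentations accepted as bona fide (score below threshold) and
BPCER the percentage of bona-fide presentations rejected as attacks
(score at or above threshold; samples exactly at the threshold classify
as attack).  ACER is their arithmetic mean.  DET curves trace APCER
against BPAR = 100 - BPCER as the threshold sweeps the observed scores.
When a protocol has several test conditions (same-sensor "known" and
cross-sensor "unknown" splits), the summary is the sample-size-weighted
average of the per-split ACERs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from irispad.errors import ValidationError


@dataclass
class ScoredSet:
    """Scores in [0, 1] (higher = attack) with their true labels."""

    scores: np.ndarray
    labels: np.ndarray  # strings "bona_fide"/"attack" or ints 0/1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        labels = np.asarray(self.labels)
        if labels.dtype.kind in "UO":
            labels = (labels == "attack").astype(int)
        self.labels = labels.astype(int)
        if self.scores.shape != self.labels.shape:
            raise ValidationError("scores and labels must have equal length")

    @property
    def has_both_classes(self) -> bool:
        return bool(self.labels.any()) and bool((1 - self.labels).any())


@dataclass
class EvalResult:
    apcer: float
    bpcer: float
    acer: float
    threshold: float
    det: list[tuple[float, float]]  # (APCER, BPAR) points


def rates(scored: ScoredSet, threshold: float) -> tuple[float, float]:
    """(APCER, BPCER) in percent at the given score threshold."""
    if not scored.has_both_classes:
        raise ValidationError("rate computation needs both classes present")
    attack = scored.labels == 1
    apcer = 100.0 * float(np.mean(scored.scores[attack] < threshold))
    bpcer = 100.0 * float(np.mean(scored.scores[~attack] >= threshold))
    return apcer, bpcer


def acer(apcer: float, bpcer: float) -> float:
    """Average classification error rate: (APCER + BPCER) / 2."""
    for v in (apcer, bpcer):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"rate {v} outside [0, 100]")
    return (apcer + bpcer) / 2.0


def det_curve(scored: ScoredSet) -> list[tuple[float, float]]:
    """(APCER, BPAR) points over all distinct-score thresholds.

    BPAR = 100 - BPCER; points are sorted by BPAR ascending, and APCER
    is non-decreasing along the curve.
    """
    if not scored.has_both_classes:
        raise ValidationError("DET computation needs both classes present")
    thresholds = np.concatenate(
        [np.unique(scored.scores), [np.max(scored.scores) + 1.0]]
    )
    points = []
    for t in thresholds:
        ap, bp = rates(scored, float(t))
        points.append((ap, 100.0 - bp))
    points.sort(key=lambda p: (p[1], p[0]))
    return points


def evaluate(scored: ScoredSet, threshold: float = 0.5) -> EvalResult:
    """Operating-point rates plus the full DET curve."""
    ap, bp = rates(scored, threshold)
    return EvalResult(
        apcer=ap, bpcer=bp, acer=acer(ap, bp), threshold=threshold,
        det=det_curve(scored),
    )


def weighted_acer(results: list[tuple[EvalResult, int]]) -> float:
    """Sample-size-weighted average ACER over several test splits."""
    if not results:
        raise ValidationError("no results to average")
    total = sum(n for _, n in results)
    if total <= 0:
        raise ValidationError("zero total samples")
    return sum(r.acer * n for r, n in results) / total
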