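"""ROC / PR machinery for the two benchmark tasks.

Task one scores per-case misclassification probabilities against the ground
truth set of flipped controls; task two scores per-SNP association p-values
against the causal set.  Curves are computed by threshold sweeps (equal
scores collapse to a single operating point), per-replicate areas by the
trapezoid rule, and mean curves by interpolation onto a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "CurvePoints",
    "MetricSummary",
    "detection_metrics",
    "snp_detection_metrics",
    "auc_trapezoid",
    "mean_curve_across_replicates",
    "count_significant_snps",
]

MEAN_CURVE_GRID = np.linspace(0.0, 1.0, 201)


@dataclass
class CurvePoints:
    """One operating curve: x is FPR (ROC) or recall (PR), y is TPR or precision."""

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray | None = None
    kind: str = "roc"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if np.any((self.x < -1e-12) | (self.x > 1 + 1e-12)):
            raise ValueError("curve x-values must lie in [0, 1]")


@dataclass
class MetricSummary:
    """Per-replicate AUCs and SNP counts with medians."""

    auc_roc: np.ndarray
    auc_pr: np.ndarray
    n_true_pos: np.ndarray | None = None
    n_novel_true_pos: np.ndarray | None = None
    n_false_pos: np.ndarray | None = None

    @property
    def median_auc_roc(self) -> float:
        return float(np.median(self.auc_roc))

    @property
    def median_auc_pr(self) -> float:
        return float(np.median(self.auc_pr))


def _roc_pr_from_scores(scores: np.ndarray, truth: np.ndarray):
    fpr, tpr, thr = roc_curve(truth, scores)
    roc = CurvePoints(x=fpr, y=tpr, thresholds=thr, kind="roc")
    prec, rec, thr_pr = precision_recall_curve(truth, scores)
    # sklearn returns decreasing recall; store increasing
    pr = CurvePoints(x=rec[::-1], y=prec[::-1],
                     thresholds=np.append(thr_pr, np.inf)[::-1], kind="pr")
    return roc, pr


def detection_metrics(scores, truth):
    """ROC and PR curves for misclassified-case detection.

    ``scores`` are average misclassification probabilities over the cases of
    the observed phenotype; ``truth`` marks the cases that are flipped
    controls.  Returns ``(roc, pr)``.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if not truth.any():
        raise ValueError("no misclassified samples in truth: PR undefined")
    if truth.all():
        raise ValueError("all samples misclassified in truth: ROC undefined")
    return _roc_pr_from_scores(scores, truth)


def snp_detection_metrics(p, causal_indices):
    """ROC and PR curves for causal-SNP recovery from association p-values.

    Smaller p means a stronger call, so the score is ``-log10(p)``.
    """
    p = np.asarray(p, dtype=float)
    causal_indices = np.asarray(causal_indices, dtype=np.int64)
    if causal_indices.size == 0:
        raise ValueError("empty causal set")
    truth = np.zeros(p.size, dtype=bool)
    truth[causal_indices] = True
    scores = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))
    return _roc_pr_from_scores(scores, truth)


def auc_trapezoid(curve: CurvePoints) -> float:
    """Trapezoidal area under the curve after sorting by x, clamped to [0, 1]."""
    if curve.x.size < 2:
        raise ValueError("need at least two points to integrate")
    order = np.argsort(curve.x, kind="stable")
    area = float(np.trapezoid(curve.y[order], curve.x[order]))
    return min(1.0, max(0.0, area))


def mean_curve_across_replicates(curves, grid=None) -> CurvePoints:
    """Pointwise mean of curves interpolated onto a common x-grid."""
    if len(curves) == 0:
        raise ValueError("no curves to average")
    grid = MEAN_CURVE_GRID if grid is None else np.asarray(grid, dtype=float)
    ys = []
    for c in curves:
        order = np.argsort(c.x, kind="stable")
        ys.append(np.interp(grid, c.x[order], c.y[order]))
    return CurvePoints(x=grid, y=np.mean(ys, axis=0), kind=curves[0].kind)


def count_significant_snps(p_corrected, causal_indices, threshold,
                           p_true=None, p_misclassified=None):
    """Counts of significant SNPs in a corrected-phenotype scan.

    ``true_positive``: causal SNPs below the threshold; ``false_positive``:
    non-causal SNPs below it; ``novel_true_positive``: causal SNPs
    significant in the corrected scan but in neither the true-phenotype nor
    the misclassified-phenotype scans (when those are supplied).
    """
    p_corrected = np.asarray(p_corrected, dtype=float)
    causal = np.zeros(p_corrected.size, dtype=bool)
    causal[np.asarray(causal_indices, dtype=np.int64)] = True
    sig = p_corrected < threshold
    counts = {
        "true_positive": int(np.sum(sig & causal)),
        "false_positive": int(np.sum(sig & ~causal)),
    }
    novel = sig & causal
    for other in (p_true, p_misclassified):
        if other is not None:
            other = np.asarray(other, dtype=float)
            if other.shape != p_corrected.shape:
                raise ValueError("p-value vectors cover different SNP universes")
            novel &= ~(other < threshold)
    counts["novel_true_positive"] = int(np.sum(novel))
    return counts
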