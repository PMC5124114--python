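"""ROC construction and PPV-constrained cutoff selection.

The classification cutoff is the operating point of maximal sensitivity
whose positive predictive value, at a stated prevalence, still meets a
target floor.  At prevalence π and PPV target P*, the feasible region is
bounded by the straight line

    spec_min(s) = 1 − s·π·(1−P*) / (P*·(1−π)),

the locus of (sensitivity, specificity) pairs achieving exactly P*: this
line is overlaid on the ROC curve and the cutoff sits at the first
intersection walking from the high-specificity corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ROCCurve", "CutoffResult", "roc_curve", "ppv_constraint_line",
           "ppv_at", "select_cutoff", "InfeasiblePPVTarget"]


class InfeasiblePPVTarget(ValueError):
    """Raised when no operating point reaches the PPV target."""

    def __init__(self, ppv_target: float, best_ppv: float):
        self.ppv_target = ppv_target
        self.best_ppv = best_ppv
        super().__init__(
            f"PPV target unattainable: target {ppv_target:.3f}, "
            f"best achievable {best_ppv:.3f}")


@dataclass(frozen=True)
class ROCCurve:
    """One point per distinct score threshold, thresholds strictly decreasing."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    @property
    def points(self):
        return list(zip(self.thresholds, self.sensitivity, self.specificity))


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    achieved_ppv: float
    prevalence_used: float
    ppv_target: float


def roc_curve(scores, labels) -> ROCCurve:
    """ROC over all distinct thresholds with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auc=auc)


def ppv_constraint_line(prevalence: float, ppv_target: float):
    """Return spec_min(s): the minimum specificity at sensitivity ``s`` that
    achieves ``ppv_target`` at the given prevalence.  Linear in s."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0 < ppv_target <= 1:
        raise ValueError("ppv_target must lie in (0, 1]")
    if ppv_target == 1.0:
        return lambda s: 1.0  # vertical limit: no false positives allowed
    slope = prevalence * (1.0 - ppv_target) / (ppv_target * (1.0 - prevalence))

    def spec_min(s: float) -> float:
        return 1.0 - s * slope

    return spec_min


def ppv_at(sensitivity: float, specificity: float, prevalence: float) -> float:
    """PPV from sensitivity/specificity at a stated prevalence
    (undefined → nan when no positives are called)."""
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    return num / den if den > 0 else float("nan")


def select_cutoff(roc: ROCCurve, prevalence: float, ppv_target: float
                  ) -> CutoffResult:
    """Maximal-sensitivity ROC point with achieved PPV ≥ target at the stated
    prevalence; ties broken toward higher specificity.  Equivalent to the
    first intersection of the constraint line with the ROC curve walking from
    the (0, 1) corner.  Raises :class:`InfeasiblePPVTarget` (reporting the
    best achievable PPV) when no point qualifies."""
    spec_min = ppv_constraint_line(prevalence, ppv_target)
    best = None  # (sens, spec, threshold)
    best_ppv = float("-inf")
    # sklearn thresholds are decreasing; walk from high-specificity end so a
    # sensitivity tie keeps the earlier (higher-specificity) point.
    for thr, sens, spec in zip(roc.thresholds, roc.sensitivity, roc.specificity):
        if not np.isfinite(thr) or sens <= 0:
            continue
        ppv = ppv_at(sens, spec, prevalence)
        if np.isfinite(ppv) and ppv > best_ppv:
            best_ppv = ppv
        if spec + 1e-12 >= spec_min(sens):
            if best is None or sens > best[0] + 1e-12:
                best = (sens, spec, thr)
    if best is None:
        raise InfeasiblePPVTarget(ppv_target, best_ppv if np.isfinite(best_ppv) else 0.0)
    sens, spec, thr = best
    return CutoffResult(
        cutoff=float(thr),
        sensitivity_at_cutoff=float(sens),
        specificity_at_cutoff=float(spec),
        achieved_ppv=float(ppv_at(sens, spec, prevalence)),
        prevalence_used=float(prevalence),
        ppv_target=float(ppv_target),
    )
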