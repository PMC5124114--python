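"""Evaluation surface: confusion-matrix metrics, case-finding yield,
temporal lead-time comparison, Wilson intervals, and the MDS training
diagnostic.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.proportion import proportion_confint

__all__ = ["ConfusionMatrix", "MetricsReport", "TemporalComparison",
           "metrics", "case_yield", "temporal_compare", "wilson_ci",
           "mds_diagnostic"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("empty confusion matrix")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("shape mismatch")
        return cls(tp=int(np.sum(y_true & y_pred)),
                   fp=int(np.sum(~y_true & y_pred)),
                   fn=int(np.sum(y_true & ~y_pred)),
                   tn=int(np.sum(~y_true & ~y_pred)))


@dataclass(frozen=True)
class MetricsReport:
    """Proportion metrics; a metric whose denominator is zero is None
    (undefined), never 0.  Raw fractions are retained alongside."""

    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None
    fractions: dict
    auc: float | None = None
    ci95: dict | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        out = {}
        for k in ("ppv", "npv", "sensitivity", "specificity", "auc"):
            v = getattr(self, k)
            out[k] = round(v, ndigits) if v is not None else None
        return out


def _ratio(num: int, den: int):
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix, *, auc: float | None = None,
            with_ci: bool = False) -> MetricsReport:
    """PPV, NPV, sensitivity and specificity from confusion counts."""
    fractions = {
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
    }
    vals = {k: _ratio(*v) for k, v in fractions.items()}
    ci95 = None
    if with_ci:
        ci95 = {k: wilson_ci(*fractions[k]) for k in fractions
                if fractions[k][1] > 0}
    return MetricsReport(ppv=vals["ppv"], npv=vals["npv"],
                         sensitivity=vals["sensitivity"],
                         specificity=vals["specificity"],
                         fractions=fractions, auc=auc, ci95=ci95)


def wilson_ci(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def case_yield(n_codified: int, n_nlp_additional: int) -> float:
    """Percent increase in found cases over code-based finding alone,
    rounded to 2 decimals."""
    if n_codified <= 0:
        raise ValueError("n_codified must be positive")
    return round(100.0 * n_nlp_additional / n_codified, 2)


@dataclass(frozen=True)
class TemporalComparison:
    n_both: int
    n_nlp_earlier: int
    n_same_day: int
    n_icd_earlier: int
    mean_lead_days: float | None
    n_lead_ge_90_days: int

    @property
    def nlp_earlier_fraction(self) -> float | None:
        return self.n_nlp_earlier / self.n_both if self.n_both else None

    @property
    def lead_ge_90_fraction(self) -> float | None:
        return (self.n_lead_ge_90_days / self.n_nlp_earlier
                if self.n_nlp_earlier else None)


def temporal_compare(nlp_dates: dict, icd_dates: dict) -> TemporalComparison:
    """Lead-time comparison over patients with both a first NLP-positive date
    and a first DM-code date.  Lead = code date − NLP date in days; only
    strictly positive leads count as NLP-earlier; the ≥90-day count
    operationalises "3 months or more"."""
    leads = []
    for pid, nlp_date in nlp_dates.items():
        icd_date = icd_dates.get(pid)
        if nlp_date is None or icd_date is None:
            continue
        if isinstance(nlp_date, str):
            nlp_date = dt.date.fromisoformat(nlp_date)
        if isinstance(icd_date, str):
            icd_date = dt.date.fromisoformat(icd_date)
        leads.append((icd_date - nlp_date).days)
    leads = np.asarray(leads, dtype=int)
    positive = leads[leads > 0]
    return TemporalComparison(
        n_both=int(leads.size),
        n_nlp_earlier=int(positive.size),
        n_same_day=int(np.sum(leads == 0)),
        n_icd_earlier=int(np.sum(leads < 0)),
        mean_lead_days=float(positive.mean()) if positive.size else None,
        n_lead_ge_90_days=int(np.sum(positive >= 90)),
    )


def mds_diagnostic(feature_vectors, labels, n_points: int = 1000,
                   seed: int = 0, *, metric: str = "jaccard"):
    """Classical metric MDS of sampled binary feature vectors, a diagnostic of
    training-set separation between codified-positive and uncodified-negative
    notes.

    Returns ``(coords, sampled_labels, sampled_index)`` where coords is
    (n, 2): the double-centered eigendecomposition of the squared pairwise
    Jaccard (by default) distance matrix.
    """
    X = np.asarray(feature_vectors, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValueError("feature_vectors must be 2-D and aligned with labels")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for an MDS diagnostic")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=min(n_points, n), replace=False))
    Xs, ys = X[idx], labels[idx]

    with warnings.catch_warnings():
        # all-zero rows give 0/0 Jaccard distances; treat them as identical
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(Xs.astype(bool), metric=metric))
    D = np.nan_to_num(D, nan=0.0)
    if not D.any():
        warnings.warn("all sampled vectors are identical; MDS coordinates are zero",
                      stacklevel=2)
        return np.zeros((len(idx), 2)), ys, idx

    m = len(idx)
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:2]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    return coords, ys, idx
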