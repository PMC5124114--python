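"""Hybrid case-finding model.

The posterior over DM status splits on the codified flag: a note carrying an
ICD-9-CM 249/250 code is DM with probability 1 (a predetermined, human-prior
branch); an uncodified note is scored by a random forest T(f) over the
NLP-derived feature vector f — the vote fraction of the ensemble's trees.

Training follows the codified-note-driven scheme: codified notes form the
positive sample and an equal-size random draw of uncodified notes the
negative sample; features are screened by a two-sided Mann-Whitney rank-sum
test; and an iterative refinement step re-adjudicates flagged training
negatives (through a pluggable truth oracle standing in for human chart
review), moving confirmed DM notes to the positive side and refitting until
a fixed point.

The public surface is statsmodels-style: :class:`DMCaseFinder` is built from
a corpus and a knowledge base, and :meth:`DMCaseFinder.fit` returns a
:class:`CaseFindingResults` carrying the fitted ensemble, screening results,
calibration state, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier

from .features import build_schema, vectorize_corpus, is_dm_codified
from .io import ClinicalNote, read_notes
from .knowledge_base import KnowledgeBase, default_knowledge_base
from .operating_point import CutoffResult, roc_curve, select_cutoff

__all__ = ["TrainingConfig", "FeatureScreenResult", "DMCaseFinder",
           "CaseFindingResults", "screen_features", "assemble_training",
           "feature_importance"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    alpha: float = 0.05            # Mann-Whitney screening level
    n_trees: int = 500
    max_iterations: int = 5        # refinement passes
    seed: int = 0
    negative_sample_ratio: float = 1.0
    flag_threshold: float = 0.5    # training-negative score that triggers review

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_trees < 1 or self.max_iterations < 1:
            raise ValueError("n_trees and max_iterations must be >= 1")


@dataclass(frozen=True)
class FeatureScreenResult:
    feature: str
    p_value: float
    selected: bool


#: use the exact permutation null when C(n, n1) is at most this large
_EXACT_ENUM_LIMIT = 200_000


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p over all label permutations.

    Midranks handle ties; rank sums are doubled so every achievable sum is an
    integer, and the full permutation distribution of the group-1 rank sum is
    built by dynamic programming over (subset size, sum).  Two-sided p is the
    doubled smaller tail, capped at 1 (the tied null is not symmetric, so the
    |deviation| form would not be well defined).
    """
    from scipy.stats import rankdata

    n = len(x)
    n1 = int(y.sum())
    r2 = np.rint(2 * rankdata(x)).astype(int)
    obs = int(r2[y == 1].sum())
    max_sum = int(r2.sum())
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in r2:
        for k in range(min(n1, n) - 1, -1, -1):
            row = counts[k]
            nz = np.flatnonzero(row)
            if nz.size:
                counts[k + 1, nz + r] += row[nz]
    dist = counts[n1]
    total = dist.sum()
    lo = dist[: obs + 1].sum() / total
    hi = dist[obs:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def screen_features(X, labels, alpha: float = 0.05) -> list[FeatureScreenResult]:
    """Per-feature two-sided Mann-Whitney rank-sum test against the binary
    label; a feature is selected iff p < alpha.  Constant columns get p = 1.

    Small samples (where the label-permutation null is exhaustively
    enumerable) use the exact permutation distribution of the rank sum; at
    production sizes the tie-corrected normal approximation is used.
    """
    from math import comb

    X = pd.DataFrame(X)
    y = np.asarray(labels).astype(int)
    n1, n0 = int(np.sum(y == 1)), int(np.sum(y == 0))
    if min(n1, n0) < 2:
        raise ValueError("need at least 2 samples per class to screen features")
    exact = comb(n1 + n0, n1) <= _EXACT_ENUM_LIMIT
    results = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            p = 1.0
        elif exact:
            p = _exact_rank_sum_p(x, y)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = mannwhitneyu(x[y == 1], x[y == 0],
                                    alternative="two-sided", method="asymptotic")
            p = float(min(p, 1.0))
        results.append(FeatureScreenResult(str(col), p, bool(p < alpha)))
    return results


def assemble_training(notes, seed: int = 0, *, ratio: float = 1.0
                      ) -> tuple[list[ClinicalNote], list[ClinicalNote]]:
    """Positives = all codified notes; negatives = a seeded simple random
    sample of uncodified notes of equal size (ratio × positives), or all
    uncodified notes if fewer are available."""
    notes = list(notes)
    pos = [n for n in notes if is_dm_codified(n.icd_codes)]
    uncod = [n for n in notes if not is_dm_codified(n.icd_codes)]
    if not pos:
        raise ValueError("nothing to learn from: corpus has no codified notes")
    want = int(round(ratio * len(pos)))
    rng = np.random.default_rng(seed)
    if len(uncod) <= want:
        if len(uncod) < want:
            warnings.warn(
                f"only {len(uncod)} uncodified notes available for "
                f"{want} requested negatives; using all of them", stacklevel=2)
        neg = list(uncod)
    else:
        idx = np.sort(rng.choice(len(uncod), size=want, replace=False))
        neg = [uncod[i] for i in idx]
    return pos, neg


def _fit_forest(X: np.ndarray, y: np.ndarray, config: TrainingConfig
                ) -> RandomForestClassifier:
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training input")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features="sqrt",
        random_state=config.seed, n_jobs=1, oob_score=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few trees can leave rows un-OOB
        forest.fit(X, y)
    return forest


def feature_importance(forest: RandomForestClassifier, X, y, seed: int = 0,
                       n_repeats: int = 10) -> pd.DataFrame:
    """Permutation importance (mean decrease in accuracy scaled by the SD of
    the decreases over repeats) plus the ensemble's total Gini impurity
    decrease, sorted descending by the permutation score.

    Zero-SD features fall back to the raw mean drop and are flagged.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    base_acc = float(np.mean(forest.predict(X.to_numpy()) == y))
    rows = []
    gini = dict(zip(X.columns, forest.feature_importances_))
    for j, col in enumerate(X.columns):
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = X.to_numpy().copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[r] = base_acc - float(np.mean(forest.predict(Xp) == y))
        sd = float(drops.std(ddof=1))
        if sd > 0:
            score, flagged = float(drops.mean()) / sd, False
        else:
            score, flagged = float(drops.mean()), True
        rows.append({"feature": str(col),
                     "mean_decrease_accuracy_scaled": score,
                     "gini_decrease": float(gini[col]),
                     "sd_zero": flagged})
    out = pd.DataFrame(rows).sort_values(
        ["mean_decrease_accuracy_scaled", "gini_decrease"],
        ascending=False, kind="mergesort").reset_index(drop=True)
    return out


class DMCaseFinder:
    """Case-finding model over a clinical-note corpus.

    Parameters
    ----------
    notes : iterable of ClinicalNote
        The training corpus (typically the notes of the training facilities).
    kb : KnowledgeBase, optional
        Defaults to the package's curated knowledge base.
    config : TrainingConfig, optional
    """

    def __init__(self, notes, kb: KnowledgeBase | None = None,
                 config: TrainingConfig | None = None):
        self.notes = list(notes)
        self.kb = kb if kb is not None else default_knowledge_base()
        self.config = config if config is not None else TrainingConfig()
        self.schema = build_schema(self.kb)

    @classmethod
    def from_jsonl(cls, path, kb=None, config=None) -> "DMCaseFinder":
        return cls(read_notes(path), kb=kb, config=config)

    def fit(self, truth_oracle=None) -> "CaseFindingResults":
        """Assemble, screen, fit, and (if an oracle is supplied) iteratively
        refine; returns a :class:`CaseFindingResults`.

        ``truth_oracle(note) -> bool`` adjudicates the true DM status of a
        flagged training negative (human chart review in production,
        synthetic ground truth in tests).
        """
        cfg = self.config
        pos, neg = assemble_training(self.notes, seed=cfg.seed,
                                     ratio=cfg.negative_sample_ratio)
        train_notes = pos + neg
        X_all, _, note_ids, schema = vectorize_corpus(train_notes, self.kb,
                                                      self.schema)
        y = np.array([1] * len(pos) + [0] * len(neg))

        screen = screen_features(X_all, y, alpha=cfg.alpha)
        selected = [r.feature for r in screen if r.selected]
        if not selected:
            raise ValueError("feature screening removed every feature")
        X = X_all[selected]

        forest = _fit_forest(X.to_numpy(), y, cfg)

        iterations_run, moved_log = 0, []
        if truth_oracle is not None:
            forest, y, iterations_run, moved_log = self._iterative_refine(
                forest, X, y, train_notes, truth_oracle, cfg)

        meta = {
            "n_trees": cfg.n_trees,
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "iterations_run": iterations_run,
            "moved_per_iteration": moved_log,
            "n_positive_notes": int(np.sum(y == 1)),
            "n_negative_notes": int(np.sum(y == 0)),
            "selected_features": selected,
            "training_note_ids": list(note_ids),
            "negative_note_ids": [n.note_id for n in neg],
        }
        return CaseFindingResults(kb=self.kb, schema=schema, forest=forest,
                                  screen=screen, selected_features=selected,
                                  training_meta=meta, config=cfg)

    @staticmethod
    def _iterative_refine(forest, X: pd.DataFrame, y: np.ndarray, train_notes,
                          truth_oracle, cfg: TrainingConfig):
        """Score current negatives; oracle-confirmed DM among the flagged
        move to the positive class; refit; stop at a fixed point or after
        ``max_iterations`` passes."""
        y = y.copy()
        moved_log = []
        iterations = 0
        for _ in range(cfg.max_iterations):
            iterations += 1
            neg_idx = np.flatnonzero(y == 0)
            # out-of-bag estimates: an in-sample forest memorizes its own
            # training labels, hiding mislabeled negatives
            oob = getattr(forest, "oob_decision_function_", None)
            if oob is not None:
                proba = oob[neg_idx, 1]
                nan = ~np.isfinite(proba)
                if nan.any():
                    proba = proba.copy()
                    proba[nan] = forest.predict_proba(
                        X.to_numpy()[neg_idx[nan]])[:, 1]
            else:  # pragma: no cover
                proba = forest.predict_proba(X.to_numpy()[neg_idx])[:, 1]
            flagged = neg_idx[proba >= cfg.flag_threshold]
            moved = []
            for i in flagged:
                try:
                    confirmed = bool(truth_oracle(train_notes[i]))
                except Exception as exc:
                    raise RuntimeError(
                        f"truth oracle failed on note {train_notes[i].note_id!r} "
                        f"after {iterations - 1} completed iterations "
                        f"({sum(moved_log)} notes moved so far): {exc}") from exc
                if confirmed:
                    moved.append(i)
            moved_log.append(len(moved))
            logger.info("refinement iteration %d: %d flagged, %d moved",
                        iterations, len(flagged), len(moved))
            if not moved:
                break
            y[moved] = 1
            forest = _fit_forest(X.to_numpy(), y, cfg)
        return forest, y, iterations, moved_log


@dataclass
class CaseFindingResults:
    """Fitted case-finding model: ensemble, screened schema, calibration
    state and diagnostics."""

    kb: KnowledgeBase
    schema: object
    forest: RandomForestClassifier
    screen: list[FeatureScreenResult]
    selected_features: list[str]
    training_meta: dict
    config: TrainingConfig
    cutoff: float | None = None
    cutoff_result: CutoffResult | None = None

    # ---------------- scoring ----------------

    def _feature_frame(self, notes) -> tuple[pd.DataFrame, np.ndarray, list]:
        X_all, codified, ids, _ = vectorize_corpus(notes, self.kb, self.schema)
        return X_all[self.selected_features], codified, ids

    def score_vector(self, values: np.ndarray, codified: bool) -> float:
        """Posterior for one note: 1.0 exactly on the codified branch, else
        the ensemble vote fraction T(f)."""
        if codified:
            return 1.0
        values = np.asarray(values, dtype=float).reshape(1, -1)
        if values.shape[1] != len(self.selected_features):
            raise ValueError(
                f"schema mismatch: expected {len(self.selected_features)} "
                f"features, got {values.shape[1]}")
        return float(self.forest.predict_proba(values)[0, 1])

    def score_notes(self, notes) -> pd.DataFrame:
        """Per-note scores: DataFrame with note_id, patient_id,
        encounter_date, codified, score."""
        notes = list(notes)
        if not notes:
            return pd.DataFrame(columns=["note_id", "patient_id",
                                         "encounter_date", "codified", "score"])
        X, codified, ids = self._feature_frame(notes)
        scores = np.empty(len(notes))
        uncod = ~codified
        scores[codified] = 1.0
        if uncod.any():
            scores[uncod] = self.forest.predict_proba(
                X.to_numpy()[uncod])[:, 1]
        return pd.DataFrame({
            "note_id": ids,
            "patient_id": [n.patient_id for n in notes],
            "encounter_date": [n.encounter_date for n in notes],
            "codified": codified,
            "score": scores,
        })

    def predict_patients(self, notes, cutoff: float | None = None) -> pd.DataFrame:
        """Patient-level classification: a patient is DM iff any note scores
        ≥ cutoff; the first-positive date is the earliest such note's
        encounter date."""
        cutoff = self._resolve_cutoff(cutoff)
        scored = self.score_notes(notes)
        rows = []
        for pid, grp in scored.groupby("patient_id", sort=True):
            positive = grp[grp["score"] >= cutoff]
            rows.append({
                "patient_id": pid,
                "n_notes": len(grp),
                "max_score": float(grp["score"].max()),
                "any_codified": bool(grp["codified"].any()),
                "dm": bool(len(positive)),
                "first_positive_date": (positive["encounter_date"].min()
                                        if len(positive) else None),
            })
        return pd.DataFrame(rows)

    def _resolve_cutoff(self, cutoff):
        if cutoff is None:
            cutoff = self.cutoff
        if cutoff is None:
            raise ValueError("no cutoff set; call calibrate() or pass cutoff=")
        return float(cutoff)

    # ---------------- calibration ----------------

    def calibrate(self, gold_notes, gold_labels: dict, ppv_target: float = 0.9,
                  prevalence: float | None = None) -> CutoffResult:
        """Choose the cutoff on a gold-standard patient set: maximal
        sensitivity subject to achieved PPV ≥ ``ppv_target`` at the stated
        (default: empirical) prevalence.  Patient score = max note score."""
        scored = self.score_notes(gold_notes)
        per_patient = scored.groupby("patient_id")["score"].max()
        pids = [p for p in per_patient.index if p in gold_labels]
        if len(pids) < len(per_patient):
            missing = len(per_patient) - len(pids)
            logger.warning("%d scored patients missing from gold labels", missing)
        scores = per_patient.loc[pids].to_numpy()
        labels = np.array([int(bool(gold_labels[p])) for p in pids])
        if prevalence is None:
            prevalence = float(labels.mean())
        roc = roc_curve(scores, labels)
        result = select_cutoff(roc, prevalence, ppv_target)
        self.cutoff = result.cutoff
        self.cutoff_result = result
        return result

    # ---------------- diagnostics ----------------

    def feature_importance(self, notes, labels, seed: int | None = None,
                           n_repeats: int = 10) -> pd.DataFrame:
        X, _, ids = self._feature_frame(notes)
        y = np.asarray(labels).astype(int)
        return feature_importance(self.forest, X, y,
                                  seed=self.config.seed if seed is None else seed,
                                  n_repeats=n_repeats)

    def summary(self) -> str:
        meta = self.training_meta
        n_sel = len(self.selected_features)
        n_all = len(self.screen)
        lines = [
            "DM case-finding model",
            "=" * 52,
            f"training notes          {meta['n_positive_notes'] + meta['n_negative_notes']:>8}"
            f"  (pos {meta['n_positive_notes']}, neg {meta['n_negative_notes']})",
            f"features screened       {n_all:>8}  selected {n_sel} at alpha={meta['alpha']}",
            f"trees                   {meta['n_trees']:>8}  seed {meta['seed']}",
            f"refinement iterations   {meta['iterations_run']:>8}"
            f"  moved {meta['moved_per_iteration']}",
        ]
        if self.cutoff_result is not None:
            c = self.cutoff_result
            lines += [
                f"cutoff                  {c.cutoff:>8.3f}  (PPV target {c.ppv_target:.2f} "
                f"at prevalence {c.prevalence_used:.3f})",
                f"  sensitivity {c.sensitivity_at_cutoff:.3f}  specificity "
                f"{c.specificity_at_cutoff:.3f}  achieved PPV {c.achieved_ppv:.3f}",
            ]
        else:
            lines.append("cutoff                  not calibrated")
        top = sorted(self.screen, key=lambda r: r.p_value)[:10]
        lines.append("-" * 52)
        lines.append("lowest screening p-values:")
        for r in top:
            lines.append(f"  {r.feature:<36} p={r.p_value:.3g}")
        return "\n".join(lines)

    # ---------------- persistence ----------------

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "CaseFindingResults":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a CaseFindingResults bundle")
        return obj
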