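"""End-to-end orchestration: simulate → train → calibrate → predict →
evaluate, with a facility split between training/calibration and blind
testing.  This mirrors a deployment where knowledge learned at some health
care facilities is transferred to score notes from others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .evaluate import (ConfusionMatrix, case_yield, metrics, temporal_compare)
from .features import is_dm_codified
from .knowledge_base import KnowledgeBase, default_knowledge_base
from .model import DMCaseFinder, TrainingConfig
from .operating_point import roc_curve
from .synthetic import GeneratorConfig, GroundTruth, generate_corpus, make_gold_standard

__all__ = ["EndToEndResult", "split_facilities", "truth_oracle_from",
           "run_end_to_end"]

logger = logging.getLogger(__name__)


@dataclass
class EndToEndResult:
    results: object                 # CaseFindingResults (calibrated)
    cutoff_result: object
    heldout_metrics: object         # MetricsReport
    heldout_cm: ConfusionMatrix
    heldout_auc: float
    n_codified_heldout: int
    n_nlp_additional: int
    n_uncodified_dm_found: int
    n_uncodified_dm_total: int
    yield_pct: float
    temporal: object
    predictions: object             # per-patient DataFrame


def split_facilities(truth: GroundTruth, train_share: float = 0.5):
    """Deterministic facility split: the lexicographically first
    ``train_share`` of facilities train/calibrate, the rest blind-test."""
    facilities = sorted({rec["facility_id"] for rec in truth.values()})
    n_train = max(1, int(round(train_share * len(facilities))))
    return set(facilities[:n_train]), set(facilities[n_train:])


def truth_oracle_from(truth: GroundTruth):
    """Adjudication oracle backed by synthetic ground truth (the stand-in for
    human chart review)."""
    def oracle(note) -> bool:
        return bool(truth[note.patient_id]["dm_status"])
    return oracle


def run_end_to_end(gen_config: GeneratorConfig | None = None,
                   kb: KnowledgeBase | None = None,
                   train_config: TrainingConfig | None = None,
                   ppv_target: float = 0.90,
                   calibration_draw: tuple[int, int] = (100, 500),
                   seed: int = 0) -> EndToEndResult:
    """Full pipeline on a synthetic corpus with a facility split.

    Training and cutoff calibration use the training facilities only; the
    held-out facilities provide the blind test.  The calibration gold
    standard is a seeded stratified patient draw (``calibration_draw``,
    default 100 DM / 500 non-DM, i.e. prevalence 1/6) excluding patients
    whose uncodified notes entered the training negative sample.
    """
    gen_config = gen_config or GeneratorConfig(seed=seed)
    kb = kb or default_knowledge_base()
    train_config = train_config or TrainingConfig(seed=seed)

    notes, truth = generate_corpus(gen_config)
    train_fac, test_fac = split_facilities(truth)
    train_notes = [n for n in notes if n.facility_id in train_fac]
    test_notes = [n for n in notes if n.facility_id in test_fac]
    logger.info("corpus: %d notes; train %d, held-out %d",
                len(notes), len(train_notes), len(test_notes))

    model = DMCaseFinder(train_notes, kb=kb, config=train_config)
    results = model.fit(truth_oracle=truth_oracle_from(truth))

    # calibration gold standard: train-facility patients not used as
    # training negatives
    neg_ids = set(results.training_meta["negative_note_ids"])
    tainted = {n.patient_id for n in train_notes if n.note_id in neg_ids}
    frame = [p for p, rec in truth.items()
             if rec["facility_id"] in train_fac and p not in tainted]
    gold = make_gold_standard(notes, truth, *calibration_draw,
                              seed=seed, patient_ids=frame)
    gold_ids = set(gold["patient_id"])
    gold_notes = [n for n in train_notes if n.patient_id in gold_ids]
    gold_labels = dict(zip(gold["patient_id"], gold["dm_status"]))
    cutoff = results.calibrate(gold_notes, gold_labels, ppv_target=ppv_target)
    logger.info("calibrated cutoff %.3f (sens %.3f, spec %.3f, PPV %.3f)",
                cutoff.cutoff, cutoff.sensitivity_at_cutoff,
                cutoff.specificity_at_cutoff, cutoff.achieved_ppv)

    # blind test on held-out facilities
    preds = results.predict_patients(test_notes)
    truth_vec = np.array([bool(truth[p]["dm_status"]) for p in preds["patient_id"]])
    pred_vec = preds["dm"].to_numpy()
    cm = ConfusionMatrix.from_predictions(truth_vec, pred_vec)
    auc = roc_curve(preds["max_score"].to_numpy(), truth_vec).auc
    report = metrics(cm, auc=auc, with_ci=True)

    codified_pids = {n.patient_id for n in test_notes if is_dm_codified(n.icd_codes)}
    n_codified = len(codified_pids)
    flagged = set(preds.loc[preds["dm"], "patient_id"])
    additional = flagged - codified_pids
    uncod_dm_total = [p for p in {n.patient_id for n in test_notes}
                      if truth[p]["dm_status"] and p not in codified_pids]
    uncod_dm_found = [p for p in additional if truth[p]["dm_status"]]
    yield_pct = case_yield(n_codified, len(additional)) if n_codified else float("nan")

    nlp_dates = {row.patient_id: row.first_positive_date
                 for row in preds.itertuples() if row.dm}
    icd_dates = {p: truth[p]["first_icd_date"] for p in nlp_dates}
    temporal = temporal_compare(nlp_dates, icd_dates)

    return EndToEndResult(
        results=results, cutoff_result=cutoff, heldout_metrics=report,
        heldout_cm=cm, heldout_auc=float(auc), n_codified_heldout=n_codified,
        n_nlp_additional=len(additional),
        n_uncodified_dm_found=len(uncod_dm_found),
        n_uncodified_dm_total=len(uncod_dm_total),
        yield_pct=float(yield_pct), temporal=temporal, predictions=preds,
    )
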