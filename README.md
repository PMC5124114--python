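# dmfind

Case finding for diabetes mellitus (DM) from electronic medical records
when diagnosis codes are absent or incomplete.  Many patients with
documented diabetes never receive an ICD-9-CM 249/250 code — care split
across facilities, acute admissions that crowd out coding — yet their
free-text notes say "type 2 diabetes mellitus, on metformin".  `dmfind`
implements an NLP case-finding pipeline for this setting: it is aimed at
population-health and EMR-phenotyping work where the deliverable is a
patient list with a guaranteed positive predictive value (PPV).

## The model

For a note with feature vector *f* and codified flag *ICD* (does the
encounter carry a 249/250 code?), the posterior splits into two branches:

    P(DM = 1 | ICD = 1)     = 1                 (predetermined rule branch)
    P(DM = 1 | ICD = 0, f)  = T(f) = (1/N) Σₙ tₙ(f)   (random-forest branch)

where *tₙ* is the *n*-th tree's vote.  Before feature extraction, notes are
segmented into basic units and every unit containing a negation trigger
("denies diabetes") or family-history trigger ("mother had diabetes") is
removed.  Features are binary controlled-vocabulary term and medication
indicators, one-hot risk factors (WHO BMI class, blood pressure, smoking,
alcohol, history-of-DM), age and sex, screened by a two-sided Mann-Whitney
test at α = .05.  Training positives are codified notes, negatives an
equal-size sample of uncodified notes, refined iteratively: flagged
training negatives confirmed as DM by an adjudication oracle move to the
positive class and the forest is refit.

The patient-level cutoff *c* is chosen on a gold-standard draw as the
maximal-sensitivity point of the ROC curve satisfying a PPV floor: at
prevalence π and target P\*, feasible operating points lie above the line
`spec_min(s) = 1 − s·π·(1−P*) / (P*·(1−π))`.  A patient is DM if any note
scores ≥ *c*; the earliest such encounter date supports lead-time analysis
against the first coded date.

A seeded synthetic corpus generator (affirmative/negated/family DM
mentions, medication lists, vitals lines with decimal-point hazards,
configurable codified fraction and ICD lag) provides ground truth for
development and testing.  See `docs/methods.md` for the full method
description and its limitations.

## Worked example

```python
from dmfind import (GeneratorConfig, TrainingConfig, DMCaseFinder,
                    generate_corpus, make_gold_standard, truth_oracle_from)

notes, truth = generate_corpus(GeneratorConfig(n_patients=1500, seed=1))
facilities = sorted({n.facility_id for n in notes})
train = [n for n in notes if n.facility_id in facilities[:4]]
test = [n for n in notes if n.facility_id not in facilities[:4]]

model = DMCaseFinder(train, config=TrainingConfig(seed=1, n_trees=200))
results = model.fit(truth_oracle=truth_oracle_from(truth))

gold = make_gold_standard(train, truth, 50, 250, seed=1,
                          patient_ids={n.patient_id for n in train})
gold_ids = set(gold["patient_id"])
results.calibrate([n for n in train if n.patient_id in gold_ids],
                  dict(zip(gold["patient_id"], gold["dm_status"])),
                  ppv_target=0.90)
print(results.summary())
preds = results.predict_patients(test)
print(preds["dm"].sum(), "of", len(preds), "held-out patients flagged")
```

prints:

```
DM case-finding model
====================================================
training notes               144  (pos 76, neg 68)
features screened            141  selected 45 at alpha=0.05
trees                        200  seed 1
refinement iterations          2  moved [4, 0]
cutoff                     0.685  (PPV target 0.90 at prevalence 0.167)
  sensitivity 1.000  specificity 1.000  achieved PPV 1.000
----------------------------------------------------
lowest screening p-values:
  term:diabetes                        p=6.02e-21
  term:diabetes mellitus               p=1.67e-17
  term:mellitus                        p=1.67e-17
  term:type                            p=3.92e-12
  age                                  p=6.98e-11
  term:type 2                          p=2.1e-09
  term:diabetic                        p=4.73e-09
  risk:bmi=obesity                     p=1.04e-08
  term:2                               p=6.07e-08
  risk:bmi=normal                      p=3.96e-06
81 of 734 held-out patients flagged
```

Reading it: 76 codified notes trained against 68 uncodified negatives; 45
of 141 candidate features survived the rank-sum screen, led by the direct
DM terms with age and obesity close behind; the refinement pass moved 4
mislabeled negatives into the positive class; and the cutoff 0.685 is the
highest-sensitivity operating point keeping PPV ≥ 90% on the 50/250
calibration draw (prevalence 1/6).  Of the 734 held-out patients, 81 are
flagged — codified patients (score 1.0 by the rule branch) plus uncodified
patients whose note text scores above the cutoff.

The same pipeline is scriptable from the shell:

```
dmfind simulate --n-patients 2000 --seed 1 --out-dir work/
dmfind train --corpus work/corpus.jsonl --truth work/truth.jsonl \
             --model-out work/model.joblib
dmfind calibrate --model work/model.joblib --corpus work/corpus.jsonl \
                 --truth work/truth.jsonl --model-out work/model_cal.joblib
dmfind predict --model work/model_cal.joblib --corpus work/corpus.jsonl \
               --out work/preds.tsv
dmfind evaluate --predictions work/preds.tsv --truth work/truth.jsonl
```

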