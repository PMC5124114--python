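import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from dmfind import (DMCaseFinder, GeneratorConfig, TrainingConfig,
                    assemble_training, generate_corpus, roc_curve,
                    screen_features, truth_oracle_from)
from dmfind.model import feature_importance, _fit_forest

from conftest import make_note


def brute_force_rank_p(x, y):
    """Independent oracle: exhaustive enumeration of the U statistic built
    from pairwise comparisons; two-sided p = doubled smaller tail."""
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    n, n1 = len(x), int(y.sum())

    def ustat(idx):
        g1 = x[list(idx)]
        g0 = np.delete(x, list(idx))
        return float(np.sum(g1[:, None] > g0[None, :])
                     + 0.5 * np.sum(g1[:, None] == g0[None, :]))

    obs = ustat(tuple(np.flatnonzero(y == 1)))
    lo = hi = tot = 0
    for idx in itertools.combinations(range(n), n1):
        u = ustat(idx)
        tot += 1
        lo += u <= obs + 1e-9
        hi += u >= obs - 1e-9
    return min(1.0, 2 * min(lo, hi) / tot)


class TestScreenFeatures:
    def test_constant_column_never_selected(self):
        X = np.ones((20, 1))
        y = np.array([1] * 10 + [0] * 10)
        res = screen_features(X, y)[0]
        assert res.p_value == 1.0 and not res.selected

    def test_identical_distribution_not_selected(self):
        col = np.array([0, 1] * 10, dtype=float)
        y = np.array([1] * 10 + [0] * 10)
        assert not screen_features(col.reshape(-1, 1), y)[0].selected

    def test_perfect_separation_selected(self):
        col = np.array([1.0] * 10 + [0.0] * 10)
        y = np.array([1] * 10 + [0] * 10)
        res = screen_features(col.reshape(-1, 1), y)[0]
        assert res.selected
        assert res.p_value == pytest.approx(
            brute_force_rank_p(col, y), abs=1e-12)

    def test_alpha_zero_boundary_selects_nothing(self):
        col = np.array([1.0] * 10 + [0.0] * 10)
        y = np.array([1] * 10 + [0] * 10)
        with pytest.raises(ValueError):
            TrainingConfig(alpha=0.0)
        # selection rule is strict p < alpha
        assert not screen_features(col.reshape(-1, 1), y, alpha=0.0)[0].selected

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            screen_features(np.zeros((3, 1)), [1, 0, 0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n1, n0 = rng.integers(3, 11, size=2)
            x = rng.integers(0, 3, size=n1 + n0).astype(float)
            if np.all(x == x[0]):
                continue
            y = np.array([1] * n1 + [0] * n0)
            p = screen_features(x.reshape(-1, 1), y)[0].p_value
            assert p == pytest.approx(brute_force_rank_p(x, y), abs=0.02)


class TestAssembleTraining:
    def _notes(self, n_cod, n_uncod):
        notes = [make_note("x", note_id=f"c{i}", patient_id=f"c{i}",
                           icd_codes=["250.00"]) for i in range(n_cod)]
        notes += [make_note("x", note_id=f"u{i}", patient_id=f"u{i}")
                  for i in range(n_uncod)]
        return notes

    def test_balanced_sampling(self):
        pos, neg = assemble_training(self._notes(100, 1000), seed=0)
        assert len(pos) == 100 and len(neg) == 100

    def test_exhaustion_with_warning(self):
        with pytest.warns(UserWarning, match="uncodified"):
            pos, neg = assemble_training(self._notes(100, 50), seed=0)
        assert len(pos) == 100 and len(neg) == 50

    def test_seed_determinism(self):
        notes = self._notes(50, 500)
        _, neg1 = assemble_training(notes, seed=3)
        _, neg2 = assemble_training(notes, seed=3)
        assert [n.note_id for n in neg1] == [n.note_id for n in neg2]

    def test_no_codified_errors(self):
        with pytest.raises(ValueError, match="nothing to learn"):
            assemble_training(self._notes(0, 10), seed=0)


class TestFitAndScore:
    def test_separable_toy_training_probabilities(self):
        rng = np.random.default_rng(0)
        X = np.vstack([np.ones((30, 1)) + rng.normal(0, .05, (30, 1)),
                       np.zeros((30, 1)) + rng.normal(0, .05, (30, 1))])
        y = np.array([1] * 30 + [0] * 30)
        forest = _fit_forest(X, y, TrainingConfig(seed=0, n_trees=100))
        assert np.all(forest.predict_proba(X[:30])[:, 1] >= 0.9)

    def test_shuffled_labels_no_signal(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(300, 5)).astype(float)
        y = rng.integers(0, 2, size=300)
        forest = _fit_forest(X[:200], y[:200], TrainingConfig(seed=0, n_trees=100))
        scores = forest.predict_proba(X[200:])[:, 1]
        auc = roc_curve(scores, y[200:]).auc
        assert abs(auc - 0.5) < 0.15

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single-class"):
            _fit_forest(np.zeros((10, 2)), np.ones(10), TrainingConfig())

    def test_refit_same_seed_identical(self, small_corpus, kb):
        notes, truth, _ = small_corpus
        config = TrainingConfig(seed=7, n_trees=50)
        r1 = DMCaseFinder(notes, kb=kb, config=config).fit()
        r2 = DMCaseFinder(notes, kb=kb, config=config).fit()
        s1 = r1.score_notes(notes[:50])["score"]
        s2 = r2.score_notes(notes[:50])["score"]
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_codified_branch_scores_one(self, fitted_results):
        results, notes, _ = fitted_results
        scored = results.score_notes(notes)
        codified = scored[scored["codified"]]
        assert len(codified) > 0
        assert np.all(codified["score"].to_numpy() == 1.0)

    def test_scores_within_unit_interval(self, fitted_results):
        results, notes, _ = fitted_results
        s = results.score_notes(notes)["score"].to_numpy()
        assert np.all((s >= 0.0) & (s <= 1.0))

    def test_schema_mismatch_errors(self, fitted_results):
        results, _, _ = fitted_results
        with pytest.raises(ValueError, match="schema mismatch"):
            results.score_vector(np.zeros(3), codified=False)


class TestClassifyPatient:
    def test_any_positive_note_flags_patient(self, fitted_results):
        results, _, _ = fitted_results
        notes = [make_note("Lungs clear.", note_id=f"n{i}", date=f"2014-0{i+1}-01")
                 for i in range(3)]
        notes.append(make_note("f/u.", note_id="n9", date="2014-05-01",
                               icd_codes=["250.00"]))
        preds = results.predict_patients(notes, cutoff=0.6)
        row = preds.iloc[0]
        assert row["dm"] and str(row["first_positive_date"]) == "2014-05-01"

    def test_all_below_cutoff_not_dm(self, fitted_results):
        results, _, _ = fitted_results
        notes = [make_note("Lungs clear to auscultation.")]
        preds = results.predict_patients(notes, cutoff=0.99)
        assert not preds.iloc[0]["dm"]
        assert preds.iloc[0]["first_positive_date"] is None

    def test_earliest_positive_date_wins(self, fitted_results):
        results, _, _ = fitted_results
        notes = [make_note("a", note_id="n1", date="2014-03-01", icd_codes=["250.0"]),
                 make_note("b", note_id="n2", date="2014-01-01", icd_codes=["250.0"])]
        preds = results.predict_patients(notes, cutoff=0.5)
        assert str(preds.iloc[0]["first_positive_date"]) == "2014-01-01"

    def test_cutoff_monotonicity(self, fitted_results, small_corpus):
        results, notes, _ = fitted_results
        low = results.predict_patients(notes, cutoff=0.4)
        high = results.predict_patients(notes, cutoff=0.8)
        flagged_low = set(low.loc[low["dm"], "patient_id"])
        flagged_high = set(high.loc[high["dm"], "patient_id"])
        assert flagged_high <= flagged_low


class TestIterativeRefine:
    def test_oracle_confirms_none_is_fixed_point(self, small_corpus, kb):
        notes, _, _ = small_corpus
        config = TrainingConfig(seed=0, n_trees=50)
        res = DMCaseFinder(notes, kb=kb, config=config).fit(
            truth_oracle=lambda note: False)
        assert res.training_meta["iterations_run"] == 1
        assert res.training_meta["moved_per_iteration"] == [0]

    def test_max_iterations_respected(self, small_corpus, kb):
        notes, truth, _ = small_corpus
        config = TrainingConfig(seed=0, n_trees=50, max_iterations=1)
        res = DMCaseFinder(notes, kb=kb, config=config).fit(
            truth_oracle=truth_oracle_from(truth))
        assert res.training_meta["iterations_run"] == 1

    def test_contaminated_negatives_are_recovered(self, kb):
        # uncodified true-DM notes land in the negative sample; refinement
        # must move at least one and not hurt held-out performance
        config = GeneratorConfig(n_patients=600, codified_fraction=0.5, seed=11)
        notes, truth = generate_corpus(config)
        tc = TrainingConfig(seed=1, n_trees=100)
        plain = DMCaseFinder(notes, kb=kb, config=tc).fit()
        refined = DMCaseFinder(notes, kb=kb, config=tc).fit(
            truth_oracle=truth_oracle_from(truth))
        assert sum(refined.training_meta["moved_per_iteration"]) >= 1
        assert refined.training_meta["n_positive_notes"] > \
            plain.training_meta["n_positive_notes"]

    def test_oracle_failure_reports_partial_state(self, small_corpus, kb):
        notes, _, _ = small_corpus

        def broken(note):
            raise OSError("curator unavailable")

        config = TrainingConfig(seed=0, n_trees=50)
        model = DMCaseFinder(notes, kb=kb, config=config)
        try:
            model.fit(truth_oracle=broken)
        except RuntimeError as exc:
            assert "curator unavailable" in str(exc)
            assert "iterations" in str(exc)
        # a corpus where nothing is flagged never consults the oracle: fine


class TestFeatureImportance:
    def _one_signal(self, seed=0, n=400, p=6):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(n, p)).astype(float)
        y = X[:, 2].astype(int)  # only column 2 is informative
        flip = rng.random(n) < 0.05
        y[flip] = 1 - y[flip]
        return X, y

    def test_generating_feature_ranks_first(self):
        X, y = self._one_signal()
        forest = _fit_forest(X, y, TrainingConfig(seed=0, n_trees=100))
        imp = feature_importance(forest, X, y, seed=0)
        assert imp.iloc[0]["feature"] == "2"

    def test_noise_features_near_zero_drop(self):
        X, y = self._one_signal()
        forest = _fit_forest(X, y, TrainingConfig(seed=0, n_trees=100))
        imp = feature_importance(forest, X, y, seed=0).set_index("feature")
        signal = imp.loc["2", "mean_decrease_accuracy_scaled"]
        noise = imp.drop("2")["mean_decrease_accuracy_scaled"].abs().max()
        assert signal > 5 * max(noise, 1e-9)

    def test_seeded_repeat_identical(self):
        X, y = self._one_signal()
        forest = _fit_forest(X, y, TrainingConfig(seed=0, n_trees=100))
        a = feature_importance(forest, X, y, seed=3)
        b = feature_importance(forest, X, y, seed=3)
        assert a.equals(b)


class TestRobustness:
    def test_one_percent_label_noise_stable_auc(self, kb):
        """Mislabeling ~1% of training negatives barely moves held-out AUC."""
        config = GeneratorConfig(n_patients=900, seed=21)
        notes, truth = generate_corpus(config)
        facs = sorted({n.facility_id for n in notes})
        train = [n for n in notes if n.facility_id in facs[:4]]
        test = [n for n in notes if n.facility_id not in facs[:4]]
        tc = TrainingConfig(seed=2, n_trees=100)

        res_clean = DMCaseFinder(train, kb=kb, config=tc).fit()

        # flip 1% of training negatives to positive by faking a DM code
        rng = np.random.default_rng(0)
        neg_ids = res_clean.training_meta["negative_note_ids"]
        n_flip = max(1, len(neg_ids) // 100)
        flip = set(rng.choice(neg_ids, size=n_flip, replace=False))
        noisy = [n if n.note_id not in flip else
                 type(n)(**{**n.to_record(), "icd_codes": ("250.00",)})
                 for n in train]
        res_noisy = DMCaseFinder(noisy, kb=kb, config=tc).fit()

        truth_vec = np.array([truth[p]["dm_status"] for p in
                              sorted({n.patient_id for n in test})])

        def heldout_auc(res):
            preds = res.predict_patients(test, cutoff=0.5)
            return roc_curve(preds.sort_values("patient_id")["max_score"],
                             truth_vec).auc

        assert abs(heldout_auc(res_clean) - heldout_auc(res_noisy)) < 0.02

    def test_summary_renders(self, fitted_results):
        results, _, _ = fitted_results
        text = results.summary()
        assert "features screened" in text and "trees" in text

    def test_save_load_round_trip(self, fitted_results, tmp_path):
        results, notes, _ = fitted_results
        path = tmp_path / "model.joblib"
        results.save(path)
        from dmfind import CaseFindingResults
        loaded = CaseFindingResults.load(path)
        a = results.score_notes(notes[:20])["score"].to_numpy()
        b = loaded.score_notes(notes[:20])["score"].to_numpy()
        assert np.array_equal(a, b)
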