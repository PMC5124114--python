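import datetime as dt

import numpy as np
import pytest

from dmfind import (ConfusionMatrix, case_yield, mds_diagnostic, metrics,
                    temporal_compare, wilson_ci)


class TestMetrics:
    def test_retrospective_blind_test_counts(self):
        m = metrics(ConfusionMatrix(tp=62, fp=3, fn=38, tn=497))
        assert m.rounded() == {"ppv": .954, "npv": .929, "sensitivity": .62,
                               "specificity": .994, "auc": None}

    def test_prospective_gold_standard_counts(self):
        m = metrics(ConfusionMatrix(tp=136, fp=15, fn=64, tn=985))
        r = m.rounded()
        assert (r["ppv"], r["sensitivity"]) == (.901, .68)
        assert (r["specificity"], r["npv"]) == (.985, .939)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert m.ppv is None
        assert m.npv == pytest.approx(0.7)

    def test_two_path_consistency(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 500).astype(bool)
        pred = rng.integers(0, 2, 500).astype(bool)
        cm = ConfusionMatrix.from_predictions(truth, pred)
        # independent tally
        tp = int(np.sum(truth & pred)); fp = int(np.sum(~truth & pred))
        fn = int(np.sum(truth & ~pred)); tn = int(np.sum(~truth & ~pred))
        assert metrics(cm).rounded() == metrics(
            ConfusionMatrix(tp, fp, fn, tn)).rounded()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 5)


class TestYield:
    def test_statewide_yield_arithmetic(self):
        assert case_yield(64168, 5756) == 8.97

    @pytest.mark.parametrize("cod,add,expected", [(100, 0, 0.0), (200, 50, 25.0)])
    def test_simple_cases(self, cod, add, expected):
        assert case_yield(cod, add) == expected

    def test_zero_codified_errors(self):
        with pytest.raises(ValueError):
            case_yield(0, 5)


class TestWilson:
    def test_blind_test_ppv_interval(self):
        lo, hi = wilson_ci(62, 65)
        assert lo == pytest.approx(0.873, abs=0.01)
        assert hi == pytest.approx(0.984, abs=0.01)

    def test_prospective_ppv_inside_blind_interval(self):
        lo, hi = wilson_ci(62, 65)
        assert lo <= 136 / 151 <= hi


class TestTemporal:
    def test_lead_time_arithmetic(self):
        t = temporal_compare({"p": dt.date(2014, 1, 1)},
                             {"p": dt.date(2014, 2, 18)})
        assert t.n_nlp_earlier == 1
        assert t.mean_lead_days == pytest.approx(48.0)

    def test_same_day_not_counted_earlier(self):
        t = temporal_compare({"p": dt.date(2014, 1, 1)},
                             {"p": dt.date(2014, 1, 1)})
        assert t.n_nlp_earlier == 0 and t.n_same_day == 1

    def test_icd_earlier_excluded_from_lead(self):
        t = temporal_compare({"p": dt.date(2014, 3, 1)},
                             {"p": dt.date(2014, 1, 1)})
        assert t.n_nlp_earlier == 0 and t.n_icd_earlier == 1
        assert t.mean_lead_days is None

    def test_missing_dates_excluded(self):
        t = temporal_compare({"a": dt.date(2014, 1, 1), "b": dt.date(2014, 1, 1)},
                             {"a": None})
        assert t.n_both == 0

    def test_totals_conserved(self):
        rng = np.random.default_rng(3)
        base = dt.date(2014, 1, 1)
        nlp = {f"p{i}": base + dt.timedelta(days=int(rng.integers(0, 300)))
               for i in range(200)}
        icd = {f"p{i}": base + dt.timedelta(days=int(rng.integers(0, 300)))
               for i in range(200)}
        t = temporal_compare(nlp, icd)
        assert t.n_both == t.n_nlp_earlier + t.n_same_day + t.n_icd_earlier
        assert t.n_lead_ge_90_days <= t.n_nlp_earlier

    def test_ninety_day_threshold(self):
        nlp = {"a": dt.date(2014, 1, 1), "b": dt.date(2014, 1, 1)}
        icd = {"a": dt.date(2014, 4, 1),   # 90 days
               "b": dt.date(2014, 3, 31)}  # 89 days
        t = temporal_compare(nlp, icd)
        assert t.n_lead_ge_90_days == 1


class TestMDS:
    def _two_class_vectors(self, rng, n=60, p=20):
        # disjoint feature supports -> well-separated classes
        X = np.zeros((n, p))
        half = n // 2
        X[:half, :p // 2] = rng.integers(0, 2, (half, p // 2))
        X[half:, p // 2:] = rng.integers(0, 2, (n - half, p // 2))
        X[:half, 0] = 1  # guarantee non-empty rows
        X[half:, -1] = 1
        y = np.array([1] * half + [0] * (n - half))
        return X, y

    def test_separated_classes_separate_in_plane(self):
        rng = np.random.default_rng(0)
        X, y = self._two_class_vectors(rng)
        coords, labels, _ = mds_diagnostic(X, y, n_points=60, seed=0)
        c1 = coords[labels == 1].mean(axis=0)
        c0 = coords[labels == 0].mean(axis=0)
        between = np.linalg.norm(c1 - c0)
        within = np.mean([np.linalg.norm(coords[labels == k]
                                         - coords[labels == k].mean(axis=0), axis=1).mean()
                          for k in (0, 1)])
        assert between > within

    def test_duplicated_points_coincide(self):
        X = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0], [1, 1, 0]], dtype=float)
        coords, _, _ = mds_diagnostic(X, [1, 1, 0, 0], n_points=4, seed=0)
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_seeded_sampling_deterministic(self):
        rng = np.random.default_rng(1)
        X, y = self._two_class_vectors(rng, n=80)
        a = mds_diagnostic(X, y, n_points=40, seed=5)
        b = mds_diagnostic(X, y, n_points=40, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[2], b[2])

    def test_degenerate_identical_vectors_warn(self):
        X = np.ones((5, 3))
        with pytest.warns(UserWarning, match="identical"):
            coords, _, _ = mds_diagnostic(X, [1, 0, 1, 0, 1], n_points=5, seed=0)
        assert np.all(coords == 0.0)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            mds_diagnostic(np.ones((2, 2)), [0, 1], n_points=2, seed=0)
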