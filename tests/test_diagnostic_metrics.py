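import numpy as np
import pytest
from sklearn.metrics import multilabel_confusion_matrix

from mcma.diagnostic_metrics import (ConfusionCounts, DiagMetrics,
                                     RuleBasedHrClassifier, class_metrics,
                                     confusion_from_labels,
                                     evaluate_diagnostic, gain,
                                     labels_to_matrix, macro_average,
                                     metrics_from_counts)
from mcma.synthetic_data import SynthConfig, simulate_record


class TestClassMetrics:
    def test_first_degree_block_worked_example(self):
        # 28 positives of 827 records, 21 found, 3 false alarms
        pre, rec, spe, f1 = class_metrics(ConfusionCounts(21, 3, 7, 796))
        assert round(pre, 4) == 0.8750
        assert round(rec, 4) == 0.7500
        assert round(spe, 4) == 0.9962
        assert round(f1, 4) == 0.8077

    def test_perfect_classifier(self):
        assert class_metrics(ConfusionCounts(10, 0, 0, 90)) == (1, 1, 1, 1)

    def test_never_predicted_class_scores_zero(self):
        pre, rec, spe, f1 = class_metrics(ConfusionCounts(0, 0, 5, 95))
        assert (pre, rec, f1) == (0.0, 0.0, 0.0)
        assert spe == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            pre, rec, _, f1 = class_metrics(ConfusionCounts(tp, fp, fn, tn))
            assert np.isclose(f1, 2 * pre * rec / (pre + rec))


class TestConfusionFromLabels:
    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 2, size=(30, 4))
        counts = confusion_from_labels(y, y)
        for j in range(4):
            assert counts[j].fp == 0 and counts[j].fn == 0
            assert counts[j].tp == int(y[:, j].sum())

    def test_all_zero_prediction(self, rng):
        y = rng.integers(0, 2, size=(30, 3))
        counts = confusion_from_labels(y, np.zeros_like(y))
        for j in range(3):
            assert counts[j].tp == 0 and counts[j].fp == 0
            assert counts[j].fn == int(y[:, j].sum())

    def test_matches_brute_force_and_sklearn(self, rng):
        y_true = rng.integers(0, 2, size=(50, 5))
        y_pred = rng.integers(0, 2, size=(50, 5))
        counts = confusion_from_labels(y_true, y_pred)
        sk = multilabel_confusion_matrix(y_true, y_pred)
        for j in range(5):
            # brute-force per-record tally
            tp = sum(int(t and p) for t, p in zip(y_true[:, j], y_pred[:, j]))
            fp = sum(int(not t and p) for t, p in zip(y_true[:, j], y_pred[:, j]))
            fn = sum(int(t and not p) for t, p in zip(y_true[:, j], y_pred[:, j]))
            c = counts[j]
            assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
            assert c.total == 50
            # sklearn layout: [[tn, fp], [fn, tp]]
            assert (c.tn, c.fp, c.fn, c.tp) == tuple(sk[j].ravel())

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_labels(np.array([[2]]), np.array([[1]]))

    def test_order_invariance(self, rng):
        y_true = rng.integers(0, 2, size=(40, 3))
        y_pred = rng.integers(0, 2, size=(40, 3))
        perm = rng.permutation(40)
        a = confusion_from_labels(y_true, y_pred)
        b = confusion_from_labels(y_true[perm], y_pred[perm])
        for j in range(3):
            assert a[j] == b[j]


class TestMacroAndGain:
    def test_macro_of_identical_classes(self):
        d = DiagMetrics(("a", "b", "c"), {k: (0.5, 0.6, 0.9, 0.55)
                                          for k in "abc"})
        assert macro_average(d) == (0.5, 0.6, 0.9, 0.55)

    def test_single_class_macro(self):
        d = DiagMetrics(("x",), {"x": (0.1, 0.2, 0.3, 0.4)})
        assert macro_average(d) == (0.1, 0.2, 0.3, 0.4)

    def test_zero_gain_for_identical_inputs(self):
        d = DiagMetrics(("a",), {"a": (0.5, 0.5, 0.5, 0.5)})
        assert gain(d, d) == (0.0, 0.0, 0.0, 0.0)

    def test_gain_is_elementwise_difference(self):
        g = DiagMetrics(("a",), {"a": (0.8, 0.9, 1.0, 0.85)})
        b = DiagMetrics(("a",), {"a": (0.3, 0.1, 0.9, 0.15)})
        np.testing.assert_allclose(gain(g, b), (0.5, 0.8, 0.1, 0.7))

    def test_class_mismatch_rejected(self):
        g = DiagMetrics(("a",), {"a": (1, 1, 1, 1)})
        b = DiagMetrics(("b",), {"b": (0, 0, 0, 0)})
        with pytest.raises(ValueError):
            gain(g, b)


def _rate_records(rates, noise=0.0, seed0=100):
    records, labels = [], []
    for k, hr in enumerate(rates):
        rec = simulate_record(SynthConfig(hr_bpm=hr, noise_sd=noise,
                                          hr_jitter=0.01, seed=seed0 + k))
        records.append(rec.record)
        labels.append(rec.labels)
    return records, labels


class TestRuleBasedClassifier:
    def test_rates_classified_on_clean_data(self):
        records, labels = _rate_records([45, 50, 55, 80, 85, 105, 110, 120])
        clf = RuleBasedHrClassifier()
        y_true = labels_to_matrix(labels, clf.classes)
        y_pred = np.vstack([clf(r.samples) for r in records])
        counts = confusion_from_labels(y_true, y_pred, clf.classes)
        d = metrics_from_counts(counts)
        for cls in clf.classes:
            assert d.per_class[cls][1] >= 0.9  # recall on clean data

    def test_blind_without_lead_ii(self):
        records, _ = _rate_records([45, 110])
        clf = RuleBasedHrClassifier()
        blank = np.zeros_like(records[0].samples)
        blank[0] = records[0].samples[0]  # only lead I present
        assert np.all(clf(blank) == 0)


class TestEvaluateDiagnostic:
    def test_oracle_classifier_scores_one_everywhere(self):
        # class encoded as a constant offset on every lead: visible in any
        # configuration, so reference, baseline and generated all score 1.0
        rng = np.random.default_rng(5)
        records, y_true = [], []
        for _ in range(12):
            cls = int(rng.integers(0, 2))
            offset = 5.0 if cls else -5.0
            records.append(offset + 0.1 * rng.normal(size=(12, 2048)))
            y_true.append([cls, 1 - cls])

        def oracle(ecg12):
            ecg12 = np.asarray(ecg12)
            j = int(np.argmax(np.abs(ecg12.mean(axis=1))))
            c = int(ecg12[j].mean() > 0)
            return np.array([c, 1 - c])

        res = evaluate_diagnostic(
            oracle, lambda x, i: records[_find(records, x, i)],
            records, np.array(y_true), input_leads=[0, 5],
            classes=("pos", "neg"))
        assert res["reference"].macro == (1.0, 1.0, 1.0, 1.0)
        for entry in res["per_lead"].values():
            assert entry["generated"].macro == (1.0, 1.0, 1.0, 1.0)
            assert entry["baseline"].macro == (1.0, 1.0, 1.0, 1.0)
            assert entry["gain"] == (0.0, 0.0, 0.0, 0.0)

    def test_identity_generator_with_rate_classifier(self):
        records, labels = _rate_records([45, 50, 80, 85, 105, 115])
        clf = RuleBasedHrClassifier()
        y_true = labels_to_matrix(labels, clf.classes)
        lookup = {}
        for r in records:
            for i in range(12):
                lookup[(r.samples[i].tobytes(), i)] = r.samples
        res = evaluate_diagnostic(clf, lambda x, i: lookup[(x.tobytes(), i)],
                                  records, y_true, input_leads=[0, 1])
        # identity generation restores lead II -> matches the reference
        for entry in res["per_lead"].values():
            assert entry["generated"].macro == res["reference"].macro
        # zero-padded lead I hides lead II from the classifier: recall drops
        rec_baseline_I = res["per_lead"][0]["baseline"].macro[1]
        rec_reference = res["reference"].macro[1]
        assert rec_baseline_I < rec_reference
        # with lead II as the input, the baseline still sees lead II
        assert res["per_lead"][1]["baseline"].macro[1] == rec_reference

    def test_report_frame_has_gain_rows(self):
        records, labels = _rate_records([45, 110])
        clf = RuleBasedHrClassifier()
        y_true = labels_to_matrix(labels, clf.classes)
        res = evaluate_diagnostic(clf, lambda x, i: np.tile(x, (12, 1)),
                                  records, y_true, input_leads=[1])
        from mcma.diagnostic_metrics import report_to_frame

        df = report_to_frame(res)
        assert "GAIN+II" in df.index
        assert list(df.columns) == ["Pre", "Rec", "Spe", "F1"]


def _find(records, x, i):
    for k, r in enumerate(records):
        if np.array_equal(r[i], x):
            return k
    raise AssertionError("window not found")
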