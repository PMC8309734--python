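import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score

import painfeat as pf
from painfeat.evaluate import binary_macro_f1, comparison_table


class TestMetrics:
    def test_worked_confusion_example(self):
        m = pf.metrics(pf.ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
        assert m["accuracy"] == pytest.approx(0.625)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_prediction(self):
        m = pf.metrics(pf.ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_denominators_yield_zero(self):
        m = pf.metrics(pf.ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m["precision"] == m["recall"] == m["f1"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pf.metrics(pf.ConfusionCounts(0, 0, 0, 0))

    def test_macro_f1_examples(self):
        assert pf.macro_f1([0.8, 0.4]) == pytest.approx(0.6)
        assert pf.macro_f1([0.7]) == pytest.approx(0.7)
        with pytest.raises(ValueError):
            pf.macro_f1([])

    def test_metrics_agree_with_brute_force_oracle(self):
        """Accuracy/precision/recall/F1/macro-F1 vs. an independent pairwise
        recount (and sklearn's macro F1) over many random prediction sets."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 40)
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            counts = pf.confusion_from_predictions(y_true, y_pred)
            # brute-force recount, one pair at a time
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
            tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == \
                (tp, fp, tn, fn)
            m = pf.metrics(counts)
            assert m["accuracy"] == pytest.approx((tp + tn) / n)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert m["precision"] == pytest.approx(prec)
            assert m["recall"] == pytest.approx(rec)
            expected_f1 = (2 * prec * rec / (prec + rec)) if prec + rec else 0.0
            assert m["f1"] == pytest.approx(expected_f1)
            assert binary_macro_f1(y_true, y_pred) == pytest.approx(
                f1_score(y_true, y_pred, average="macro",
                         labels=[0, 1], zero_division=0))


def feature_frame(n_subjects=4, per_level=4, levels=("B", "P1", "P4"),
                  seed=0, signal=0.0):
    """Random feature rows; `signal` shifts the painful classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for level in levels:
            shift = signal * (level != "B")
            for _ in range(per_level):
                rows.append({"subject_id": f"S{s}", "temp_label": level,
                             "covas_label": "C4" if level == "P4" else "C0",
                             "covas_sum": 0.0,
                             **{f"f{i}": rng.normal() + shift
                                for i in range(5)}})
    return pd.DataFrame(rows)


class TestBinaryTask:
    def test_filter_semantics(self):
        df = feature_frame()
        x, y, subs = pf.make_binary_task(df, "B", "P4")
        assert set(np.unique(y)) == {0, 1}
        assert x.shape[1] == 5
        assert np.sum(y == 0) == np.sum(y == 1)

    def test_covas_label_source(self):
        df = feature_frame()
        x, y, _ = pf.make_binary_task(df, "C0", "C4", label_source="covas")
        # C0 covers both B and P1 rows; balancing equalises the classes
        assert np.sum(y == 0) == np.sum(y == 1) > 0

    def test_unknown_level_rejected(self):
        with pytest.raises(pf.EmptyTaskError):
            pf.make_binary_task(feature_frame(), "B", "P9")

    def test_unbalanced_mode_keeps_all_rows(self):
        df = feature_frame(levels=("B", "B2", "P4"))
        df.loc[df.temp_label == "B2", "temp_label"] = "B"
        x, y, _ = pf.make_binary_task(df, "B", "P4", balance=False)
        assert np.sum(y == 0) == 2 * np.sum(y == 1)


class TestLoso:
    def test_each_subject_tested_once_per_run(self):
        df = feature_frame(signal=3.0)
        x, y, subs = pf.make_binary_task(df, "B", "P4")
        res = pf.loso_evaluate(x, y, subs, n_runs=1, n_trees=10)
        assert sorted(res.table["subject"]) == sorted(np.unique(subs))
        assert len(res.table) == len(np.unique(subs))

    def test_strong_signal_recovers_high_accuracy(self):
        df = feature_frame(n_subjects=6, signal=3.0)
        x, y, subs = pf.make_binary_task(df, "B", "P4")
        res = pf.loso_evaluate(x, y, subs, n_runs=2, n_trees=50, base_seed=1)
        assert res.aggregate()["accuracy_mean"] > 0.9

    def test_shuffled_labels_sit_at_chance(self):
        """Permuting labels within subject must push LOSO accuracy to the
        0.5 chance floor (within sampling noise)."""
        df = feature_frame(n_subjects=10, per_level=8, levels=("B", "P4"),
                           signal=3.0, seed=5)
        x, y, subs = pf.make_binary_task(df, "B", "P4")
        rng = np.random.default_rng(11)
        y_shuffled = y.copy()
        for s in np.unique(subs):
            m = subs == s
            y_shuffled[m] = rng.permutation(y_shuffled[m])
        res = pf.loso_evaluate(x, y_shuffled, subs, n_runs=2, n_trees=50,
                               base_seed=2)
        assert 0.4 <= res.aggregate()["accuracy_mean"] <= 0.6

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            pf.loso_evaluate(np.zeros((4, 2)), np.array([0, 1, 0, 1]),
                             np.array(["A"] * 4))

    def test_aggregation_is_mean_of_per_run_sd(self):
        table = pd.DataFrame({
            "run": [1, 1, 2, 2], "subject": ["A", "B", "A", "B"],
            "accuracy": [1.0, 0.0, 0.5, 0.5],
            "macro_f1": [1.0, 0.0, 0.5, 0.5]})
        res = pf.CVResult(task="t", method="m", table=table)
        agg = res.aggregate()
        assert agg["accuracy_mean"] == pytest.approx(0.5)
        # run 1 SD (ddof=1) = 0.7071, run 2 SD = 0 -> mean 0.3536
        assert agg["accuracy_sd"] == pytest.approx(np.std([1.0, 0.0], ddof=1) / 2)


class TestPairedTest:
    def test_identical_methods_not_significant(self):
        a = [0.8, 0.7, 0.9]
        out = pf.paired_method_test(a, a)
        assert not out["significant"] and out["direction"] == 0

    def test_closed_form_t_statistic(self):
        out = pf.paired_method_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert out["t"] == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))

    def test_antisymmetry(self):
        a, b = [0.9, 0.85, 0.95, 0.8], [0.7, 0.75, 0.8, 0.72]
        ab = pf.paired_method_test(a, b)
        ba = pf.paired_method_test(b, a)
        assert ab["p"] == pytest.approx(ba["p"])
        assert ab["direction"] == -ba["direction"]

    def test_constant_nonzero_difference_is_significant(self):
        out = pf.paired_method_test([0.9, 0.9], [0.8, 0.8])
        assert out["significant"] and out["p"] == 0.0

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            pf.paired_method_test([0.1, 0.2], [0.1])


def test_comparison_table_renders_percentages():
    df = feature_frame(n_subjects=4, signal=3.0)
    x, y, subs = pf.make_binary_task(df, "B", "P4")
    results = {}
    for method, seed in (("good", 0), ("also_good", 1)):
        results[("B_vs_P4", method)] = pf.loso_evaluate(
            x, y, subs, n_runs=1, n_trees=10, base_seed=seed, method=method,
            task="B_vs_P4")
    table = comparison_table(results)
    assert table.shape == (2, 1)
    assert "±" in table.iloc[0, 0]
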