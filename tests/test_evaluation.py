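"""Metrics: confusion, per-class and aggregate scores, ROC/AUC, folds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mriaug import (ClassRegistry, DomainError, ImageRecord, confusion,
                    aggregate, cross_validate, f1_from_precision_recall,
                    per_class_metrics, roc_auc, run_ablation, summarize_folds)
from mriaug.evaluation import (ConfusionMatrix, FoldSummary, full_report,
                               render_ablation_table, round_half_up)

REG3 = ClassRegistry(("glioma", "meningioma", "pituitary"))
REG4 = ClassRegistry()


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion([0, 0, 0, 1, 1], [0, 0, 0, 1, 1], REG3)
        assert np.array_equal(np.diag(cm.counts), [3, 2, 0])
        assert cm.counts.sum() == 5 == np.trace(cm.counts)

    def test_degenerate_predictor_fills_one_column(self):
        cm = confusion([0, 1, 2, 1], [0, 0, 0, 0], REG3)
        assert np.array_equal(cm.counts[:, 0], cm.counts.sum(axis=1))

    def test_hand_tally(self):
        cm = confusion([0, 0, 1, 1, 2], [0, 1, 1, 1, 0], REG3)
        assert np.array_equal(cm.counts,
                              [[1, 1, 0], [0, 2, 0], [1, 0, 0]])

    def test_length_mismatch_and_bad_labels(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], REG3)
        with pytest.raises(DomainError):
            confusion([0, 3], [0, 0], REG3)

    def test_row_sums_are_supports(self):
        cm = confusion([0, 1, 1, 2, 2, 2], [1, 1, 1, 0, 2, 2], REG3)
        assert np.array_equal(cm.supports, [1, 2, 3])


class TestPerClassMetrics:
    def test_published_f1_arithmetic(self):
        # measured three-class study: glioma P=88.7 R=99.3 -> F1 93.7,
        # pituitary P=100.0 R=87.1 -> F1 93.1 at one decimal
        assert round_half_up(f1_from_precision_recall(88.7, 99.3), 1) == 93.7
        assert round_half_up(f1_from_precision_recall(100.0, 87.1), 1) == 93.1

    def test_diagonal_matrix_scores_100(self):
        cm = ConfusionMatrix(np.diag([5, 3, 2]), REG3)
        rep = per_class_metrics(cm)
        assert np.allclose(rep.precision, 100.0)
        assert np.allclose(rep.recall, 100.0)
        assert np.allclose(rep.f1, 100.0)
        assert not rep.zero_denominator.any()

    def test_zero_denominator_convention(self):
        # class 2 never predicted and never true -> flagged, metric 0
        cm = ConfusionMatrix(np.array([[2, 0, 0], [0, 2, 0], [0, 0, 0]]),
                             REG3)
        rep = per_class_metrics(cm)
        assert rep.zero_denominator[2]
        assert rep.precision[2] == rep.recall[2] == rep.f1[2] == 0.0

    def test_aggregates_macro_and_weighted(self):
        # macro precision of (88.7, 98.5, 100.0) = 95.7(3)
        cm = ConfusionMatrix(np.diag([1, 1, 1]), REG3)
        rep = per_class_metrics(cm)
        object.__setattr__(rep, "precision", np.array([88.7, 98.5, 100.0]))
        agg = aggregate(rep, cm)
        assert round_half_up(agg.macro_precision, 1) == 95.7
        # weighted precision of (99.3, 98.4, 99.0) @ supports (300, 306, 300)
        cm2 = ConfusionMatrix(np.diag([300, 306, 300]), REG3)
        rep2 = per_class_metrics(cm2)
        object.__setattr__(rep2, "precision", np.array([99.3, 98.4, 99.0]))
        agg2 = aggregate(rep2, cm2)
        assert round_half_up(agg2.weighted_precision, 1) == 98.9

    def test_single_class_macro_equals_weighted(self):
        cm = confusion([0, 0, 1], [0, 0, 1], REG3)
        rep = aggregate(per_class_metrics(cm), cm)
        # equal supports -> weighted equals macro
        cm_eq = ConfusionMatrix(np.diag([4, 4, 4]), REG3)
        rep_eq = aggregate(per_class_metrics(cm_eq), cm_eq)
        assert np.isclose(rep_eq.macro_f1, rep_eq.weighted_f1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=5, max_size=60))
    def test_micro_average_equals_accuracy(self, pairs):
        """Pooled (micro) precision = recall = accuracy for single-label
        multi-class data."""
        t = [a for a, _ in pairs]
        p = [b for _, b in pairs]
        cm = confusion(t, p, REG3)
        tp = np.trace(cm.counts)
        micro_p = tp / cm.counts.sum(axis=0).sum()
        micro_r = tp / cm.counts.sum(axis=1).sum()
        acc = tp / cm.total
        assert micro_p == micro_r == acc

    def test_report_rendering_and_json(self, tmp_path):
        cm = confusion([0, 1, 2, 2], [0, 1, 2, 1], REG3)
        rep = aggregate(per_class_metrics(cm, decimals=1), cm)
        table = rep.render_table()
        assert "Pre (%)" in table and "Weighted avg" in table
        rep.to_json(tmp_path / "m.json")
        import json
        loaded = json.loads((tmp_path / "m.json").read_text())
        assert loaded["accuracy"] == 75.0


class TestRocAuc:
    def test_one_hot_probabilities_are_perfect(self):
        y = [0, 1, 2, 0]
        probs = np.eye(3)[y]
        res = roc_auc(y, probs, REG3)
        assert np.allclose(res.auc, 1.0)
        assert np.isclose(res.micro_auc, 1.0)

    def test_label_independent_probabilities_are_chance(self):
        y = [0, 1, 2, 0, 1, 2]
        probs = np.tile([0.5, 0.3, 0.2], (6, 1))
        res = roc_auc(y, probs, REG3)
        assert np.allclose(res.auc, 0.5)

    def test_small_instance_enumerated(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        rest = (1.0 - scores) / 2
        probs = np.column_stack([scores, rest, rest])   # rows sum to 1
        # pair enumeration: AUC = #(pos > neg) / (P*N)
        y_sep = [0, 0, 1, 1]     # members (1,1,0,0): 4/4 pairs -> 1.0
        assert np.isclose(roc_auc(y_sep, probs, REG3).auc[0], 1.0)
        y_mix = [0, 1, 0, 1]     # members (1,0,1,0): 3/4 pairs -> 0.75
        assert np.isclose(roc_auc(y_mix, probs, REG3).auc[0], 0.75)
        y_bal = [0, 1, 1, 0]     # members (1,0,0,1): 2/4 pairs -> 0.5
        assert np.isclose(roc_auc(y_bal, probs, REG3).auc[0], 0.5)

    def test_absent_class_flagged_undefined(self):
        y = [0, 1, 0, 1]
        probs = np.tile([0.4, 0.4, 0.2], (4, 1))
        res = roc_auc(y, probs, REG3)
        assert res.undefined[2] and np.isnan(res.auc[2])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(6, 50))
    def test_trapezoidal_auc_equals_mann_whitney(self, seed, n):
        """AUC by threshold sweep equals the pairwise statistic
        (#(pos > neg) + 0.5 #ties) / (P*N), brute-forced."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, size=n)
        if len(np.unique(y)) < 3:
            y[:3] = [0, 1, 2]
        raw = rng.uniform(0.05, 1.0, size=(n, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        res = roc_auc(y, probs, REG3)
        for k in range(3):
            pos = probs[y == k, k]
            neg = probs[y != k, k]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            mw = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert np.isclose(res.auc[k], mw, atol=1e-12)

    def test_csv_export(self, tmp_path):
        y = [0, 1, 2, 0]
        res = roc_auc(y, np.eye(3)[y], REG3)
        res.to_csv(tmp_path / "roc.csv")
        header = (tmp_path / "roc.csv").read_text().splitlines()[0]
        assert header == "class,threshold,fpr,tpr"


class TestFoldSummaries:
    def test_published_fold_mean(self):
        mean, _ = summarize_folds([99.22, 98.56, 98.23])
        assert round_half_up(mean, 2) == 98.67

    def test_population_sd_convention(self):
        # population sd (divisor k) reproduces the printed 0.29 / 0.10
        _, sd_val = summarize_folds([98.53, 99.05, 99.21])
        _, sd_test = summarize_folds([99.08, 99.24, 99.31])
        assert round_half_up(sd_val, 2) == 0.29
        assert round_half_up(sd_test, 2) == 0.10

    def test_identical_folds_zero_sd(self):
        summary = FoldSummary((97.0, 97.0, 97.0), (98.0, 98.0, 98.0), k=3)
        assert summary.val_sd == 0.0 and summary.test_sd == 0.0

    def test_hand_sd(self):
        _, sd = summarize_folds([98.53, 99.05, 99.21])
        xbar = (98.53 + 99.05 + 99.21) / 3
        by_hand = np.sqrt(((98.53 - xbar) ** 2 + (99.05 - xbar) ** 2
                           + (99.21 - xbar) ** 2) / 3)
        assert np.isclose(sd, by_hand)


def _fake_records(n_per_class, with_test=True):
    out = []
    for cid, n in n_per_class.items():
        for i in range(n):
            split = "test" if (with_test and i < 2) else \
                ("val" if i < 4 else "train")
            out.append(ImageRecord(f"x{cid}_{i}.png", cid, f"c{cid}", split))
    return out


class _MajorityModel:
    """Stub: predicts the modal training class; lets CV run without IO."""

    def __init__(self, records):
        ids = [r.class_id for r in records if r.split == "train"]
        self.pick = int(np.bincount(ids).argmax())


class TestCrossValidate:
    def test_folds_and_summary_shape(self):
        records = _fake_records({0: 14, 1: 14, 2: 14})

        def train_fn(recs):
            return _MajorityModel(recs)

        def acc_fn(model, recs):
            if not recs:
                return 0.0
            return float(np.mean([r.class_id == model.pick for r in recs]))

        summary = cross_validate(records, train_fn, acc_fn, k=3, seed=0)
        assert summary.k == 3
        assert len(summary.val_accuracies) == 3
        assert summary.test_mean == pytest.approx(
            float(np.mean(summary.test_accuracies)))

    def test_class_smaller_than_k_rejected(self):
        records = _fake_records({0: 14, 1: 4})
        with pytest.raises(DomainError, match="c1"):
            cross_validate(records, lambda r: None, lambda m, r: 0.0, k=3)


class TestAblationHarness:
    def test_four_reports_on_identical_test_sets(self):
        records = _fake_records({0: 14, 1: 14, 2: 14})
        seen_tests = []

        def pipeline(recs, use_ae, use_cgan):
            return (use_ae, use_cgan)

        def evaluate(model, test_recs):
            seen_tests.append(tuple(r.path for r in test_recs))
            y = [r.class_id for r in test_recs]
            return full_report(y, np.eye(3)[y], REG3)

        reports = run_ablation(records, REG3, pipeline, evaluate)
        assert set(reports) == {"classifier", "classifier+cgan",
                                "ae+classifier", "full"}
        assert len(set(seen_tests)) == 1      # same test records everywhere
        table = render_ablation_table(reports)
        assert "classifier+cgan" in table

    def test_unknown_configuration_rejected(self):
        with pytest.raises(ValueError):
            run_ablation([], REG3, lambda *a: None, lambda *a: None,
                         configs=["classifier", "mystery"])
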