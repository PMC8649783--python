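"""Split protocol, metrics and cross-model statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from biofusion import evaluation as ev
from biofusion.imaging import ImageDataset


def _fake_windows(n_per_rep_per_class=5, n_reps=3, speeds=("slow", "fast")):
    """Index-only stand-in for a WindowSet: one trial per speed x class."""
    rep_index, trial_index, weight_class, speed = [], [], [], []
    t = 0
    for s in speeds:
        for c in range(3):
            for r in range(n_reps):
                for _ in range(n_per_rep_per_class):
                    rep_index.append(r)
                    trial_index.append(t)
                    weight_class.append(c)
                    speed.append(s)
            t += 1

    class _WS:
        pass

    ws = _WS()
    ws.rep_index = np.array(rep_index)
    ws.trial_index = np.array(trial_index)
    ws.weight_class = np.array(weight_class)
    ws.speed_label = np.array(speed)
    return ws


class _FixedPredictor:
    """Model stub that returns a preset label sequence."""

    def __init__(self, preds):
        self.preds = np.asarray(preds)

    def predict(self, images):
        assert len(images) == len(self.preds)
        return self.preds


def _dataset(labels, speeds=None, subject="S01"):
    labels = np.asarray(labels)
    n = len(labels)
    speeds = np.asarray(speeds if speeds is not None else ["slow"] * n)
    return ImageDataset(
        layout="grouped", subject_id=subject,
        images=np.zeros((n, 4, 4), np.float32), labels=labels,
        weight_label=labels.astype(float), speed_label=speeds,
        rep_index=np.full(n, 2), trial_index=np.zeros(n, int),
        row_order=("C3",),
    )


class TestSplit:
    def test_counts_for_balanced_holdout(self):
        ws = _fake_windows(n_per_rep_per_class=5)
        split = ev.split_windows(ws)
        # 2 speeds x 3 classes x 5 windows: reps 0-1 train, rep 2 split 50/50
        assert len(split.train) == 60
        assert len(split.val) == 15 and len(split.test) == 15
        for part in (split.val, split.test):
            cls, counts = np.unique(ws.weight_class[part], return_counts=True)
            assert cls.tolist() == [0, 1, 2] and counts.tolist() == [5, 5, 5]

    def test_odd_class_counts_differ_by_at_most_one(self):
        ws = _fake_windows(n_per_rep_per_class=7, speeds=("slow",))
        split = ev.split_windows(ws)
        for c in range(3):
            nv = np.sum(ws.weight_class[split.val] == c)
            nt = np.sum(ws.weight_class[split.test] == c)
            assert abs(int(nt) - int(nv)) <= 1
            assert nv + nt == 7

    def test_partition_is_exact(self):
        ws = _fake_windows()
        split = ev.split_windows(ws)
        merged = np.sort(np.concatenate([split.train, split.val, split.test]))
        np.testing.assert_array_equal(merged, np.arange(len(ws.rep_index)))

    def test_train_reps_only(self):
        ws = _fake_windows()
        split = ev.split_windows(ws)
        assert set(ws.rep_index[split.train]) == {0, 1}
        assert set(ws.rep_index[split.val]) == {2}
        assert set(ws.rep_index[split.test]) == {2}

    def test_deterministic_and_seed_sensitive(self):
        ws = _fake_windows()
        a = ev.split_windows(ws, ev.SplitSpec(shuffle_seed=1))
        b = ev.split_windows(ws, ev.SplitSpec(shuffle_seed=1))
        c = ev.split_windows(ws, ev.SplitSpec(shuffle_seed=2))
        np.testing.assert_array_equal(a.val, b.val)
        assert not np.array_equal(a.val, c.val)

    def test_missing_repetition_is_an_error(self):
        ws = _fake_windows()
        keep = ws.rep_index != 2
        ws.rep_index = ws.rep_index[keep]
        ws.trial_index = ws.trial_index[keep]
        ws.weight_class = ws.weight_class[keep]
        with pytest.raises(ValueError, match="missing repetition"):
            ev.split_windows(ws)


class TestMetrics:
    def test_worked_confusion_example(self):
        # true/pred chosen so the confusion matrix is
        # [[5,0,0],[0,3,2],[0,2,3]]: 11/15 correct
        y = [0] * 5 + [1] * 5 + [2] * 5
        p = [0] * 5 + [1, 1, 1, 2, 2] + [2, 2, 2, 1, 1]
        ds = _dataset(y)
        rep = ev.evaluate(_FixedPredictor(p), ds, "demo")
        assert rep.accuracy_pct == pytest.approx(100 * 11 / 15)
        np.testing.assert_array_equal(
            rep.confusion, [[5, 0, 0], [0, 3, 2], [0, 2, 3]])
        assert rep.precision[0] == 1.0 and rep.recall[0] == 1.0
        assert rep.precision[2] == pytest.approx(3 / 5)
        assert rep.recall[2] == pytest.approx(3 / 5)
        assert rep.f_score[2] == pytest.approx(3 / 5)
        assert not rep.undefined_metrics

    def test_uniform_guessing_scores_chance(self):
        # block length divisible by 3, so the cyclic guesser hits each
        # class exactly one third of the time
        y = np.repeat([0, 1, 2], 39)
        p = np.tile([0, 1, 2], 39)
        rep = ev.evaluate(_FixedPredictor(p), _dataset(y))
        assert rep.accuracy_pct == pytest.approx(100 / 3, abs=1e-9)

    def test_absent_predicted_class_flags_undefined(self):
        y = [0, 1, 2, 0, 1, 2]
        p = [0, 0, 0, 0, 0, 0]  # never predicts classes 1, 2
        rep = ev.evaluate(_FixedPredictor(p), _dataset(y))
        assert rep.undefined_metrics
        assert rep.precision[1] == 0.0 and rep.f_score[2] == 0.0

    def test_speed_accuracy_weighted_mean_identity(self):
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        p = np.array([0, 1, 0, 0, 2, 2, 1, 1])
        speeds = np.array(["slow"] * 5 + ["fast"] * 3)
        rep = ev.evaluate(_FixedPredictor(p), _dataset(y, speeds))
        weighted = sum(rep.speed_accuracy_pct[s] * np.sum(speeds == s)
                       for s in ("slow", "fast")) / len(y)
        assert weighted == pytest.approx(rep.accuracy_pct)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ev.evaluate(_FixedPredictor([]), _dataset([]))


class TestAggregate:
    def _report(self, acc, cm, subject="S", name="m"):
        cm = np.asarray(cm, float)
        k = ev.classification_report
        prec = np.diag(cm) / np.maximum(cm.sum(axis=0), 1)
        return ev.SubjectReport(
            subject_id=subject, model_name=name, n_test=int(cm.sum()),
            accuracy_pct=acc, speed_accuracy_pct={}, confusion=cm,
            precision=prec, recall=prec, f_score=prec,
            macro_f_pct=100 * prec.mean())

    def test_mean_and_sample_sd(self):
        cm = np.eye(3) * 5
        agg = ev.aggregate([self._report(80.0, cm, "S1"),
                            self._report(90.0, cm, "S2")])
        assert agg.mean_accuracy_pct == pytest.approx(85.0)
        assert agg.sd_accuracy_pct == pytest.approx(np.sqrt(50), abs=1e-9)
        assert not agg.sd_undefined

    def test_single_subject_sd_flagged(self):
        agg = ev.aggregate([self._report(80.0, np.eye(3))])
        assert agg.sd_accuracy_pct == 0.0 and agg.sd_undefined

    def test_pooled_confusion_conserves_counts(self):
        a = [[5, 0, 0], [0, 3, 2], [0, 2, 3]]
        b = [[4, 1, 0], [1, 4, 0], [0, 0, 5]]
        agg = ev.aggregate([self._report(70.0, a, "S1"),
                            self._report(85.0, b, "S2")])
        np.testing.assert_array_equal(agg.pooled_confusion,
                                      np.asarray(a) + np.asarray(b))
        assert agg.pooled_confusion.sum() == 30

    def test_pooled_differs_from_macro_when_sizes_differ(self):
        # subject 1: 10 windows at 100%; subject 2: 30 windows at 50%
        a = np.eye(3) * np.array([4, 3, 3])
        b = np.array([[5, 5, 0], [0, 5, 5], [5, 0, 5]])
        agg = ev.aggregate([self._report(100.0, a, "S1"),
                            self._report(50.0, b, "S2")])
        pooled_acc = 100 * np.trace(agg.pooled_confusion) / 40
        assert pooled_acc == pytest.approx(62.5)
        assert agg.mean_accuracy_pct == pytest.approx(75.0)
        assert pooled_acc != agg.mean_accuracy_pct

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no subject"):
            ev.aggregate([])


class TestAnova:
    def _table(self, seed=0, n=8, k=3, effect=(0.0, 2.0, 5.0)):
        rng = np.random.default_rng(seed)
        base = rng.normal(70, 8, size=(n, 1))
        x = base + np.asarray(effect) + rng.normal(0, 3, size=(n, k))
        return pd.DataFrame(x, columns=[f"m{i}" for i in range(k)])

    def test_matches_pingouin_oracle(self):
        import pingouin

        table = self._table(seed=3)
        f, p, df1, df2, degen = ev.rm_anova(table)
        long = table.reset_index().melt(id_vars="index", var_name="model",
                                        value_name="acc")
        ref = pingouin.rm_anova(data=long, dv="acc", within="model",
                                subject="index")
        assert not degen
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)
        assert (df1, df2) == (int(ref["ddof1"].iloc[0]),
                              int(ref["ddof2"].iloc[0]))

    def test_textbook_two_condition_equals_paired_t(self):
        # with k=2, F equals the squared paired t statistic
        from scipy import stats as sps

        table = self._table(seed=5, k=2, effect=(0.0, 3.0))
        f, p, *_ = ev.rm_anova(table)
        t = sps.ttest_rel(table["m0"], table["m1"])
        assert f == pytest.approx(t.statistic ** 2, rel=1e-9)
        assert p == pytest.approx(t.pvalue, rel=1e-9)

    def test_identical_columns_degenerate(self):
        x = np.tile(np.array([[70.0], [80.0], [90.0]]), (1, 3))
        f, p, _, _, degen = ev.rm_anova(pd.DataFrame(x, columns=list("abc")))
        assert degen and f == 0.0 and p == 1.0

    def test_missing_cell_rejected(self):
        table = self._table()
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ev.rm_anova(table)


class TestCompareModels:
    def test_bonferroni_scaling_and_symmetry(self):
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(70, 5, (10, 3)),
                             columns=["a", "b", "c"])
        res = ev.compare_models(table)
        raw = float(sps.ttest_rel(table["a"], table["b"]).pvalue)
        assert res.pairwise_p.loc["a", "b"] == pytest.approx(
            min(raw * 3, 1.0))
        assert res.pairwise_p.loc["a", "b"] == res.pairwise_p.loc["b", "a"]
        assert (np.diag(res.pairwise_p) == 1.0).all()

    def test_large_effect_detected(self):
        rng = np.random.default_rng(11)
        base = rng.normal(60, 2, (12, 1))
        table = pd.DataFrame(
            np.concatenate([base, base + 20 + rng.normal(0, 1, (12, 1))],
                           axis=1), columns=["weak", "strong"])
        res = ev.compare_models(table)
        assert res.p_value < 0.001
        assert res.pairwise_p.loc["weak", "strong"] < 0.001

    def test_constant_nonzero_difference_flagged(self):
        table = pd.DataFrame({"a": [70.0, 80.0, 90.0],
                              "b": [75.0, 85.0, 95.0]})
        res = ev.compare_models(table)
        assert res.degenerate
        assert res.pairwise_p.loc["a", "b"] == 0.0
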