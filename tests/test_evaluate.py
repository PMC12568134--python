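import numpy as np
import pytest

from fallwin import (
    ConfusionCounts,
    ModelSpec,
    StreamConfig,
    SyntheticConfig,
    WindowScheme,
    binary_metrics,
    confusion,
    gen_continuous_recording,
    gen_event_dataset,
    macro_average_accuracy,
    make_folds,
    or_rule_sample_label,
    run_cv,
    streaming_evaluate,
)
from fallwin.balance import SYNTHETIC_SUBJECT, LabeledFeatures
from fallwin.errors import UsageError
from fallwin.evaluate import FALL, FoldPlan, audit_fold_plan, streaming_overlap_sweep


class TestConfusion:
    def test_direct_count(self):
        c = confusion(["F", "F", "A", "A"], ["F", "A", "F", "A"], positive="F")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion(["F", "A"], ["F", "A"], positive="F")
        assert c.fp == 0 and c.fn == 0

    def test_empty_input(self):
        c = confusion([], [], positive="F")
        assert c.total == 0

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            confusion(["F"], ["F", "A"], positive="F")


class TestBinaryMetrics:
    def test_worked_example(self):
        rep = binary_metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert rep.sensitivity == pytest.approx(0.900)
        assert rep.specificity == pytest.approx(0.800)
        assert rep.precision == pytest.approx(9 / 11)
        assert rep.f1 == pytest.approx(0.8571, abs=1e-4)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.maa == pytest.approx(0.85)

    def test_perfect_counts(self):
        rep = binary_metrics(ConfusionCounts(tp=5, tn=5))
        assert all(v == 1.0 for v in rep.as_dict().values())

    def test_zero_denominators_flagged(self):
        rep = binary_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=1))
        assert rep.precision == 0.0
        assert "precision" in rep.undefined and "f1" in rep.undefined

    def test_metric_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 30, size=4)))
            rep = binary_metrics(c)
            assert rep.accuracy * c.total == pytest.approx(c.tp + c.tn)
            assert rep.maa == pytest.approx((rep.sensitivity + rep.specificity) / 2)
            assert rep.f1 == pytest.approx(
                2 / (1 / rep.sensitivity + 1 / rep.precision)
            )

    def test_zero_total_rejected(self):
        with pytest.raises(UsageError):
            binary_metrics(ConfusionCounts())


class TestMacroAverageAccuracy:
    def test_mean_of_per_class_accuracies(self):
        y_true = ["a"] * 2 + ["b"] * 2 + ["c"] * 4
        y_pred = ["a", "a", "b", "a", "c", "c", "c", "b"]
        assert macro_average_accuracy(y_true, y_pred) == pytest.approx(0.75)

    def test_binary_equals_mean_sens_spec(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y_true = rng.choice(["FALL", "ADL"], size=60)
            y_pred = rng.choice(["FALL", "ADL"], size=60)
            if len(np.unique(y_true)) < 2:
                continue
            rep = binary_metrics(confusion(y_true, y_pred))
            assert macro_average_accuracy(y_true, y_pred) == pytest.approx(rep.maa)

    def test_matches_brute_force_on_four_classes(self):
        rng = np.random.default_rng(2)
        classes = ["w", "x", "y", "z"]
        y_true = rng.choice(classes, size=200)
        y_pred = rng.choice(classes, size=200)
        per_class = [
            sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
            / sum(1 for t in y_true if t == c)
            for c in classes
        ]
        assert macro_average_accuracy(y_true, y_pred, classes) == pytest.approx(
            float(np.mean(per_class))
        )

    def test_absent_class_rejected(self):
        with pytest.raises(UsageError):
            macro_average_accuracy(["a", "a"], ["a", "a"], classes=["a", "b"])


def toy_features(n=10, n_subjects=5, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledFeatures(
        rng.normal(size=(n, 3)),
        np.array(["FALL", "ADL"] * (n // 2)),
        np.array([f"S{i % n_subjects}" for i in range(n)], dtype=object),
    )


class TestFolds:
    def test_kfold_even_split(self):
        plan = make_folds(toy_features(10), "kfold", 5, seed=0)
        assert len(plan.folds) == 5
        assert all(len(test) == 2 for _, test in plan.folds)

    def test_loso_one_fold_per_subject(self):
        data = toy_features(12, n_subjects=3)
        plan = make_folds(data, "loso")
        assert len(plan.folds) == 3
        for train, test in plan.folds:
            subj = set(data.subject_ids[test])
            assert len(subj) == 1
            assert not subj & set(data.subject_ids[train])

    def test_same_seed_same_plan(self):
        a = make_folds(toy_features(20), "kfold", 4, seed=5)
        b = make_folds(toy_features(20), "kfold", 4, seed=5)
        for (_, ta), (_, tb) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(ta, tb)

    def test_audit_rejects_synthetic_rows_in_test(self):
        data = toy_features(10)
        subjects = data.subject_ids.copy()
        subjects[3] = SYNTHETIC_SUBJECT
        tainted = LabeledFeatures(data.matrix, data.labels, subjects)
        plan = make_folds(data, "kfold", 5, seed=0)
        with pytest.raises(UsageError, match="synthetic"):
            audit_fold_plan(tainted, plan)

    def test_audit_rejects_non_partition(self):
        data = toy_features(10)
        bad = FoldPlan("kfold", ((np.arange(5), np.arange(5, 9)),), seed=0)
        with pytest.raises(UsageError, match="partition"):
            audit_fold_plan(data, bad)


class TestRunCV:
    def test_loso_knn_recovers_falls(self, small_features):
        plan = make_folds(small_features, "loso")
        result = run_cv(small_features, plan, ModelSpec(kind="knn"), seed=0)
        assert result.pooled_metrics.sensitivity >= 0.9
        assert len(result.fold_reports) == 4

    def test_single_class_training_fold_skipped(self):
        rng = np.random.default_rng(3)
        data = LabeledFeatures(
            rng.normal(size=(8, 3)),
            np.array(["FALL", "FALL", "ADL", "ADL"] * 2),
            np.array([f"S{i}" for i in range(8)], dtype=object),
        )
        # fold 0 trains on a mixed set; fold 1 trains on FALL-only rows
        folds = (
            (np.array([4, 5, 6, 7]), np.array([0, 1, 2, 3])),
            (np.array([0, 1]), np.array([4, 5, 6, 7])),
        )
        plan = FoldPlan("kfold", folds, seed=0)
        with pytest.warns(UserWarning, match="skipped"):
            result = run_cv(data, plan, ModelSpec(kind="knn"),
                            use_smote=False, seed=0)
        assert result.skipped_folds == (1,)

    def test_kfold_beats_loso_under_strong_subject_effects(self):
        cfg = SyntheticConfig(seed=42, subject_effect_sd=0.4)
        data = gen_event_dataset(cfg).to_labeled_features()
        loso = run_cv(data, make_folds(data, "loso"), ModelSpec(kind="knn"),
                      seed=42)
        kfold = run_cv(data, make_folds(data, "kfold", 5, seed=42),
                       ModelSpec(kind="knn"), seed=42)
        assert kfold.mean["accuracy"] >= loso.mean["accuracy"]


class TestOrRule:
    def test_any_fall_window_flags_sample(self):
        assert or_rule_sample_label(["ADL", "ADL", "FALL"]) == "FALL"

    def test_all_adl(self):
        assert or_rule_sample_label(["ADL", "ADL"]) == "ADL"

    def test_singleton(self):
        assert or_rule_sample_label(["FALL"]) == "FALL"

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            or_rule_sample_label([])


@pytest.fixture(scope="module")
def recording():
    cfg = SyntheticConfig(seed=9)
    return gen_continuous_recording(cfg, duration_s=120, n_falls=2, seed=9)


class TestStreaming:
    def oracle(self, recording):
        def classify(w):
            ws, we = w.start_sample / recording.rate, w.end_time_s
            hit = any(ws < a.end_s and we > a.start_s
                      for a in recording.annotations)
            return FALL if hit else "ADL"
        return classify

    def test_oracle_detector_scores_perfectly(self, recording):
        r = streaming_evaluate(recording, self.oracle(recording),
                               WindowScheme(), StreamConfig(3.0, 0.5))
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_silent_detector(self, recording):
        r = streaming_evaluate(recording, lambda w: "ADL",
                               WindowScheme(), StreamConfig(3.0, 0.5))
        assert r.sensitivity == 0.0 and r.specificity == 1.0
        assert r.event_fn == 2 and r.alarms == ()

    def test_1200s_30pct_gives_571_decisions(self):
        cfg = SyntheticConfig(seed=10)
        rec = gen_continuous_recording(cfg, 1200, 1, seed=10)
        r = streaming_evaluate(rec, lambda w: "ADL", WindowScheme(),
                               StreamConfig(3.0, 0.3))
        assert len(r.window_decisions) == 571

    def test_alarms_stamped_at_window_ends(self, recording):
        cfg = StreamConfig(3.0, 0.3)
        r = streaming_evaluate(recording, self.oracle(recording),
                               WindowScheme(), cfg)
        hop, w = cfg.hop_s, cfg.window_s
        for alarm in r.alarms:
            t = (alarm - w) / hop
            assert t == pytest.approx(round(t), abs=1e-9)

    def test_decisions_are_causal(self, recording):
        """No decision may read samples past its own window end."""
        seen = []

        def probe(w):
            seen.append((w.start_sample + w.length_samples, w.end_time_s))
            return "ADL"

        streaming_evaluate(recording, probe, WindowScheme(),
                           StreamConfig(3.0, 0.5))
        for last_sample_exclusive, decision_time in seen:
            assert last_sample_exclusive <= decision_time * recording.rate + 1e-9

    def test_trained_detector_detects_falls_at_half_overlap(self, small_cfg,
                                                            small_features):
        """End-to-end pipeline: with a 1.5 s hop the OR rule sees every
        impact well-placed in some window, so falls are found."""
        from fallwin import balance_training_set, fit

        det = fit(balance_training_set(small_features, seed=11),
                  ModelSpec(kind="knn"), seed=11)
        tp = fn = tn = fp = 0
        for i in range(4):
            rec = gen_continuous_recording(small_cfg, 300, 1, seed=2000 + i)
            r = streaming_evaluate(rec, det, WindowScheme(),
                                   StreamConfig(3.0, 0.5))
            tp += r.event_tp
            fn += r.event_fn
            tn += r.window_tn
            fp += r.window_fp
        assert tp / (tp + fn) >= 0.75
        assert tn / (tn + fp) >= 0.95

    def test_overlap_sweep_covers_grid(self, recording):
        rows = streaming_overlap_sweep([recording], self.oracle(recording),
                                       WindowScheme())
        assert [r["overlap"] for r in rows] == [round(0.1 * i, 1)
                                                for i in range(1, 10)]
        assert all(r["sensitivity"] == 1.0 for r in rows)
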