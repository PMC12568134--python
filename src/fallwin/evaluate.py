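"""Metrics, cross-validation harnesses, and the streaming detection protocol.

Covers the detection metrics (accuracy, MAA, sensitivity, specificity,
precision, F1), k-fold / leave-one-subject-out fold construction with a
leakage audit, the per-sample OR aggregation rule, and causal streaming
evaluation over annotated continuous recordings: event-level sensitivity
(was each annotated fall alarmed?) alongside window-level specificity
(how many non-fall windows raised a false alarm?).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from fallwin.balance import SYNTHETIC_SUBJECT, LabeledFeatures, balance_training_set
from fallwin.classify import ModelSpec, TrainedDetector, fit, predict
from fallwin.errors import UsageError
from fallwin.features import extract_features
from fallwin.signal_core import TriaxialTrace
from fallwin.windowing import StreamConfig, Window, WindowScheme, slide_windows

logger = logging.getLogger(__name__)

FALL = "FALL"
ADL = "ADL"

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "maa")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies; positives are falls."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise UsageError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    """All detection metrics for one evaluation, as fractions in [0, 1].

    ``undefined`` lists metrics whose ratio had a zero denominator and was
    reported as 0 by convention (so sweeps over empty-positive folds do not
    crash).
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    maa: float
    counts: ConfusionCounts
    per_class_accuracy: dict = field(default_factory=dict)
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FoldPlan:
    """A list of (train_indices, test_indices) pairs partitioning the rows."""

    mode: Literal["kfold", "loso"]
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]
    seed: int


@dataclass(frozen=True)
class StreamingResult:
    """Outcome of streaming a detector over one continuous recording."""

    window_decisions: tuple[tuple[int, str, float], ...]  # (index, label, decision_s)
    alarms: tuple[float, ...]  # alarm timestamps (window ends), seconds
    event_tp: int
    event_fn: int
    window_tn: int
    window_fp: int

    @property
    def sensitivity(self) -> float:
        d = self.event_tp + self.event_fn
        return self.event_tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.window_tn + self.window_fp
        return self.window_tn / d if d else 0.0


def binarize_labels(data: LabeledFeatures, positive=FALL) -> LabeledFeatures:
    """Collapse every non-positive label (ADL subtypes) into the ADL class."""
    labels = np.where(data.labels == positive, positive, ADL)
    return LabeledFeatures(data.matrix, labels, data.subject_ids,
                           data.feature_names)


def confusion(y_true, y_pred, positive=FALL) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with ``positive`` as the fall class."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise UsageError(
            f"label lengths differ: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    tpos = y_true == positive
    ppos = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def binary_metrics(c: ConfusionCounts) -> MetricsReport:
    """All binary metrics from confusion counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), precision = TP/(TP+FP),
    F1 = 2*sens*prec/(sens+prec), MAA = (sensitivity+specificity)/2.
    A zero-denominator ratio is reported as 0 and flagged.
    """
    if c.total == 0:
        raise UsageError("cannot compute metrics from zero counts")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    if sens + prec == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * sens * prec / (sens + prec)
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        maa=(sens + spec) / 2.0,
        counts=c,
        per_class_accuracy={"positive": sens, "negative": spec},
        undefined=tuple(undefined),
    )


def macro_average_accuracy(y_true, y_pred, classes=None) -> float:
    """Unweighted mean of per-class accuracies (macro average accuracy).

    Each class contributes correct_a / total_a equally, so rare classes
    weigh as much as common ones. For binary labels this equals
    (sensitivity + specificity) / 2.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = np.unique(y_true)
    accs = []
    for cls in classes:
        mask = y_true == cls
        if not mask.any():
            raise UsageError(f"class {cls!r} has no true instances")
        accs.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(accs))


def make_folds(
    data: LabeledFeatures,
    mode: Literal["kfold", "loso"],
    k: int | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Build a cross-validation plan.

    ``kfold`` shuffles rows with the seed and splits them as evenly as
    possible into k folds. ``loso`` makes one fold per subject; each test
    fold holds exactly one subject's rows and that subject appears in no
    training fold.
    """
    n = data.n_rows
    all_idx = np.arange(n)
    if mode == "kfold":
        if k is None or not (2 <= k <= n):
            raise UsageError(f"kfold needs 2 <= k <= {n} rows, got k={k}")
        perm = np.random.default_rng(seed).permutation(n)
        tests = np.array_split(perm, k)
        folds = tuple(
            (np.setdiff1d(all_idx, t), np.sort(t)) for t in tests
        )
    elif mode == "loso":
        subjects = np.unique(data.subject_ids)
        if len(subjects) < 2:
            raise UsageError("LOSO needs >= 2 subjects")
        folds = tuple(
            (
                all_idx[data.subject_ids != s],
                all_idx[data.subject_ids == s],
            )
            for s in subjects
        )
    else:
        raise UsageError(f"unknown fold mode {mode!r}")
    plan = FoldPlan(mode=mode, folds=folds, seed=seed)
    audit_fold_plan(data, plan)
    return plan


def audit_fold_plan(data: LabeledFeatures, plan: FoldPlan) -> None:
    """Raise unless test folds partition the rows (and LOSO is subject-disjoint,
    with no synthetic SMOTE rows anywhere in a test fold)."""
    seen = np.concatenate([t for _, t in plan.folds]) if plan.folds else np.array([])
    if sorted(seen.tolist()) != list(range(data.n_rows)):
        raise UsageError("test folds do not partition the dataset rows")
    for train, test in plan.folds:
        if np.any(data.subject_ids[test] == SYNTHETIC_SUBJECT):
            raise UsageError("synthetic SMOTE rows leaked into a test fold")
        if plan.mode == "loso":
            test_subjects = set(np.unique(data.subject_ids[test]))
            if len(test_subjects) != 1:
                raise UsageError("LOSO test fold spans multiple subjects")
            if test_subjects & set(np.unique(data.subject_ids[train])):
                raise UsageError("LOSO test subject appears in its training fold")


@dataclass(frozen=True)
class CVResult:
    """Per-fold reports plus a pooled summary."""

    fold_reports: tuple[MetricsReport, ...]
    pooled: ConfusionCounts
    mean: dict
    sd: dict
    skipped_folds: tuple[int, ...] = ()

    @property
    def pooled_metrics(self) -> MetricsReport:
        return binary_metrics(self.pooled)


def run_cv(
    data: LabeledFeatures,
    plan: FoldPlan,
    spec: ModelSpec,
    use_smote: bool = True,
    seed: int = 0,
    positive=FALL,
    smote_k: int = 5,
) -> CVResult:
    """Run cross-validation: SMOTE (training rows only), fit, predict, score.

    Per fold the training rows are optionally rebalanced with SMOTE, a
    detector is fitted, and the untouched test rows are predicted. A fold
    whose training set holds a single class is skipped with a warning.
    Returns per-fold metrics, their mean and SD, and the pooled confusion.
    """
    audit_fold_plan(data, plan)
    reports: list[MetricsReport] = []
    pooled = ConfusionCounts()
    skipped: list[int] = []
    for i, (train_idx, test_idx) in enumerate(plan.folds):
        train = data.subset(train_idx)
        if len(np.unique(train.labels)) < 2:
            warnings.warn(f"fold {i}: single-class training set, skipped",
                          stacklevel=2)
            skipped.append(i)
            continue
        if use_smote:
            train = balance_training_set(train, k=smote_k, seed=seed + i)
        det = fit(train, spec, seed=seed)
        test = data.subset(test_idx)
        y_pred = predict(det, test.matrix)
        c = confusion(test.labels, y_pred, positive=positive)
        rep = binary_metrics(c)
        reports.append(rep)
        pooled = pooled + c
        logger.info(
            "fold %d: train=%d (smote=%s) test=%d acc=%.4f sens=%.4f spec=%.4f",
            i, train.n_rows, use_smote, len(test_idx),
            rep.accuracy, rep.sensitivity, rep.specificity,
        )
    if not reports:
        raise UsageError("no usable folds (all skipped)")
    mean = {m: float(np.mean([r.as_dict()[m] for r in reports])) for m in METRIC_NAMES}
    sd = {m: float(np.std([r.as_dict()[m] for r in reports])) for m in METRIC_NAMES}
    return CVResult(
        fold_reports=tuple(reports), pooled=pooled, mean=mean, sd=sd,
        skipped_folds=tuple(skipped),
    )


def or_rule_sample_label(window_labels: Sequence) -> str:
    """Aggregate per-window labels to one sample label: FALL iff any window
    is FALL (prioritizes sensitivity and earliest detection)."""
    labels = list(window_labels)
    if not labels:
        raise UsageError("OR rule needs at least one window label")
    return FALL if any(lab == FALL for lab in labels) else ADL


WindowClassifier = Callable[[Window], str]


def streaming_evaluate(
    trace: TriaxialTrace,
    model: TrainedDetector | WindowClassifier,
    scheme: WindowScheme,
    cfg: StreamConfig,
    match_tolerance_s: float = 3.0,
) -> StreamingResult:
    """Causally stream a detector over an annotated continuous recording.

    Windows come from :func:`slide_windows`; the decision for each is
    available only at its end time and uses only samples up to that end
    (no look-ahead, asserted). Every FALL decision stamps an alarm at the
    window end. An annotated fall is an event true positive iff at least
    one alarm window overlaps [start - tol, end + tol]; windows that do not
    overlap any padded fall interval count toward window-level TN/FP
    (windows that overlap a fall but raised no alarm are ambiguous and are
    excluded from specificity).

    ``model`` may be a :class:`TrainedDetector` (features of ``scheme`` are
    extracted per window) or any callable mapping a Window to a label —
    useful for oracle detectors in protocol tests.
    """
    if isinstance(model, TrainedDetector):
        if model.n_features != scheme.n_features:
            raise UsageError(
                f"model expects {model.n_features} features but scheme "
                f"yields {scheme.n_features}"
            )

        def classify_window(w: Window) -> str:
            return predict(model, extract_features(w, scheme).values[None, :])[0]
    else:
        classify_window = model

    decisions: list[tuple[int, str, float]] = []
    alarms: list[float] = []
    padded = [
        (a.start_s - match_tolerance_s, a.end_s + match_tolerance_s)
        for a in trace.annotations
    ]
    alarmed = [False] * len(padded)
    window_tn = window_fp = 0
    for t, w in enumerate(slide_windows(trace, cfg)):
        decision_time = w.end_time_s
        # no look-ahead: the last sample this decision may touch
        assert w.start_sample + w.length_samples - 1 < decision_time * trace.rate + 1
        label = classify_window(w)
        decisions.append((t, label, decision_time))
        w_start, w_end = w.start_sample / trace.rate, decision_time
        overlapping = [
            i for i, (s, e) in enumerate(padded) if w_start < e and w_end > s
        ]
        if label == FALL:
            alarms.append(decision_time)
            if overlapping:
                for i in overlapping:
                    alarmed[i] = True
            else:
                window_fp += 1
        elif not overlapping:
            window_tn += 1
    event_tp = sum(alarmed)
    return StreamingResult(
        window_decisions=tuple(decisions),
        alarms=tuple(alarms),
        event_tp=event_tp,
        event_fn=len(padded) - event_tp,
        window_tn=window_tn,
        window_fp=window_fp,
    )


def streaming_overlap_sweep(
    traces: Sequence[TriaxialTrace],
    model: TrainedDetector | WindowClassifier,
    scheme: WindowScheme,
    overlaps: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(1, 10)),
    window_s: float = 3.0,
    match_tolerance_s: float = 3.0,
):
    """Sensitivity/specificity per sliding-window overlap, pooled over traces.

    Reproduces the streaming overlap grid (10%..90% by default). Returns a
    list of dicts, one per overlap value.
    """
    rows = []
    for o in overlaps:
        cfg = StreamConfig(window_s=window_s, overlap=o)
        tp = fn = tn = fp = 0
        for trace in traces:
            r = streaming_evaluate(trace, model, scheme, cfg, match_tolerance_s)
            tp += r.event_tp
            fn += r.event_fn
            tn += r.window_tn
            fp += r.window_fp
        rows.append({
            "overlap": o,
            "event_tp": tp, "event_fn": fn,
            "window_tn": tn, "window_fp": fp,
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        })
    return rows
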