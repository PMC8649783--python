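"""Subject-specific evaluation protocol and cross-model statistics.

Models are subject specific: the first two repetitions of every
speed/weight trial form the training data, and the windows of the third
repetition are shuffled and split 50/50 into validation and test sets,
stratified by weight class.  Reports carry overall accuracy, per-speed
accuracy, the 3x3 confusion matrix (rows = true, columns = predicted),
class-wise precision/recall and F-scores; subject accuracies are compared
across models with a one-way within-subjects ANOVA plus Bonferroni-adjusted
pairwise paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass(frozen=True)
class SplitSpec:
    """Train on reps 0-1, split rep 2 into validation/test (stratified)."""

    train_reps: tuple[int, ...] = (0, 1)
    holdout_rep: int = 2
    val_fraction: float = 0.5
    shuffle_seed: int = 0


@dataclass
class Split:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def split_windows(ws, spec: SplitSpec | None = None) -> Split:
    """Partition window indices into train/val/test per the protocol.

    ``ws`` is any object with ``rep_index``, ``trial_index`` and label
    arrays (a WindowSet or an ImageDataset).  The holdout repetition is
    shuffled with the seeded RNG and split class-by-class so validation
    and test counts differ by at most one per class.
    """
    spec = spec or SplitSpec()
    rep = np.asarray(ws.rep_index)
    labels = np.asarray(getattr(ws, "labels", None)
                        if hasattr(ws, "labels") else ws.weight_class)
    trial = np.asarray(ws.trial_index)

    needed = set(spec.train_reps) | {spec.holdout_rep}
    for t in np.unique(trial):
        have = set(rep[trial == t].tolist())
        if not needed <= have:
            raise ValueError(
                f"trial {t} is missing repetition(s) {sorted(needed - have)}")

    train = np.flatnonzero(np.isin(rep, spec.train_reps))
    holdout = np.flatnonzero(rep == spec.holdout_rep)
    rng = np.random.default_rng(spec.shuffle_seed)
    holdout = rng.permutation(holdout)

    val_parts, test_parts = [], []
    for c in np.unique(labels[holdout]):
        idx = holdout[labels[holdout] == c]
        n_val = int(len(idx) * spec.val_fraction)
        val_parts.append(idx[:n_val])
        test_parts.append(idx[n_val:])
    return Split(train=np.sort(train),
                 val=np.sort(np.concatenate(val_parts)),
                 test=np.sort(np.concatenate(test_parts)))


def _safe_div(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise num/den with 0/0 -> 0; returns (values, undefined mask)."""
    und = den == 0
    out = np.divide(num, den, out=np.zeros_like(num, dtype=float),
                    where=~und)
    return out, und


@dataclass
class SubjectReport:
    """Per-subject test-set performance for one model."""

    subject_id: str
    model_name: str
    n_test: int
    accuracy_pct: float
    speed_accuracy_pct: dict[str, float]
    confusion: np.ndarray               # (3, 3) rows true, cols predicted
    precision: np.ndarray               # (3,)
    recall: np.ndarray                  # (3,)
    f_score: np.ndarray                 # (3,)
    macro_f_pct: float
    undefined_metrics: bool = False


def classification_report(y_true: np.ndarray, y_pred: np.ndarray,
                          n_classes: int = 3) -> dict:
    """Confusion matrix plus class-wise precision/recall/F from it."""
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes)).astype(float)
    precision, u1 = _safe_div(np.diag(cm), cm.sum(axis=0))
    recall, u2 = _safe_div(np.diag(cm), cm.sum(axis=1))
    f, u3 = _safe_div(2 * precision * recall, precision + recall)
    return {
        "confusion": cm,
        "precision": precision,
        "recall": recall,
        "f_score": f,
        "undefined": bool(u1.any() or u2.any() or u3.any()),
    }


def evaluate(model, test_ds, model_name: str = "") -> SubjectReport:
    """Score a trained model on a held-out ImageDataset split.

    Predictions are argmax class probabilities (ties resolved toward the
    lowest class index); per-speed accuracies partition the test windows
    by the speed at which the movement was performed.
    """
    if len(test_ds) == 0:
        raise ValueError("test set is empty")
    y = np.asarray(test_ds.labels)
    pred = model.predict(test_ds.images)
    rep = classification_report(y, pred, test_ds.n_classes)
    acc = 100.0 * float(np.mean(pred == y))
    speed_acc = {}
    for s in np.unique(np.asarray(test_ds.speed_label)):
        m = np.asarray(test_ds.speed_label) == s
        speed_acc[str(s)] = 100.0 * float(np.mean(pred[m] == y[m]))
    return SubjectReport(
        subject_id=test_ds.subject_id,
        model_name=model_name or getattr(model, "layout", ""),
        n_test=len(y),
        accuracy_pct=acc,
        speed_accuracy_pct=speed_acc,
        confusion=rep["confusion"],
        precision=rep["precision"],
        recall=rep["recall"],
        f_score=rep["f_score"],
        macro_f_pct=100.0 * float(rep["f_score"].mean()),
        undefined_metrics=rep["undefined"],
    )


@dataclass
class AggregateReport:
    """Across-subject summary for one model.

    ``pooled_*`` metrics come from the elementwise-summed confusion matrix
    (the combined predictions of all subjects), which is not the same as
    averaging per-subject scores.
    """

    model_name: str
    n_subjects: int
    mean_accuracy_pct: float
    sd_accuracy_pct: float
    sd_undefined: bool
    pooled_confusion: np.ndarray
    pooled_precision: np.ndarray
    pooled_recall: np.ndarray
    pooled_f_pct: float
    mean_macro_f_pct: float
    subject_reports: list[SubjectReport] = field(default_factory=list)


def aggregate(reports: list[SubjectReport]) -> AggregateReport:
    """Unweighted mean +/- sample SD of subject accuracies, pooled matrix."""
    if not reports:
        raise ValueError("no subject reports to aggregate")
    accs = np.array([r.accuracy_pct for r in reports])
    sd_undef = len(accs) < 2
    sd = 0.0 if sd_undef else float(np.std(accs, ddof=1))
    pooled = np.sum([r.confusion for r in reports], axis=0)
    prec, _ = _safe_div(np.diag(pooled), pooled.sum(axis=0))
    rec, _ = _safe_div(np.diag(pooled), pooled.sum(axis=1))
    f, _ = _safe_div(2 * prec * rec, prec + rec)
    return AggregateReport(
        model_name=reports[0].model_name,
        n_subjects=len(reports),
        mean_accuracy_pct=float(accs.mean()),
        sd_accuracy_pct=sd,
        sd_undefined=sd_undef,
        pooled_confusion=pooled,
        pooled_precision=prec,
        pooled_recall=rec,
        pooled_f_pct=100.0 * float(f.mean()),
        mean_macro_f_pct=float(np.mean([r.macro_f_pct for r in reports])),
        subject_reports=list(reports),
    )


@dataclass
class ComparisonResult:
    """One-way within-subjects ANOVA + Bonferroni pairwise paired t-tests."""

    f_statistic: float
    p_value: float
    df_models: int
    df_error: int
    pairwise_p: pd.DataFrame    # Bonferroni-adjusted, capped at 1
    degenerate: bool = False
    alpha: float = 0.05


def rm_anova(table: pd.DataFrame) -> tuple[float, float, int, int, bool]:
    """One-way repeated-measures ANOVA via sums of squares.

    ``table``: rows = subjects, columns = models.  Returns
    (F, p, df_models, df_error, degenerate) with
    F = MS_models / MS_error, df = (k-1), (k-1)(n-1).
    """
    x = table.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("accuracy table has missing cells")
    n, k = x.shape
    grand = x.mean()
    ss_models = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_models - ss_subjects
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_models = ss_models / df1
    ms_error = ss_error / df2 if df2 > 0 else 0.0
    if ms_error <= 0:
        if ms_models == 0:
            return 0.0, 1.0, df1, df2, True
        return float("inf"), 0.0, df1, df2, True
    f = ms_models / ms_error
    return float(f), float(sps.f.sf(f, df1, df2)), df1, df2, False


def compare_models(table: pd.DataFrame, alpha: float = 0.05) -> ComparisonResult:
    """Compare per-subject accuracies across models.

    ``table`` has one row per subject and one column per model; every cell
    must be present (no imputation).  Pairwise p-values are paired t-tests
    multiplied by the number of comparisons (capped at 1); a zero-variance
    difference with a nonzero mean is reported as p = 0 and flagged.
    """
    f, p, df1, df2, degen = rm_anova(table)
    cols = list(table.columns)
    m = len(cols) * (len(cols) - 1) // 2
    pw = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            d = table[a].to_numpy(float) - table[b].to_numpy(float)
            if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
                raw = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
                degen = degen or raw == 0.0
            else:
                raw = float(sps.ttest_rel(table[a], table[b]).pvalue)
            adj = min(raw * m, 1.0)
            pw.loc[a, b] = pw.loc[b, a] = adj
    return ComparisonResult(f, p, df1, df2, pw, degenerate=degen, alpha=alpha)
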