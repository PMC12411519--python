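"""Metrics and experiment protocols.

Per-class precision/recall/F1 with macro and support-weighted averages,
confusion matrices, one-vs-rest and micro-average ROC/AUC, k-fold
cross-validation summaries (population-sd convention), and the four-way
ablation harness (classifier alone, classifier + cGAN augmentation,
AE + classifier, and the full AE + cGAN + classifier pipeline).

All percent metrics are kept at full precision internally; rounding
(half-up, 1 or 2 decimals) happens only when a report is rendered.
Curve construction and confusion counting are delegated to scikit-learn;
the percent arithmetic, the zero-denominator convention and the fold
summary conventions are defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from ._common import DomainError
from .phantom_data import ClassRegistry, ImageRecord, classifier_chain, load_batch

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocResult",
    "FoldSummary",
    "confusion",
    "per_class_metrics",
    "aggregate",
    "f1_from_precision_recall",
    "roc_auc",
    "summarize_folds",
    "cross_validate",
    "run_ablation",
    "full_report",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding for report display."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion matrix and per-class metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    registry: ClassRegistry

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (self.registry.num_classes,) * 2 or (c < 0).any():
            raise ValueError("confusion matrix must be CxC nonnegative counts")
        object.__setattr__(self, "counts", c)

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        names = self.registry.names
        lines = ["true\\pred," + ",".join(names)]
        for i, name in enumerate(names):
            lines.append(name + "," + ",".join(map(str, self.counts[i])))
        Path(path).write_text("\n".join(lines) + "\n")


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int],
              registry: ClassRegistry) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label sequences differ in length: "
                         f"{t.shape} vs {p.shape}")
    c = registry.num_classes
    if t.size and (t.min() < 0 or t.max() >= c or p.min() < 0 or p.max() >= c):
        raise DomainError(f"labels must lie in [0, {c - 1}]")
    counts = _sk_confusion(t, p, labels=np.arange(c))
    return ConfusionMatrix(counts, registry)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate metrics on the percent scale.

    ``zero_denominator`` flags classes where precision or recall hit a 0/0
    and were set to 0 by convention.  ``decimals`` only affects rendering.
    """

    class_names: tuple[str, ...]
    precision: np.ndarray            # percent
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    zero_denominator: np.ndarray
    accuracy: float | None = None
    macro_precision: float | None = None
    macro_recall: float | None = None
    macro_f1: float | None = None
    weighted_precision: float | None = None
    weighted_recall: float | None = None
    weighted_f1: float | None = None
    per_class_auc: np.ndarray | None = None
    micro_auc: float | None = None
    decimals: int = 2

    def to_json_dict(self) -> dict:
        d = self.decimals
        out = {
            "classes": {
                name: {
                    "precision": round_half_up(self.precision[i], d),
                    "recall": round_half_up(self.recall[i], d),
                    "f1": round_half_up(self.f1[i], d),
                    "support": int(self.support[i]),
                }
                for i, name in enumerate(self.class_names)
            }
        }
        for key in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                    "weighted_precision", "weighted_recall", "weighted_f1",
                    "micro_auc"):
            val = getattr(self, key)
            if val is not None:
                out[key] = round_half_up(val, d)
        if self.per_class_auc is not None:
            out["auc"] = {
                name: (None if np.isnan(self.per_class_auc[i])
                       else round_half_up(float(self.per_class_auc[i]), 3))
                for i, name in enumerate(self.class_names)
            }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_json_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def render_table(self) -> str:
        d = self.decimals
        rows = [("Class", "Pre (%)", "Rec (%)", "F1-S (%)", "Support")]
        fmt = f"{{:.{d}f}}"
        for i, name in enumerate(self.class_names):
            rows.append((name, fmt.format(round_half_up(self.precision[i], d)),
                         fmt.format(round_half_up(self.recall[i], d)),
                         fmt.format(round_half_up(self.f1[i], d)),
                         str(int(self.support[i]))))
        if self.accuracy is not None:
            rows.append(("Accuracy", "", "",
                         fmt.format(round_half_up(self.accuracy, d)),
                         str(int(self.support.sum()))))
            rows.append(("Macro avg",
                         fmt.format(round_half_up(self.macro_precision, d)),
                         fmt.format(round_half_up(self.macro_recall, d)),
                         fmt.format(round_half_up(self.macro_f1, d)),
                         str(int(self.support.sum()))))
            rows.append(("Weighted avg",
                         fmt.format(round_half_up(self.weighted_precision, d)),
                         fmt.format(round_half_up(self.weighted_recall, d)),
                         fmt.format(round_half_up(self.weighted_f1, d)),
                         str(int(self.support.sum()))))
        widths = [max(len(r[i]) for r in rows) for i in range(5)]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
            for row in rows)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean on the percent scale; 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def per_class_metrics(cm: ConfusionMatrix, decimals: int = 2) -> MetricsReport:
    """Precision/recall/F1 per class in percent, 0/0 -> 0 with a flag."""
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    flags = np.zeros(len(tp), dtype=bool)
    precision = np.zeros(len(tp))
    recall = np.zeros(len(tp))
    for i in range(len(tp)):
        if tp[i] + fp[i] == 0:
            flags[i] = True
        else:
            precision[i] = 100.0 * tp[i] / (tp[i] + fp[i])
        if tp[i] + fn[i] == 0:
            flags[i] = True
        else:
            recall[i] = 100.0 * tp[i] / (tp[i] + fn[i])
    f1 = np.array([f1_from_precision_recall(p, r)
                   for p, r in zip(precision, recall)])
    return MetricsReport(cm.registry.names, precision, recall, f1,
                         cm.supports.copy(), flags, decimals=decimals)


def aggregate(report: MetricsReport, cm: ConfusionMatrix) -> MetricsReport:
    """Fill accuracy, macro (unweighted) and support-weighted averages."""
    w = report.support / report.support.sum()
    return replace(
        report,
        accuracy=100.0 * np.trace(cm.counts) / cm.total,
        macro_precision=float(report.precision.mean()),
        macro_recall=float(report.recall.mean()),
        macro_f1=float(report.f1.mean()),
        weighted_precision=float((report.precision * w).sum()),
        weighted_recall=float((report.recall * w).sum()),
        weighted_f1=float((report.f1 * w).sum()),
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    class_names: tuple[str, ...]
    curves: tuple          # per class: (fpr, tpr, thresholds) or None
    auc: np.ndarray        # per class; NaN where undefined
    undefined: np.ndarray  # flag: class absent from the true labels
    micro_curve: tuple
    micro_auc: float

    def to_csv(self, path: str | Path) -> None:
        lines = ["class,threshold,fpr,tpr"]
        for name, curve in zip(self.class_names, self.curves):
            if curve is None:
                continue
            fpr, tpr, thr = curve
            for f, t, th in zip(fpr, tpr, thr):
                lines.append(f"{name},{th:.6g},{f:.6g},{t:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")


def roc_auc(true_labels: Sequence[int], probabilities: np.ndarray,
            registry: ClassRegistry) -> RocResult:
    """One-vs-rest ROC per class plus the pooled micro-average.

    Each class's curve uses that class's probability column as the score;
    AUC is the trapezoidal area over the full threshold sweep.  A class
    with no true samples gets ``auc = NaN`` and an undefined flag.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(probabilities, dtype=np.float64)
    c = registry.num_classes
    if p.ndim != 2 or p.shape != (len(y), c):
        raise ValueError(f"need ({len(y)}, {c}) probabilities, got {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    curves, aucs, undef = [], [], []
    for k in range(c):
        members = (y == k).astype(int)
        if members.sum() == 0 or members.sum() == len(y):
            curves.append(None)
            aucs.append(np.nan)
            undef.append(True)
            continue
        fpr, tpr, thr = _sk_roc_curve(members, p[:, k])
        curves.append((fpr, tpr, thr))
        aucs.append(float(_sk_auc(fpr, tpr)))
        undef.append(False)
    onehot = np.eye(c, dtype=int)[y].ravel()
    m_fpr, m_tpr, m_thr = _sk_roc_curve(onehot, p.ravel())
    return RocResult(registry.names, tuple(curves), np.asarray(aucs),
                     np.asarray(undef), (m_fpr, m_tpr, m_thr),
                     float(_sk_auc(m_fpr, m_tpr)))


def full_report(true_labels: Sequence[int], probabilities: np.ndarray,
                registry: ClassRegistry, decimals: int = 2) -> MetricsReport:
    """Complete report (per-class + aggregates + AUC) from probabilities."""
    preds = np.argmax(probabilities, axis=1)
    cm = confusion(true_labels, preds, registry)
    report = aggregate(per_class_metrics(cm, decimals=decimals), cm)
    roc = roc_auc(true_labels, probabilities, registry)
    return replace(report, per_class_auc=roc.auc, micro_auc=100.0 * roc.micro_auc)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class FoldSummary:
    """Per-fold accuracies (percent) with mean and *population* sd.

    The population convention (divisor k, not k-1) is the stated one for
    fold summaries in this package.
    """

    val_accuracies: tuple[float, ...]
    test_accuracies: tuple[float, ...]
    k: int

    @property
    def val_mean(self) -> float:
        return float(np.mean(self.val_accuracies))

    @property
    def val_sd(self) -> float:
        return float(np.std(self.val_accuracies))       # ddof=0: population

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_accuracies))

    @property
    def test_sd(self) -> float:
        return float(np.std(self.test_accuracies))

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "val_accuracies": [round_half_up(v, 2)
                               for v in self.val_accuracies],
            "test_accuracies": [round_half_up(v, 2)
                                for v in self.test_accuracies],
            "val_mean": round_half_up(self.val_mean, 2),
            "val_sd": round_half_up(self.val_sd, 2),
            "test_mean": round_half_up(self.test_mean, 2),
            "test_sd": round_half_up(self.test_sd, 2),
        }


def summarize_folds(values: Sequence[float]) -> tuple[float, float]:
    """(mean, population sd) of fold accuracies."""
    v = np.asarray(values, dtype=np.float64)
    return float(v.mean()), float(np.std(v))


def cross_validate(records: Sequence[ImageRecord],
                   train_fn: Callable[[Sequence[ImageRecord]], object],
                   accuracy_fn: Callable[[object, Sequence[ImageRecord]], float],
                   k: int = 3, seed: int = 0,
                   extra_train_records: Sequence[ImageRecord] = (),
                   ) -> FoldSummary:
    """Stratified k-fold over the non-test pool with a fixed test split.

    The records' existing ``test`` tags define the held-out set once; the
    remaining (train + val) pool is re-divided into k stratified folds.  Per
    fold, ``train_fn`` receives records retagged fold-train/fold-val (plus
    any ``extra_train_records``, e.g. synthetic images, always as train) and
    ``accuracy_fn(model, records)`` scores the fold-val and fixed-test sets.
    Accuracies are reported in percent.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    test = [r for r in records if r.split == "test"]
    pool = [r for r in records if r.split in ("train", "val")]
    labels = np.asarray([r.class_id for r in pool])
    names = {r.class_id: r.class_name for r in pool}
    counts = np.bincount(labels)
    for cid, cnt in enumerate(counts):
        if 0 < cnt < k:
            raise DomainError(f"class {names[cid]!r} has {cnt} records; "
                              f"needs >= {k} for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    val_accs, test_accs = [], []
    for train_idx, val_idx in skf.split(np.zeros(len(pool)), labels):
        fold_records = (
            [replace(pool[i], split="train") for i in train_idx]
            + [replace(pool[i], split="val") for i in val_idx]
            + [replace(r, split="train") for r in extra_train_records]
        )
        model = train_fn(fold_records)
        fold_val = [r for r in fold_records
                    if r.split == "val" and r.source == "real"]
        val_accs.append(100.0 * accuracy_fn(model, fold_val))
        test_accs.append(100.0 * accuracy_fn(model, test))
    return FoldSummary(tuple(val_accs), tuple(test_accs), k)


# ---------------------------------------------------------------------------
# ablation harness


ABLATION_CONFIGS = ("classifier", "classifier+cgan", "ae+classifier", "full")


def run_ablation(records: Sequence[ImageRecord],
                 registry: ClassRegistry,
                 pipeline: Callable[[Sequence[ImageRecord], bool, bool], object],
                 evaluate_fn: Callable[[object, Sequence[ImageRecord]], MetricsReport],
                 configs: Sequence[str] = ABLATION_CONFIGS,
                 ) -> dict[str, MetricsReport]:
    """Controlled comparison over the standard four configurations.

    ``pipeline(records, use_ae, use_cgan)`` trains one configuration on
    identical splits/seeds and returns a model; ``evaluate_fn`` scores it on
    the shared test split.  Returns one MetricsReport per configuration.
    """
    flags = {
        "classifier": (False, False),
        "classifier+cgan": (False, True),
        "ae+classifier": (True, False),
        "full": (True, True),
    }
    unknown = [c for c in configs if c not in flags]
    if unknown:
        raise ValueError(f"unknown ablation configuration(s): {unknown}")
    test = [r for r in records if r.split == "test"]
    out: dict[str, MetricsReport] = {}
    for name in configs:
        use_ae, use_cgan = flags[name]
        model = pipeline(records, use_ae, use_cgan)
        out[name] = evaluate_fn(model, test)
    return out


def render_ablation_table(reports: dict[str, MetricsReport]) -> str:
    rows = [("Configuration", "Accuracy", "Macro P", "Macro R", "Macro F1",
             "Weighted P", "Weighted R", "Weighted F1")]
    for name, rep in reports.items():
        d = rep.decimals
        fmt = f"{{:.{d}f}}"
        rows.append((name, fmt.format(round_half_up(rep.accuracy, d)),
                     fmt.format(round_half_up(rep.macro_precision, d)),
                     fmt.format(round_half_up(rep.macro_recall, d)),
                     fmt.format(round_half_up(rep.macro_f1, d)),
                     fmt.format(round_half_up(rep.weighted_precision, d)),
                     fmt.format(round_half_up(rep.weighted_recall, d)),
                     fmt.format(round_half_up(rep.weighted_f1, d))))
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows)
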