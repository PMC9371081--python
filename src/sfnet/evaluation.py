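"""Confusion matrices and classification metrics.

Matrices are stored as full 2x2 count tables indexed (true class, predicted
class) over (fracture, healthy) rather than as TP/TN/FP/FN scalars, because
scalar conventions are ambiguous: the per-class metrics here are recovered by
taking each class in turn as positive. Accuracy, precision, recall and F1 use
the standard definitions; zero-denominator metrics are reported as 0 with a
warning flag.

``REFERENCE_CONFUSION_COUNTS`` holds the published confusion matrices from
the original bone X-ray benchmark (6,800 balanced test images) for the five
evaluated architectures; they serve as worked examples for the metric
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .image_io import CLASSES, ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i][j] = items of true class CLASSES[i] predicted as CLASSES[j]."""

    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValidationError(f"counts must be a non-negative 2x2 table, got {self.counts}")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    positive_class: str
    zero_denominator_warning: bool = field(default=False)

    def rounded(self, decimals: int = 2) -> dict:
        """The report-table view: every metric rounded to ``decimals``."""
        out: dict = {"accuracy": round(self.accuracy, decimals)}
        for cls, m in self.per_class.items():
            out[cls] = {
                "precision": round(m.precision, decimals),
                "recall": round(m.recall, decimals),
                "f1": round(m.f1, decimals),
            }
        return out


def confusion_matrix(true: Sequence[str], pred: Sequence[str]) -> ConfusionMatrix:
    """Tabulate counts over the two classes (rows true, columns predicted)."""
    if len(true) != len(pred):
        raise ValidationError(f"label sequences differ in length: {len(true)} vs {len(pred)}")
    for seq, name in ((true, "true"), (pred, "pred")):
        bad = set(seq) - set(CLASSES)
        if bad:
            raise ValidationError(f"unknown {name} labels {sorted(bad)}; expected {CLASSES}")
    arr = _sk_confusion(list(true), list(pred), labels=list(CLASSES))
    return ConfusionMatrix(tuple(tuple(int(v) for v in row) for row in arr))


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def metrics_from_confusion(cm: ConfusionMatrix, positive: str = "fracture") -> MetricsReport:
    """Accuracy plus per-class precision/recall/F1 from a 2x2 count table.

    Each class is taken as positive in turn; ``positive`` only records which
    class the report is oriented around. Zero-denominator metrics come out as
    0 with the report's warning flag set.
    """
    if positive not in CLASSES:
        raise ValidationError(f"positive class must be one of {CLASSES}, got {positive!r}")
    arr = cm.array
    if arr.sum() == 0:
        raise ValidationError("empty confusion matrix")
    warned = False
    per_class: dict[str, ClassMetrics] = {}
    for k, cls in enumerate(CLASSES):
        tp = float(arr[k, k])
        fp = float(arr[1 - k, k])
        fn = float(arr[k, 1 - k])
        precision, w1 = _safe_div(tp, tp + fp)
        recall, w2 = _safe_div(tp, tp + fn)
        f1, w3 = _safe_div(2 * precision * recall, precision + recall)
        warned |= w1 or w2 or w3
        per_class[cls] = ClassMetrics(precision=precision, recall=recall, f1=f1)
    accuracy = float(np.trace(arr) / arr.sum())
    return MetricsReport(
        per_class=per_class,
        accuracy=accuracy,
        positive_class=positive,
        zero_denominator_warning=warned,
    )


# Published confusion matrices from the original bone X-ray benchmark
# (3,400 test images per class). Row order (fracture, healthy), column order
# (predicted fracture, predicted healthy). The error counts are placed as the
# unique assignment consistent with every published per-class metric row:
# for AlexNet/VGG16/ResNeXt the errors are healthy images called fracture;
# for the hybrid SFNet 60 fractures were called healthy; MobileNetV2 erred
# both ways.
REFERENCE_CONFUSION_COUNTS: dict[str, ConfusionMatrix] = {
    "AlexNet": ConfusionMatrix(((3400, 0), (645, 2755))),
    "VGG16": ConfusionMatrix(((3400, 0), (352, 3048))),
    "ResNeXt": ConfusionMatrix(((3400, 0), (341, 3059))),
    "MobileNetV2": ConfusionMatrix(((678, 2722), (830, 2570))),
    "Hybrid SFNet": ConfusionMatrix(((3340, 60), (0, 3400))),
}


def format_report_table(reports: dict[str, MetricsReport]) -> str:
    """Plain-text metric table, one precision/recall/F1 row per class per
    model plus the model's accuracy."""
    lines = [f"{'Model':<22}{'Class':<10}{'Prec':>6}{'Rec':>6}{'F1':>6}{'Acc':>7}"]
    for name, rep in reports.items():
        r = rep.rounded()
        for j, cls in enumerate(CLASSES):
            acc = f"{r['accuracy']:.2f}" if j == 0 else ""
            m = r[cls]
            lines.append(
                f"{name if j == 0 else '':<22}{cls:<10}"
                f"{m['precision']:>6.2f}{m['recall']:>6.2f}{m['f1']:>6.2f}{acc:>7}"
            )
    return "\n".join(lines)
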