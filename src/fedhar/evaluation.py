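"""Confusion-matrix metrics, stability statistics, cross-dataset harness.

Metrics follow the one-vs-rest confusion counts per class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)   (overall fraction correct
                                                   for the multi-class case)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Zero-denominator metrics are defined as 0. Macro averages are unweighted
class means; weighted averages weight by class support.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelingError",
    "HarnessError",
    "MetricsReport",
    "StabilitySummary",
    "CrossDatasetResult",
    "compute_metrics",
    "stability_summary",
    "cross_dataset_eval",
]


class LabelingError(ValueError):
    pass


class HarnessError(ValueError):
    pass


@dataclass
class MetricsReport:
    """Per-class confusion counts and derived metrics."""

    classes: list[str]
    tp: dict[str, int]
    tn: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int] = field(default_factory=dict)

    @property
    def macro_precision(self) -> float:
        return float(np.mean([self.precision[c] for c in self.classes]))

    @property
    def macro_recall(self) -> float:
        return float(np.mean([self.recall[c] for c in self.classes]))

    @property
    def macro_f1(self) -> float:
        return float(np.mean([self.f1[c] for c in self.classes]))

    @property
    def weighted_f1(self) -> float:
        total = sum(self.support.values())
        if total == 0:
            return 0.0
        return float(
            sum(self.f1[c] * self.support.get(c, 0) for c in self.classes) / total
        )

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                c: {
                    "tp": self.tp[c],
                    "tn": self.tn[c],
                    "fp": self.fp[c],
                    "fn": self.fn[c],
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "support": self.support.get(c, 0),
                }
                for c in self.classes
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _safe_div(num: float, den: float, what: str = "") -> float:
    if den == 0:
        if what:
            warnings.warn(f"zero denominator for {what}; defining metric as 0")
        return 0.0
    return num / den


def compute_metrics(predictions, truth, classes=None) -> MetricsReport:
    """One-vs-rest confusion counts and the derived metric set.

    ``classes`` fixes the label universe (defaults to the labels observed
    in truth); predictions outside it raise LabelingError.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth) or not truth:
        raise LabelingError("predictions and truth must share a positive length")
    if classes is None:
        classes = sorted(set(truth))
    classes = list(classes)
    universe = set(classes) | set(truth)
    for p in predictions:
        if p not in universe:
            raise LabelingError(f"prediction label {p!r} not in the class set")

    n = len(truth)
    tp, tn, fp, fn = {}, {}, {}, {}
    precision, recall, f1, support = {}, {}, {}, {}
    correct = sum(p == t for p, t in zip(predictions, truth))
    for c in classes:
        tp_c = sum(1 for p, t in zip(predictions, truth) if p == c and t == c)
        fp_c = sum(1 for p, t in zip(predictions, truth) if p == c and t != c)
        fn_c = sum(1 for p, t in zip(predictions, truth) if p != c and t == c)
        tn_c = n - tp_c - fp_c - fn_c
        tp[c], tn[c], fp[c], fn[c] = tp_c, tn_c, fp_c, fn_c
        support[c] = tp_c + fn_c
        precision[c] = _safe_div(tp_c, tp_c + fp_c, f"precision[{c}]" if tp_c else "")
        recall[c] = _safe_div(tp_c, tp_c + fn_c, f"recall[{c}]" if tp_c else "")
        f1[c] = _safe_div(
            2.0 * precision[c] * recall[c], precision[c] + recall[c]
        )
    return MetricsReport(
        classes=classes,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=correct / n,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
    )


@dataclass
class StabilitySummary:
    """Spread statistics of a per-round metric series."""

    mean: float
    sd: float
    minimum: float
    maximum: float
    iqr: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.minimum,
            "max": self.maximum,
            "iqr": self.iqr,
            "n": self.n,
        }


def stability_summary(values) -> StabilitySummary:
    """Mean, sample SD (n-1; 0 for singletons), min, max, IQR.

    IQR uses linear-interpolation quantiles (p75 - p25).
    """
    x = np.asarray(list(values), dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty series")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return StabilitySummary(
        mean=float(x.mean()),
        sd=sd,
        minimum=float(x.min()),
        maximum=float(x.max()),
        iqr=float(np.percentile(x, 75) - np.percentile(x, 25)),
        n=int(x.size),
    )


@dataclass
class CrossDatasetResult:
    metrics: MetricsReport
    coverage: float  # fraction of target windows whose label was retained
    retained: int
    total: int


def cross_dataset_eval(
    predict,
    source_label_set,
    target_windows,
    target_label_set,
    label_map: dict[str, str] | None = None,
) -> CrossDatasetResult:
    """Evaluate a model trained on one label universe on another dataset.

    ``predict`` maps a list of windows to predicted source-universe
    labels (e.g. functools.partial(model.predict, params)). Target labels
    are first mapped through ``label_map`` (identity by default); only
    windows whose mapped label falls in the intersection of the two label
    sets are evaluated. Coverage is the retained fraction.
    """
    source = set(source_label_set)
    target = set(target_label_set)
    label_map = label_map or {}
    mapped_target = {label_map.get(t, t) for t in target}
    shared = source & mapped_target
    if len(shared) < 2:
        raise HarnessError(
            f"label sets share {len(shared)} classes; need at least 2"
        )
    total = len(target_windows)
    kept = [
        w for w in target_windows if label_map.get(w.label, w.label) in shared
    ]
    if not kept:
        raise HarnessError("no target windows fall in the shared label set")
    truth = [label_map.get(w.label, w.label) for w in kept]
    predictions = predict(kept)
    # a source-only prediction is a valid (always wrong) model output, so
    # it joins the class universe rather than raising
    classes = sorted(shared | (set(predictions) & source))
    metrics = compute_metrics(predictions, truth, classes=classes)
    return CrossDatasetResult(
        metrics=metrics,
        coverage=len(kept) / total,
        retained=len(kept),
        total=total,
    )
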