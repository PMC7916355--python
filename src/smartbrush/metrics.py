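"""Classification quality and brushing-completion scoring.

Per-class one-vs-rest counts (TP/FP/FN/TN) feed the standard identities

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F_a       = (a^2 + 1) P R / (a^2 (P + R))     (F1 at a = 1)

summarized both macro (mean over classes) and micro (from pooled counts).
Brushing completion compares per-region dwell time against a prescribed
schedule:  completion = dwell / prescribed x 100%, capped at 100% per
region so over-brushing one region cannot mask neglect of another (the raw
uncapped ratio is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ConfigError, DimensionError

N_REGIONS = 15


@dataclass
class ConfusionCounts:
    labels: np.ndarray
    matrix: np.ndarray  # rows = true class, cols = predicted
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray
    undefined_precision: np.ndarray
    undefined_recall: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f: float
    micro_precision: float
    micro_recall: float
    micro_f: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f": self.macro_f,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f": self.micro_f,
            "per_class_precision": self.precision.tolist(),
            "per_class_recall": self.recall.tolist(),
            "per_class_f": self.f_score.tolist(),
        }


@dataclass
class CompletionReport:
    regions: list
    dwell_seconds: np.ndarray
    prescribed_seconds: np.ndarray
    percent: np.ndarray  # capped at 100 per region
    percent_raw: np.ndarray  # uncapped
    overall_percent: float
    overall_percent_raw: float

    def as_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "dwell_seconds": self.dwell_seconds.tolist(),
            "prescribed_seconds": self.prescribed_seconds.tolist(),
            "percent": self.percent.tolist(),
            "percent_raw": self.percent_raw.tolist(),
            "overall_percent": self.overall_percent,
            "overall_percent_raw": self.overall_percent_raw,
        }


def confusion(y_true, y_pred, labels=None) -> ConfusionCounts:
    """Multi-class confusion matrix plus one-vs-rest counts per class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise DimensionError(
            f"y_true has {len(y_true)} labels but y_pred has {len(y_pred)}"
        )
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    else:
        labels = np.asarray(labels)
    m = _sk_confusion(y_true, y_pred, labels=labels)
    tp = np.diag(m).astype(int)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    return ConfusionCounts(labels=labels, matrix=m, tp=tp, fp=fp, fn=fn, tn=tn)


def f_measure(precision, recall, a: float = 1.0):
    """Weighted harmonic mean F_a; 0 where both components vanish."""
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    num = (a**2 + 1.0) * precision * recall
    den = a**2 * (precision + recall)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(den > 0, num / den, 0.0)
    return f if f.ndim else float(f)


def scores(counts: ConfusionCounts, a: float = 1.0) -> MetricsReport:
    """Accuracy and per-class precision/recall/F with macro and micro summaries.

    A class with TP + FP = 0 has undefined precision (reported as 0 with the
    ``undefined_precision`` flag set); likewise recall for TP + FN = 0.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    accuracy = float(np.diag(counts.matrix).sum() / counts.total) if counts.total else 0.0
    undef_p = (tp + fp) == 0
    undef_r = (tp + fn) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(undef_p, 0.0, tp / np.maximum(tp + fp, 1))
        recall = np.where(undef_r, 0.0, tp / np.maximum(tp + fn, 1))
    f = f_measure(precision, recall, a=a)
    micro_tp, micro_fp, micro_fn = tp.sum(), fp.sum(), fn.sum()
    micro_p = micro_tp / (micro_tp + micro_fp) if micro_tp + micro_fp else 0.0
    micro_r = micro_tp / (micro_tp + micro_fn) if micro_tp + micro_fn else 0.0
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_score=f,
        undefined_precision=undef_p,
        undefined_recall=undef_r,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f=float(f.mean()),
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f=float(f_measure(micro_p, micro_r, a=a)),
    )


def evaluate(y_true, y_pred, labels=None, a: float = 1.0) -> MetricsReport:
    """Convenience: confusion + scores in one call."""
    return scores(confusion(y_true, y_pred, labels=labels), a=a)


def default_schedule(
    total_seconds: float = 120.0, regions=range(1, N_REGIONS + 1)
) -> dict:
    """Prescribed dwell schedule: two minutes split equally over 15 regions."""
    regions = list(regions)
    return {int(r): total_seconds / len(regions) for r in regions}


def brushing_completion(
    t, labels, prescribed: dict | None = None, ignore=(0,)
) -> CompletionReport:
    """Per-region completion percentages from a timestamped label sequence.

    Dwell per region is the summed sample spacing over frames carrying that
    label; labels in ``ignore`` (default: 0 = unlabeled) accrue no dwell.
    Every region appearing in the labels must be in the schedule.
    """
    t = np.asarray(t, dtype=float)
    labels = np.asarray(labels)
    if len(t) != len(labels):
        raise DimensionError(f"{len(t)} timestamps but {len(labels)} labels")
    prescribed = prescribed if prescribed is not None else default_schedule()
    for r, secs in prescribed.items():
        if not secs > 0:
            raise ConfigError(f"prescribed time for region {r} must be > 0, got {secs}")
    present = {int(v) for v in np.unique(labels)} - set(int(i) for i in ignore)
    missing = present - {int(r) for r in prescribed}
    if missing:
        raise ConfigError(f"regions {sorted(missing)} missing from the prescribed schedule")

    if len(t) > 1:
        dt = np.empty(len(t))
        dt[1:] = np.diff(t)
        dt[0] = np.median(dt[1:])
    else:
        dt = np.ones(len(t))
    regions = sorted(int(r) for r in prescribed)
    dwell = np.array([float(dt[labels == r].sum()) for r in regions])
    presc = np.array([float(prescribed[r]) for r in regions])
    raw = dwell / presc * 100.0
    capped = np.minimum(raw, 100.0)
    return CompletionReport(
        regions=regions,
        dwell_seconds=dwell,
        prescribed_seconds=presc,
        percent=capped,
        percent_raw=raw,
        overall_percent=float(capped.mean()),
        overall_percent_raw=float(raw.mean()),
    )
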