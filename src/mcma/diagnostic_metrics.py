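"""Diagnostic-level evaluation: does the generated 12-lead ECG preserve the
information a 12-lead arrhythmia classifier needs?

A plug-in classifier (any ``callable(12 x L array) -> binary class vector``)
is scored per class with one-vs-rest confusion counts: precision TP/(TP+FP),
recall TP/(TP+FN), specificity TN/(TN+FP) and F1 = 2TP/(2TP+FN+FP); 0/0
cells score 0, matching the convention of printing 0.0000 for classes never
predicted.  Macro averages are unweighted means over classes.  The "gain" of
the generator for an input lead is the macro metric on the generated 12-lead
ECG minus the macro metric on the raw zero-padded single lead.

No trained classifier ships with the package; :class:`RuleBasedHrClassifier`
is a self-contained rate-based stand-in (tachycardia / bradycardia from the
lead-II heart rate) so the diagnostic level runs end-to-end on synthetic
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_metrics import detect_rpeaks, mhr


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def class_metrics(c: ConfusionCounts) -> tuple:
    """(precision, recall, specificity, F1) for one class; 0/0 -> 0."""
    pre = _safe_div(c.tp, c.tp + c.fp)
    rec = _safe_div(c.tp, c.tp + c.fn)
    spe = _safe_div(c.tn, c.tn + c.fp)
    f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fn + c.fp)
    return pre, rec, spe, f1


@dataclass
class DiagMetrics:
    """Per-class and macro-averaged classification metrics."""

    classes: tuple
    per_class: dict  # class -> (pre, rec, spe, f1)

    @property
    def macro(self) -> tuple:
        vals = np.array([self.per_class[c] for c in self.classes], dtype=float)
        return tuple(float(v) for v in vals.mean(axis=0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            self.per_class, orient="index", columns=["Pre", "Rec", "Spe", "F1"])
        df = df.loc[list(self.classes)]
        df.loc["Mean"] = list(self.macro)
        df.index.name = "Class"
        return df


def metrics_from_counts(counts: dict) -> DiagMetrics:
    """Build :class:`DiagMetrics` from a ``class -> ConfusionCounts`` map."""
    classes = tuple(counts)
    return DiagMetrics(classes, {c: class_metrics(counts[c]) for c in classes})


def confusion_from_labels(y_true, y_pred, classes=None) -> dict:
    """Per-class one-vs-rest confusion counts from binary label matrices.

    ``y_true`` and ``y_pred`` are ``(records, classes)`` binary arrays.
    Returns ``class -> ConfusionCounts`` keyed by ``classes`` (or column
    index when class names are not given).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 2:
        raise ValueError(f"label matrices must share a 2-D shape, got "
                         f"{y_true.shape} and {y_pred.shape}")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    n, k = y_true.shape
    classes = tuple(range(k)) if classes is None else tuple(classes)
    if len(classes) != k:
        raise ValueError("classes length must match the number of columns")
    out = {}
    for j, cls in enumerate(classes):
        t = y_true[:, j].astype(bool)
        p = y_pred[:, j].astype(bool)
        out[cls] = ConfusionCounts(
            tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)), tn=int(np.sum(~t & ~p)))
    return out


def macro_average(d: DiagMetrics) -> tuple:
    """Unweighted macro (pre, rec, spe, f1) across classes."""
    if not d.classes:
        raise ValueError("no classes to average")
    return d.macro


def gain(metrics_generated: DiagMetrics, metrics_baseline: DiagMetrics) -> tuple:
    """Macro-metric differences: generated minus single-lead baseline."""
    if set(metrics_generated.classes) != set(metrics_baseline.classes):
        raise ValueError("class sets differ between generated and baseline")
    g = np.array(metrics_generated.macro) - np.array(metrics_baseline.macro)
    return tuple(float(v) for v in g)


# ---------------------------------------------------------------------------
# Shipped rule-based classifier (rate-based stand-in for a trained model)
# ---------------------------------------------------------------------------

class RuleBasedHrClassifier:
    """Synthetic rate-based classifier: thresholds the lead-II heart rate.

    Emits a binary vector over ``("bradycardia", "tachycardia")``:
    bradycardia when MHR < 60 bpm, tachycardia when MHR > 100 bpm, from
    R peaks detected on lead II.  It exists so the diagnostic level can run
    without any trained weights; it reads only lead II, which also makes the
    single-lead-baseline degradation visible (a zero-padded non-II input
    leaves it blind).
    """

    classes = ("bradycardia", "tachycardia")

    def __init__(self, fs: float = 500.0, brady_bpm: float = 60.0,
                 tachy_bpm: float = 100.0):
        self.fs = fs
        self.brady_bpm = brady_bpm
        self.tachy_bpm = tachy_bpm

    def __call__(self, ecg12) -> np.ndarray:
        ecg12 = np.asarray(ecg12, dtype=np.float64)
        if ecg12.ndim != 2 or ecg12.shape[0] != 12:
            raise ValueError(f"classifier expects a 12 x L array, got {ecg12.shape}")
        rate = mhr(detect_rpeaks(ecg12[1], self.fs, lead_index=1))
        if rate is None:
            return np.zeros(2, dtype=int)
        return np.array([int(rate < self.brady_bpm),
                         int(rate > self.tachy_bpm)], dtype=int)


def labels_to_matrix(labels, classes) -> np.ndarray:
    """Convert per-record label collections into a binary matrix."""
    classes = tuple(classes)
    mat = np.zeros((len(labels), len(classes)), dtype=int)
    for i, labs in enumerate(labels):
        for j, cls in enumerate(classes):
            if cls in labs:
                mat[i, j] = 1
    return mat


def threshold_scores(scores, threshold: float = 0.5) -> np.ndarray:
    """Binarize classifier scores/probabilities at ``threshold``.

    Already-binary vectors pass through unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    if np.isin(scores, (0.0, 1.0)).all():
        return scores.astype(int)
    return (scores >= threshold).astype(int)


def evaluate_diagnostic(classifier, generator, records, y_true,
                        input_leads=None, classes=None,
                        score_threshold: float = 0.5) -> dict:
    """Run the three diagnostic configurations per input lead.

    For every input lead ``i``: (a) the true 12-lead record (reference,
    computed once), (b) the zero-padded single lead fed directly to the
    classifier (baseline), (c) the generated 12-lead record.  Returns a dict
    with the reference :class:`DiagMetrics` plus per-lead baseline/generated
    metrics and their macro gains (c minus b).

    ``records`` are 12 x L arrays (or objects with ``.samples``); ``y_true``
    is the binary label matrix aligned with ``records``.
    """
    classes = tuple(classes if classes is not None
                    else getattr(classifier, "classes", None)
                    or range(np.asarray(y_true).shape[1]))
    y_true = np.asarray(y_true)
    arrays = [np.asarray(getattr(r, "samples", r), dtype=np.float64)
              for r in records]
    if y_true.shape != (len(arrays), len(classes)):
        raise ValueError("y_true shape must be (n_records, n_classes)")
    input_leads = (tuple(range(12)) if input_leads is None
                   else tuple(int(i) for i in input_leads))

    def _score(pred_rows):
        y_pred = np.vstack([threshold_scores(r, score_threshold)
                            for r in pred_rows])
        if y_pred.shape != y_true.shape:
            raise ValueError(f"classifier output shape {y_pred.shape} does not "
                             f"match labels {y_true.shape}")
        return metrics_from_counts(confusion_from_labels(y_true, y_pred, classes))

    reference = _score([np.asarray(classifier(a)).ravel() for a in arrays])
    per_lead = {}
    for i in input_leads:
        base_preds, gen_preds = [], []
        for a in arrays:
            n = a.shape[1]
            padded = np.zeros((12, n))
            padded[i] = a[i]
            base_preds.append(np.asarray(classifier(padded)).ravel())
            gen = np.asarray(generator(a[i], i))
            if gen.shape != a.shape:
                raise ValueError(f"generator returned {gen.shape}, expected {a.shape}")
            gen_preds.append(np.asarray(classifier(gen)).ravel())
        baseline = _score(base_preds)
        generated = _score(gen_preds)
        per_lead[i] = {"baseline": baseline, "generated": generated,
                       "gain": gain(generated, baseline)}
    return {"reference": reference, "per_lead": per_lead, "classes": classes}


def report_to_frame(result: dict) -> pd.DataFrame:
    """Flatten an :func:`evaluate_diagnostic` result into the table layout of
    the published diagnostic comparison (reference row, then per input lead:
    baseline, generated, gain)."""
    from .io_windowing import LEAD_NAMES

    rows = {}
    rows["Original 12-lead"] = list(result["reference"].macro)
    for i, entry in result["per_lead"].items():
        name = LEAD_NAMES[i]
        rows[name] = list(entry["baseline"].macro)
        rows[f"Generated+{name}"] = list(entry["generated"].macro)
        rows[f"GAIN+{name}"] = list(entry["gain"])
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["Pre", "Rec", "Spe", "F1"])
    df.index.name = "Input"
    return df
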