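"""Confusion matrix and the six performance criteria.

The positive class is COPD (label 1). Counts follow the convention rows =
actual, columns = predicted. The criteria reported per model are:

* sensitivity  = TP / (TP + FN)                 (proportion)
* specificity  = TN / (TN + FP)                 (proportion)
* accuracy     = 100 * (TP + TN) / N            (percent)
* Cohen kappa  = (p_o - p_e) / (1 - p_e) with
  p_o = (TP+TN)/N, p_e = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / N^2
* F-measure    = F1, harmonic mean of precision and sensitivity
* AUC          = Mann-Whitney rank statistic of the scores
  (ties credited 0.5)

Accuracy is on the percent scale while the other criteria are proportions;
this mixed convention is deliberate and matches the reporting format the
tool mirrors. Kappa is interpreted through the conventional agreement
bands (see ``KAPPA_BANDS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import SchemaError, UndefinedMetric

KAPPA_BANDS = (
    (0.81, "Very good compatibility"),
    (0.61, "Good compatibility"),
    (0.41, "Moderate compliance"),
    (0.21, "Low level of compliance"),
    (0.00, "Poor fit"),
    (-np.inf, "Very poor fit"),
)


def kappa_band(kappa: float) -> str:
    """Agreement-band label for a kappa value in [-1, 1]."""
    for lower, label in KAPPA_BANDS:
        if kappa >= lower:
            return label
    return "Very poor fit"  # pragma: no cover — -inf band always matches


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0 or v != int(v):
                raise ValueError("confusion counts must be non-negative ints")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with positive class = 1 (COPD)."""
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    if t.shape != p.shape:
        raise SchemaError("y_true and y_pred differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


@dataclass
class PerformanceReport:
    sensitivity: float
    specificity: float
    accuracy: float           # percent
    kappa: float
    f_measure: float
    auc: float
    kappa_band: str
    f_measure_defined: bool = True
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Accuracy": self.accuracy,
            "Kappa": self.kappa,
            "F-measure": self.f_measure,
            "AUC": self.auc,
        }


def criteria(cm: ConfusionMatrix, scores=None, y_true=None) -> PerformanceReport:
    """All six criteria from a confusion matrix (+ scores for AUC).

    Without scores, AUC falls back to the hard-label ROC point estimate
    (balanced accuracy as a proportion), flagged in ``extras``.
    """
    n = cm.total
    if n == 0:
        raise UndefinedMetric("empty confusion matrix")
    pos = cm.tp + cm.fn
    neg = cm.fp + cm.tn
    if pos == 0 or neg == 0:
        raise UndefinedMetric("kappa and AUC need both classes in the truth")

    sens = cm.tp / pos
    spec = cm.tn / neg
    acc = 100.0 * (cm.tp + cm.tn) / n
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp)
           + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n ** 2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 0.0

    f_defined = (cm.tp + cm.fp) > 0
    if f_defined:
        precision = cm.tp / (cm.tp + cm.fp)
        f1 = (0.0 if precision + sens == 0.0
              else 2.0 * precision * sens / (precision + sens))
    else:
        f1 = 0.0

    extras = {}
    if scores is not None:
        if y_true is None:
            raise SchemaError("scores given without matching y_true")
        auc = float(roc_auc_score(np.asarray(y_true).astype(int),
                                  np.asarray(scores, dtype=float)))
    else:
        auc = (sens + spec) / 2.0
        extras["auc_from_hard_labels"] = True

    return PerformanceReport(
        sensitivity=sens, specificity=spec, accuracy=acc, kappa=kappa,
        f_measure=f1, auc=auc, kappa_band=kappa_band(kappa),
        f_measure_defined=f_defined, extras=extras)


def evaluate_predictions(y_true, y_pred, scores=None) -> PerformanceReport:
    """Convenience: confusion + criteria in one call."""
    return criteria(confusion(y_true, y_pred), scores=scores, y_true=y_true)


REPORT_COLUMNS = ("Sensitivity", "Specificity", "Accuracy",
                  "Kappa", "F-measure", "AUC")


def report_table(reports: dict) -> pd.DataFrame:
    """Flatten {(pool, level, model): report} into a fixed-column table.

    ``level`` None means the all-features protocol (no selection).
    """
    if not reports:
        raise ValueError("no reports to tabulate")
    rows = []
    for (pool, level, model), rep in reports.items():
        row = {"pool": pool,
               "level": "all" if level is None else int(level),
               "model": model}
        row.update(rep.as_row())
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["pool", "level", "model", *REPORT_COLUMNS]]
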