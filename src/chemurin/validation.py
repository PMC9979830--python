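"""Leave-one-out cross-validation, confusion accounting and screening metrics.

Percentages are reported to one decimal, rounding half away from zero
(36.36 -> 36.4).  Ratios with zero denominators are flagged as undefined
(None / "NA"), never coerced to 0 or 100.  The random-chance accuracy of a
binary screen is reported as ``50% [lo, hi]`` where lo and hi are the
accuracies of the degenerate all-positive and all-negative classifiers given
the class prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import fit_dapc_pipeline
from .errors import OrphanClassError, UndefinedMetricError
from .preprocess import preprocess_pipeline


def round_half_away(x, decimals=1):
    """Round half away from zero (the convention used for reported metrics)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _pct(numerator, denominator):
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def _fmt(value, decimals=1):
    return "NA" if value is None else f"{round_half_away(value, decimals):.{decimals}f}"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts against a declared positive label."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: str = "positive"

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_labels(cls, true_labels, predicted_labels, positive_label):
        t = np.asarray(true_labels)
        p = np.asarray(predicted_labels)
        if t.shape != p.shape:
            raise ValueError("label vectors must be aligned and equal length")
        pos = t == positive_label
        hit = p == positive_label
        return cls(
            tp=int(np.sum(pos & hit)),
            fp=int(np.sum(~pos & hit)),
            fn=int(np.sum(pos & ~hit)),
            tn=int(np.sum(~pos & ~hit)),
            positive_label=str(positive_label),
        )

    @property
    def n(self):
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self):
        return self.tp + self.fn

    @property
    def n_negative(self):
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricPanel:
    """Accuracy / sensitivity / specificity / PPV / NPV, as percentages.

    Values are exact (unrounded); ``rounded()`` applies the 1-decimal
    half-away-from-zero reporting convention.  Undefined metrics are None.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def __post_init__(self):
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 100]")

    def rounded(self, decimals=1):
        return {
            name: (None if getattr(self, name) is None
                   else round_half_away(getattr(self, name), decimals))
            for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        }

    def __str__(self):
        r = self.rounded()
        return (
            f"accuracy {_fmt(self.accuracy)}% | sensitivity {_fmt(self.sensitivity)}% | "
            f"specificity {_fmt(self.specificity)}% | PPV {_fmt(self.ppv)}% | "
            f"NPV {_fmt(self.npv)}%"
        )


def metrics_from_confusion(cm):
    """Metric panel from binary confusion counts.

    accuracy = (tp+tn)/n, sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    PPV = tp/(tp+fp), NPV = tn/(tn+fn); all as percentages, None when the
    denominator is zero.
    """
    if cm.n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return MetricPanel(
        accuracy=_pct(cm.tp + cm.tn, cm.n),
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        ppv=_pct(cm.tp, cm.tp + cm.fp),
        npv=_pct(cm.tn, cm.tn + cm.fn),
    )


@dataclass(frozen=True)
class ChanceBounds:
    """Random-chance accuracy bracket for a binary screen.

    ``all_positive_bound`` is the accuracy of always predicting positive
    (100 * n_pos / n_total); ``all_negative_bound`` likewise for negative.
    The two bounds sum to exactly 100 before rounding.
    """

    n_pos: int
    n_total: int
    nominal: float = 50.0

    def __post_init__(self):
        if not 0 < self.n_pos < self.n_total:
            raise ValueError(
                f"degenerate composition: n_pos={self.n_pos} of n_total={self.n_total}"
            )

    @property
    def all_positive_bound(self):
        return 100.0 * self.n_pos / self.n_total

    @property
    def all_negative_bound(self):
        return 100.0 * (self.n_total - self.n_pos) / self.n_total

    def render(self, decimals=1):
        lo = round_half_away(self.all_positive_bound, decimals)
        hi = round_half_away(self.all_negative_bound, decimals)
        return f"50% [{lo:.{decimals}f}, {hi:.{decimals}f}]"


def chance_bounds(n_pos, n_total):
    """Chance-accuracy bracket given class prevalence."""
    return ChanceBounds(n_pos=int(n_pos), n_total=int(n_total))


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


def loocv_predict(matrix, labels, retention=0.99, grid=None):
    """Leave-one-out predicted labels for a preprocessed matrix.

    For every sample i the PCA and the DAPC are refit on all samples except
    i (no information leakage through the model), and sample i is then
    classified.  Pre-processing is per-sample, so rows are reused unchanged
    across folds.
    """
    X = np.asarray(matrix, dtype=float)
    labels = list(labels)
    n = X.shape[0]
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise OrphanClassError("LOOCV needs at least 2 classes")
    thin = counts[counts < 2]
    if not thin.empty:
        raise OrphanClassError(
            "class(es) with fewer than 2 samples would be orphaned in a fold: "
            f"{sorted(thin.index)}"
        )
    out = []
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit_dapc_pipeline(X[keep], [labels[j] for j in idx[keep]],
                                  retention=retention, grid=grid)
        pred, _ = model.predict_rows(X[i])
        out.append(pred[0])
    return out


def loocv(sset, preprocess_config=None, retention=0.99):
    """Preprocess a harmonized cohort and run LOOCV; labels in manifest order."""
    matrix, labels, grid = preprocess_pipeline(sset, preprocess_config)
    return loocv_predict(matrix, labels, retention=retention, grid=grid)


# ---------------------------------------------------------------------------
# multiclass reporting


def multiclass_report(true_labels, predicted_labels, classes):
    """Per-class one-vs-rest panels plus overall exact-match accuracy.

    Returns ``(overall_accuracy_pct, {class: MetricPanel})``.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must be aligned and equal length")
    classes = list(classes)
    unseen = sorted(set(p) - set(classes))
    if unseen:
        raise ValueError(f"predicted label(s) outside the class list: {unseen}")
    overall = 100.0 * float(np.mean(t == p))
    panels = {
        c: metrics_from_confusion(ConfusionMatrix.from_labels(t, p, c)) for c in classes
    }
    return overall, panels


# ---------------------------------------------------------------------------
# report writer


def _ratio_fmt(k, n, decimals=1):
    if n == 0:
        return "NA"
    return f"{k}/{n} = {round_half_away(100.0 * k / n, decimals):.{decimals}f}%"


def screen_table(reports):
    """Assemble screening reports into the study-style results table.

    ``reports`` is an iterable of :class:`~chemurin.screening.ScreenReport`
    with truth known.  Columns: target, ISREA nodes, random-chance accuracy,
    prediction accuracy, sensitivity (k/n = p%), specificity (k/n = p%),
    PPV, NPV.
    """
    rows = []
    for r in reports:
        cm = r.confusion
        panel = r.metrics
        rows.append(
            {
                "classification_target": r.name,
                "isrea_nodes": ", ".join(f"{x:g}" for x in r.nodes),
                "random_chance_accuracy": r.chance.render() if r.chance else "NA",
                "prediction_accuracy": _fmt(panel.accuracy) + "%",
                "sensitivity": _ratio_fmt(cm.tp, cm.tp + cm.fn),
                "specificity": _ratio_fmt(cm.tn, cm.tn + cm.fp),
                "ppv": _fmt(panel.ppv) + "%",
                "npv": _fmt(panel.npv) + "%",
            }
        )
    return pd.DataFrame(rows)


def write_report(reports, csv_path=None, txt_path=None):
    """Write the screening table as CSV and/or aligned plain text."""
    table = screen_table(reports)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if txt_path is not None:
        with open(txt_path, "w") as fh:
            fh.write(table.to_string(index=False))
            fh.write("\n")
    return table
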