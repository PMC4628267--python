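"""Evaluation machinery: confusion matrices against binary GoF/LoF
annotations, the restricted sensitivity/specificity/accuracy metrics, a ROC
sweep over the cutoff t, confidence filtering, and the transactivity class
labels used for TP53-style functional data.

Annotation databases typically label mutations only as gain or loss of
function, while the classifier emits four types; following the method's
evaluation protocol, the binary metrics are computed only over variants
*predicted* GoF or LoF (SoF/CoF predictions are excluded), with sensitivity
defined with respect to GoF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SoftClassification, classify_from_probs, gain_probability, loss_probability

ANNOT_LABELS = ("GoF", "LoF")
PRED_LABELS = ("GoF", "LoF", "SoF", "CoF")


class EvaluationError(ValueError):
    pass


def confusion_matrix(annotated: list[str], predicted: list[str]) -> pd.DataFrame:
    """2x4 count table: rows = database annotation (GoF/LoF), columns =
    predicted type (GoF/LoF/SoF/CoF)."""
    if len(annotated) != len(predicted):
        raise EvaluationError("annotation and prediction lists differ in length")
    cm = pd.DataFrame(0, index=list(ANNOT_LABELS), columns=list(PRED_LABELS))
    for a, p in zip(annotated, predicted):
        if a not in ANNOT_LABELS:
            raise EvaluationError(f"invalid annotation label {a!r}")
        if p not in PRED_LABELS:
            raise EvaluationError(f"invalid predicted label {p!r}")
        cm.loc[a, p] += 1
    return cm


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: float | None   # with respect to GoF
    specificity: float | None
    accuracy: float | None
    n_used: int


def binary_metrics(confusion: pd.DataFrame) -> BinaryMetrics:
    """Sensitivity/specificity/accuracy over the predicted-GoF/LoF block only.

    Undefined metrics (zero denominator) are reported as None, never as 0.
    """
    tp = int(confusion.loc["GoF", "GoF"])
    fn = int(confusion.loc["GoF", "LoF"])
    tn = int(confusion.loc["LoF", "LoF"])
    fp = int(confusion.loc["LoF", "GoF"])
    n = tp + fn + tn + fp

    def ratio(num, den):
        return num / den if den else None

    return BinaryMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        accuracy=ratio(tp + tn, n),
        n_used=n,
    )


def roc_over_cutoff(
    score_pairs: list[tuple[float, float]],
    annotations: list[str],
    t_grid: list[float],
) -> tuple[pd.DataFrame, float]:
    """Sweep the cutoff t, classifying every (S0, Sx) pair at each t and
    computing the restricted binary metrics; returns the curve (t,
    sensitivity, 1-specificity) and its trapezoidal AUC.

    Points where either metric is undefined are dropped from the curve; the
    AUC integrates the remaining points anchored at (0,0) and (1,1).
    """
    if not t_grid:
        raise EvaluationError("cutoff grid is empty")
    if not annotations:
        raise EvaluationError("no annotated variants")
    records = []
    for t in t_grid:
        preds = [
            classify_from_probs(loss_probability(s0, t), gain_probability(sx, t), t).predicted
            for s0, sx in score_pairs
        ]
        m = binary_metrics(confusion_matrix(list(annotations), preds))
        if m.sensitivity is None or m.specificity is None:
            continue
        records.append((t, m.sensitivity, 1 - m.specificity))
    curve = pd.DataFrame(records, columns=["t", "sensitivity", "fpr"])
    pts = sorted(
        {(0.0, 0.0), (1.0, 1.0)} | set(zip(curve["fpr"], curve["sensitivity"]))
    )
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    return curve, auc


def filter_by_confidence(
    results: list[SoftClassification], floor: float = 0.5
) -> list[SoftClassification]:
    """Keep only calls whose maximum confidence strictly exceeds the floor."""
    if not 0 <= floor <= 1:
        raise EvaluationError("floor must be in [0, 1]")
    return [
        r for r in results
        if r.max_confidence is not None and r.max_confidence > floor
    ]


def transactivity_class(median_activity: float) -> str:
    """TP53-style functional label from median promoter-specific activity.

    <20: nonfunctional; [20,75): partially functional; [75,140): functional;
    >=140: supertrans.  Boundary values go to the upper-adjacent class.
    """
    if median_activity < 0:
        raise EvaluationError("median activity must be nonnegative")
    if median_activity < 20:
        return "nonfunctional"
    if median_activity < 75:
        return "partially functional"
    if median_activity < 140:
        return "functional"
    return "supertrans"


def read_annotations(path) -> dict[str, str]:
    """Read a two-column TSV (variant, label)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                variant, label = line.rstrip("\n").split("\t")[:2]
                out[variant] = label
    return out


def summary_block(cm: pd.DataFrame, metrics: BinaryMetrics) -> str:
    def pct(v):
        return "undefined" if v is None else f"{100 * v:.1f} %"

    return (
        "confusion matrix (rows: annotation, columns: prediction)\n"
        + cm.to_string()
        + f"\nsensitivity (wrt GoF): {pct(metrics.sensitivity)}"
        + f"\nspecificity:           {pct(metrics.specificity)}"
        + f"\naccuracy:              {pct(metrics.accuracy)}"
        + f"\nn used (predicted GoF/LoF): {metrics.n_used}\n"
    )
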