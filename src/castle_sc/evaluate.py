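"""Evaluation measures: accuracy, per-type binary metrics, majority vote.

Accuracy is the percentage of cells classified correctly. Ground-truth
labels marking a cell as unusable (unknown / not applicable /
unclassified / contaminated) are skipped by default, since they are not
real ground truth. Per-type quality uses sensitivity, specificity,
precision and the ROC AUC; the AUC is computed by the rank
(Mann-Whitney) formulation with ties averaged, so it equals the
probability that a random positive outranks a random negative.

Note on naming: some reports call precision (TP / predicted-positive)
"specificity". Both are computed here under their textbook names;
``paper_style=True`` in :func:`evaluation_report` relabels the precision
column "specificity" for comparison against such reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._errors import InputError
from .core_data import DEFAULT_EXCLUDED_LABELS, is_excluded_label

__all__ = [
    "accuracy",
    "binary_metrics",
    "majority_vote_accuracy",
    "confusion_matrix",
    "EvaluationReport",
    "evaluation_report",
]


def accuracy(
    truth,
    predicted,
    excluded=DEFAULT_EXCLUDED_LABELS,
    include_excluded: bool = False,
) -> float:
    """Percentage of cells whose predicted label matches the truth.

    Cells whose true label is in the excluded set are omitted from the
    denominator unless ``include_excluded``; an ``"unknown"`` prediction
    counts as correct only when the truth itself is excluded.
    """
    truth = [str(t) for t in truth]
    predicted = [str(p) for p in predicted]
    if len(truth) != len(predicted):
        raise InputError(f"{len(truth)} truths vs {len(predicted)} predictions")
    if not truth:
        raise InputError("empty label vectors")
    pairs = list(zip(truth, predicted))
    if not include_excluded:
        pairs = [(t, p) for t, p in pairs if not is_excluded_label(t, excluded)]
        if not pairs:
            raise InputError("no evaluable cells: every true label is excluded")
    hits = sum(
        1
        for t, p in pairs
        if p == t or (p == "unknown" and is_excluded_label(t, excluded))
    )
    return 100.0 * hits / len(pairs)


def binary_metrics(
    truth_indicator, scores, cut: float = 0.5
) -> dict[str, float | None]:
    """Sensitivity, specificity, precision (at ``cut``) and AUC, as percents.

    Ratios with an empty denominator are reported as ``None``. The AUC is
    the tie-corrected Mann-Whitney statistic over all positive/negative
    score pairs.
    """
    y = np.asarray(truth_indicator, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1 or y.size == 0:
        raise InputError("indicator and scores must be equal-length 1-D vectors")
    if not np.isin(y, (0, 1)).all():
        raise InputError("truth indicator must be 0/1")
    if s.min() < 0 or s.max() > 1:
        raise InputError("scores must lie in [0, 1]")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InputError("binary metrics need both positive and negative instances")

    pred = s >= cut
    tp = int(np.sum(pred & (y == 1)))
    fn = n_pos - tp
    fp = int(np.sum(pred & (y == 0)))
    tn = n_neg - fp

    def pct(num, den):
        return 100.0 * num / den if den else None

    # Mann-Whitney AUC: mean rank of positives, ties averaged
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "precision": pct(tp, tp + fp),
        "auc": 100.0 * float(auc),
    }


def majority_vote_accuracy(source_labels, target_labels) -> float:
    """Accuracy of labeling every target cell with the source's modal class.

    Ties for the source majority break lexicographically.
    """
    source_labels = [str(l) for l in source_labels]
    target_labels = [str(l) for l in target_labels]
    if not source_labels or not target_labels:
        raise InputError("label vectors must be nonempty")
    counts: dict[str, int] = {}
    for l in source_labels:
        counts[l] = counts.get(l, 0) + 1
    majority = min(counts, key=lambda c: (-counts[c], c))
    share = sum(1 for l in target_labels if l == majority) / len(target_labels)
    return 100.0 * share


def confusion_matrix(truth, predicted) -> pd.DataFrame:
    """Types x types count table (rows = truth, columns = predicted)."""
    truth = pd.Series([str(t) for t in truth], name="truth")
    predicted = pd.Series([str(p) for p in predicted], name="predicted")
    if len(truth) != len(predicted):
        raise InputError("length mismatch between truth and predictions")
    labels = sorted(set(truth) | set(predicted))
    tab = pd.crosstab(truth, predicted)
    return tab.reindex(index=labels, columns=labels, fill_value=0)


@dataclass
class EvaluationReport:
    """Overall accuracy plus per-type binary metrics and the confusion table."""

    accuracy_pct: float
    per_type: pd.DataFrame  # one row per type
    confusion: pd.DataFrame


def evaluation_report(
    truth,
    predicted,
    scores=None,
    excluded=DEFAULT_EXCLUDED_LABELS,
    include_excluded: bool = False,
    paper_style: bool = False,
) -> EvaluationReport:
    """Full report: accuracy, per-type sensitivity/specificity/precision/AUC.

    ``scores`` may be a ScoreMatrix-like object (``.scores``, ``.type_ids``)
    supplying per-type membership scores for the AUC; without it only
    threshold-free columns derived from hard labels are reported.
    ``paper_style`` renames the precision column "specificity".
    """
    truth = [str(t) for t in truth]
    predicted = [str(p) for p in predicted]
    acc = accuracy(truth, predicted, excluded=excluded, include_excluded=include_excluded)
    conf = confusion_matrix(truth, predicted)

    types = sorted(set(truth) | set(predicted) - {"unknown"})
    rows = []
    t_arr = np.asarray(truth)
    p_arr = np.asarray(predicted)
    for t in types:
        y = (t_arr == t).astype(int)
        pred = (p_arr == t).astype(int)
        tp = int(np.sum((y == 1) & (pred == 1)))
        fn = int(np.sum((y == 1) & (pred == 0)))
        fp = int(np.sum((y == 0) & (pred == 1)))
        tn = int(np.sum((y == 0) & (pred == 0)))
        sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
        spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
        prec = 100.0 * tp / (tp + fp) if (tp + fp) else None
        auc = None
        if scores is not None and t in getattr(scores, "type_ids", []):
            col = scores.scores[:, scores.type_ids.index(t)]
            if 0 < y.sum() < len(y):
                auc = binary_metrics(y, col)["auc"]
        rows.append(
            {
                "type": t,
                "n_truth": int(y.sum()),
                "sensitivity_pct": sens,
                "specificity_pct": spec,
                "precision_pct": prec,
                "auc_pct": auc,
            }
        )
    per_type = pd.DataFrame(rows).set_index("type") if rows else pd.DataFrame()
    if paper_style and len(per_type):
        per_type = per_type.drop(columns=["specificity_pct"]).rename(
            columns={"precision_pct": "specificity_pct"}
        )
    return EvaluationReport(acc, per_type, conf)
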