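"""Multi-class evaluation metrics and ANOVA-F feature importances.

Threshold metrics (accuracy, per-class precision/recall/F1 with macro and
class-frequency-weighted averages, Cohen's kappa) are computed from the
confusion matrix via scikit-learn.  One-vs-rest ROC-AUC uses the rank
(Mann-Whitney) formulation with ties credited 0.5, which is analytically
identical to trapezoidal integration of the ROC curve but stable when the
classifier emits few distinct probability values; macro AUC is the
unweighted mean over classes.  Feature importances are classical one-way
ANOVA F statistics, F = (ss_between/(m-1)) / (ss_within/(N-m)).

Per-class metrics with a zero denominator are reported as 0 with a warning.
Metrics are stored as fractions in [0, 1]; rendering helpers format them as
percentages with two decimals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .fuzzy import CLASS_ORDER

__all__ = [
    "confusion_and_metrics",
    "ovr_roc_auc",
    "anova_f_scores",
    "format_percent",
    "report_to_text",
]


def format_percent(x: float) -> str:
    """Render a fraction as a percentage with two decimals, e.g. 0.915 -> '91.50%'."""
    return f"{100.0 * x:.2f}%"


def confusion_and_metrics(y_true, y_pred, classes=None):
    """Confusion matrix plus threshold metrics.

    Returns ``(confusion, report)`` where ``confusion`` is an m x m DataFrame
    (true class by row, predicted by column) and ``report`` a dict with
    accuracy, kappa, per-class precision/recall/f1/support and macro /
    weighted averages.  Kappa is (p_o - p_e)/(1 - p_e) with chance agreement
    from the marginal products.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)

    n = cm.sum()
    accuracy = float(np.trace(cm)) / n
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    if (pred_tot == 0).any() or (true_tot == 0).any():
        warnings.warn("zero denominator in per-class precision/recall; reported as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    support = true_tot
    w = support / n
    kappa = float(cohen_kappa_score(y_true, y_pred, labels=classes))
    report = {
        "accuracy": accuracy,
        "kappa": kappa,
        "per_class": {
            str(c): {
                "precision": float(precision[i]),
                "recall": float(recall[i]),
                "f1": float(f1[i]),
                "support": int(support[i]),
            }
            for i, c in enumerate(classes)
        },
        "macro": {
            "precision": float(precision.mean()),
            "recall": float(recall.mean()),
            "f1": float(f1.mean()),
        },
        "weighted": {
            "precision": float(precision @ w),
            "recall": float(recall @ w),
            "f1": float(f1 @ w),
        },
    }
    return confusion, report


def _rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties credited 0.5 (average ranks)."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def ovr_roc_auc(P, y, classes=CLASS_ORDER) -> dict:
    """One-vs-rest AUC per class plus their unweighted (macro) mean.

    ``P`` is an n x m score matrix (column order = ``classes``).  Each class
    must have at least one positive and one negative in the dichotomy.
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(y)
    per_class = {}
    for i, cls in enumerate(classes):
        labels = (y == cls).astype(int)
        if labels.sum() == 0 or labels.sum() == len(labels):
            raise ValueError(f"AUC undefined for class {cls!r}: one-class dichotomy")
        per_class[str(cls)] = _rank_auc(P[:, i], labels)
    return {
        "per_class": per_class,
        "macro": float(np.mean(list(per_class.values()))),
    }


def anova_f_scores(X, y) -> pd.DataFrame:
    """One-way ANOVA F statistic per feature across the class labels.

    Returns a DataFrame indexed by feature with ``F, ss_between, ss_within,
    df_between, df_within`` and an ``infinite`` flag where the within-class
    variance is zero with nonzero between-class spread.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    m, N = len(classes), len(y)
    if m < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    if N <= m:
        raise ValueError(f"need more samples ({N}) than classes ({m})")
    rows = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        mu = v.mean()
        ss_b = ss_w = 0.0
        for cls in classes:
            grp = v[y == cls]
            ss_b += len(grp) * (grp.mean() - mu) ** 2
            ss_w += float(((grp - grp.mean()) ** 2).sum())
        df_b, df_w = m - 1, N - m
        if ss_w == 0.0:
            F = np.inf if ss_b > 0 else 0.0
        else:
            F = (ss_b / df_b) / (ss_w / df_w)
        rows.append(
            {
                "feature": col,
                "F": F,
                "ss_between": ss_b,
                "ss_within": ss_w,
                "df_between": df_b,
                "df_within": df_w,
                "infinite": bool(np.isinf(F)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def report_to_text(report: dict, auc: dict | None = None, title: str = "") -> str:
    """Human-readable rendering of an evaluation report (percent format)."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    lines.append(f"accuracy : {format_percent(report['accuracy'])}")
    lines.append(f"kappa    : {format_percent(report['kappa'])}")
    lines.append(f"{'class':<8}{'precision':>11}{'recall':>9}{'f1':>9}{'support':>9}")
    for cls, r in report["per_class"].items():
        lines.append(
            f"{cls:<8}{format_percent(r['precision']):>11}"
            f"{format_percent(r['recall']):>9}{format_percent(r['f1']):>9}"
            f"{r['support']:>9d}"
        )
    for avg in ("macro", "weighted"):
        r = report[avg]
        lines.append(
            f"{avg:<8}{format_percent(r['precision']):>11}"
            f"{format_percent(r['recall']):>9}{format_percent(r['f1']):>9}"
        )
    if auc is not None:
        aucs = ", ".join(f"{c}: {v:.3f}" for c, v in auc["per_class"].items())
        lines.append(f"one-vs-rest AUC  {aucs}")
        lines.append(f"macro AUC: {format_percent(auc['macro'])}")
    return "\n".join(lines)
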