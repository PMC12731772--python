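"""Thin optional plotting helpers (require matplotlib)."""

from __future__ import annotations

import numpy as np

from .fuzzy import CLASS_ORDER


def plot_association_heatmap(matrix, ax=None):
    """Heatmap of a pairwise Cramér's V matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.figure.colorbar(im, ax=ax, label="Cramér's V")
    return ax


def plot_ovr_roc(P, y, classes=CLASS_ORDER, ax=None):
    """One-vs-rest ROC curves per class."""
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    if ax is None:
        _, ax = plt.subplots()
    P = np.asarray(P, dtype=float)
    y = np.asarray(y)
    for i, cls in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == cls).astype(int), P[:, i])
        ax.plot(fpr, tpr, label=f"class {cls}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend()
    return ax
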