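"""Per-class monotone-spline calibration of classifier probabilities.

For each class ``i`` (one-vs-all) the raw predicted probabilities are sorted,
fitted by pool-adjacent-violators (PAV) isotonic regression against the
binary indicator labels, and the pooled-block solution is smoothed by a
monotonicity-preserving piecewise-cubic Hermite interpolant (PCHIP) through
the block nodes.  The per-class maps ``F_i`` are then combined row-wise and
renormalized onto the probability simplex:

    P~_i = F_i(P^_i) / sum_j F_j(P^_j)

so every calibrated row sums to exactly 1.  Monotonicity guarantees that
within a class the calibrated scores preserve the ranking of the raw scores.

Numerical choices: tied raw probabilities are pooled before fitting;
evaluation outside the observed probability range extrapolates as a
constant at the boundary node values; spline outputs are clamped to [0, 1];
a row on which every per-class map evaluates to ~0 falls back to the
uniform vector with a warning (the renormalization is undefined there).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .fuzzy import CLASS_ORDER

__all__ = [
    "one_vs_all_labels",
    "pav_isotonic",
    "MonotoneSpline",
    "fit_monotone_spline",
    "CalibrationModel",
    "fit_calibration",
    "apply_calibration",
]

_FALLBACK_EPS = 1e-12


def one_vs_all_labels(y, cls) -> np.ndarray:
    """Binary indicator vector: 1 where ``y`` equals ``cls``."""
    y = np.asarray(y)
    return (y == cls).astype(float)


def pav_isotonic(p, y, w=None) -> np.ndarray:
    """Least-squares non-decreasing fit of ``y`` on sorted ``p``.

    Pool-adjacent-violators: maintains a stack of blocks (weighted means)
    and merges any adjacent pair that violates monotonicity.  ``p`` must be
    sorted ascending; the returned array is piecewise constant over the
    pooled blocks.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("p and y must have equal length")
    if np.any(np.diff(p) < 0):
        raise ValueError("p must be sorted ascending")
    if w is None:
        w = np.ones_like(y)
    # blocks of (value, weight, count)
    values, weights, counts = [], [], []
    for yi, wi in zip(y, w):
        values.append(float(yi))
        weights.append(float(wi))
        counts.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            v2, w2, c2 = values.pop(), weights.pop(), counts.pop()
            v1, w1, c1 = values.pop(), weights.pop(), counts.pop()
            wt = w1 + w2
            values.append((v1 * w1 + v2 * w2) / wt)
            weights.append(wt)
            counts.append(c1 + c2)
    return np.repeat(values, counts)


@dataclass
class MonotoneSpline:
    """Monotone map on [0, 1]: PCHIP through PAV block nodes.

    ``node_x`` are block-mean raw probabilities (strictly increasing),
    ``node_y`` the corresponding PAV block values (non-decreasing).
    Evaluation clamps the argument into the node range (constant
    extrapolation) and the output into [0, 1].
    """

    node_x: np.ndarray
    node_y: np.ndarray

    def __post_init__(self):
        self.node_x = np.asarray(self.node_x, dtype=float)
        self.node_y = np.asarray(self.node_y, dtype=float)
        if self.node_x.size == 1:
            self._interp = None
        else:
            self._interp = PchipInterpolator(self.node_x, self.node_y)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.node_x[0], self.node_x[-1])
        if self._interp is None:
            out = np.full_like(xc, self.node_y[0])
        else:
            out = self._interp(xc)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"node_x": self.node_x.tolist(), "node_y": self.node_y.tolist()}

    @classmethod
    def from_dict(cls, d) -> "MonotoneSpline":
        return cls(np.asarray(d["node_x"]), np.asarray(d["node_y"]))


def fit_monotone_spline(p_sorted, y_sorted) -> MonotoneSpline:
    """Fit the monotone calibration map for one class.

    Steps: pool tied abscissae, run PAV, collapse each pooled block to a
    (weighted-mean p, block value) node, interpolate the nodes with PCHIP.
    Inputs must already be sorted by ``p`` and contain at least 2 points.
    """
    p = np.asarray(p_sorted, dtype=float)
    y = np.asarray(y_sorted, dtype=float)
    if p.size != y.size:
        raise ValueError("p and y must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 points to fit a calibration map")
    if np.any(np.diff(p) < 0):
        raise ValueError("inputs must be sorted ascending by p")
    # pool exact ties in p
    uniq, inverse, counts = np.unique(p, return_inverse=True, return_counts=True)
    y_mean = np.bincount(inverse, weights=y) / counts
    fit = pav_isotonic(uniq, y_mean, w=counts.astype(float))
    # collapse PAV blocks (runs of equal fitted value) to single nodes
    node_x, node_y = [], []
    i = 0
    while i < len(uniq):
        j = i
        while j + 1 < len(uniq) and fit[j + 1] == fit[i]:
            j += 1
        block_w = counts[i : j + 1].astype(float)
        node_x.append(float(np.average(uniq[i : j + 1], weights=block_w)))
        node_y.append(float(fit[i]))
        i = j + 1
    return MonotoneSpline(np.asarray(node_x), np.asarray(node_y))


@dataclass
class CalibrationModel:
    """One fitted monotone spline per class, in a fixed class order."""

    splines: dict
    classes: tuple = CLASS_ORDER

    def to_json(self, path=None) -> str:
        payload = {
            "classes": list(self.classes),
            "splines": {str(c): self.splines[c].to_dict() for c in self.classes},
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        classes = tuple(payload["classes"])
        splines = {
            c: MonotoneSpline.from_dict(payload["splines"][str(c)]) for c in classes
        }
        return cls(splines=splines, classes=classes)


def fit_calibration(P, y, classes=CLASS_ORDER) -> CalibrationModel:
    """Fit one one-vs-all monotone spline per class.

    ``P`` is the n x m row-stochastic raw probability matrix; ``y`` the true
    class labels.  Every class must appear at least twice.
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(y)
    if P.shape[0] != y.shape[0]:
        raise ValueError("P and y must have equal length")
    if P.shape[1] != len(classes):
        raise ValueError("P has wrong number of columns for the class order")
    splines = {}
    for i, cls in enumerate(classes):
        labels = one_vs_all_labels(y, cls)
        if labels.sum() < 2:
            raise ValueError(f"class {cls!r} present fewer than 2 times")
        order = np.argsort(P[:, i], kind="stable")
        splines[cls] = fit_monotone_spline(P[order, i], labels[order])
    return CalibrationModel(splines=splines, classes=tuple(classes))


def apply_calibration(model: CalibrationModel, P) -> np.ndarray:
    """Calibrate a raw probability matrix and renormalize onto the simplex.

    Rows whose per-class spline outputs all vanish fall back to the uniform
    vector (with a warning): the normalization is undefined there.
    """
    P = np.asarray(P, dtype=float)
    m = len(model.classes)
    if P.ndim != 2 or P.shape[1] != m:
        raise ValueError(f"expected an n x {m} probability matrix")
    F = np.column_stack(
        [model.splines[cls](P[:, i]) for i, cls in enumerate(model.classes)]
    )
    sums = F.sum(axis=1)
    degenerate = sums < _FALLBACK_EPS
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} row(s) with vanishing calibrated mass; "
            "uniform fallback applied"
        )
        F[degenerate] = 1.0 / m
        sums[degenerate] = 1.0
    return F / sums[:, None]
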