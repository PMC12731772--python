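"""Fuzzy S-membership risk scoring and A-D class-band assignment.

Non-diabetic records are graded on a continuous risk score: the six scored
lifestyle features (age, urination, thirst, weight, height, fatigue) are
min-max normalized to [0, 1], combined into a convex composite score, and
passed through the piecewise-quadratic S-shaped membership function

    mu(x; a, b) = 0                          for x <= a
                  2((x-a)/(b-a))^2           for a <= x <= (a+b)/2
                  1 - 2((x-b)/(b-a))^2       for (a+b)/2 <= x <= b
                  1                          for x >= b

where ``a`` and ``b`` are the endpoints of the inclined segment.  The
membership value maps to ordered risk bands A (low), B (moderate),
C (high); a diagnosed record (outcome 1) is forced to mu = 1 and class D.

Default composite weights are proportional to the published Cramér's V
effect sizes of the six features, so the score follows the study's own
association ordering.  The bands are contiguous half-open intervals
A = [0, 0.4), B = [0.4, 0.7), C = [0.7, 1), D = {1}, which cover [0, 1]
without gaps while reproducing every published (membership, class) example.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SMFParams",
    "RiskBands",
    "FeatureScaler",
    "smf",
    "composite_score",
    "assign_class",
    "label_table",
    "SCORED_FEATURES",
    "DEFAULT_WEIGHTS",
    "CLASS_ORDER",
]

CLASS_ORDER = ("A", "B", "C", "D")

#: Features entering the composite risk score.
SCORED_FEATURES = ("age", "urination", "thirst", "weight", "height", "fatigue")

# published association effect sizes for the six scored features, renormalized
_V = {"age": 0.52, "urination": 0.79, "thirst": 0.43,
      "weight": 0.33, "height": 0.21, "fatigue": 0.64}
DEFAULT_WEIGHTS = {k: v / sum(_V.values()) for k, v in _V.items()}


@dataclass(frozen=True)
class SMFParams:
    """Knots of the inclined segment of the S-membership function."""

    a: float = 0.1
    b: float = 0.9

    def __post_init__(self):
        if not self.a < self.b:
            raise ValueError(f"SMF requires a < b, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class RiskBands:
    """Half-open membership bands A=[0,b1), B=[b1,b2), C=[b2,1), D={1}."""

    moderate: float = 0.4
    high: float = 0.7

    def __post_init__(self):
        if not 0.0 < self.moderate < self.high < 1.0:
            raise ValueError("bands require 0 < moderate < high < 1")


def smf(x, params: SMFParams = SMFParams()):
    """S-shaped membership function; accepts scalars or arrays."""
    a, b = params.a, params.b
    x = np.asarray(x, dtype=float)
    mid = (a + b) / 2.0
    r = b - a
    mu = np.where(
        x <= a,
        0.0,
        np.where(
            x <= mid,
            2.0 * ((x - a) / r) ** 2,
            np.where(x <= b, 1.0 - 2.0 * ((x - b) / r) ** 2, 1.0),
        ),
    )
    return float(mu) if mu.ndim == 0 else mu


class FeatureScaler:
    """Min-max scaler with pass-through of binary columns.

    Stores the observed per-column minimum and maximum at fit time so that
    the identical mapping is applied at prediction time.  A constant
    non-binary column cannot be scaled and raises naming the column.
    """

    def __init__(self):
        self.bounds_: dict[str, tuple[float, float]] | None = None

    def fit(self, table: pd.DataFrame, columns) -> "FeatureScaler":
        bounds = {}
        for col in columns:
            vals = table[col].to_numpy(dtype=float)
            uniq = np.unique(vals)
            if set(uniq.tolist()) <= {0.0, 1.0}:
                bounds[col] = (0.0, 1.0)
                continue
            lo, hi = float(vals.min()), float(vals.max())
            if lo == hi:
                raise ValueError(f"cannot min-max scale constant column '{col}'")
            bounds[col] = (lo, hi)
        self.bounds_ = bounds
        return self

    @property
    def columns(self):
        self._check_fitted()
        return list(self.bounds_)

    def _check_fitted(self):
        if self.bounds_ is None:
            raise RuntimeError("scaler is not fitted")

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        out = {}
        for col, (lo, hi) in self.bounds_.items():
            out[col] = np.clip((table[col].to_numpy(dtype=float) - lo) / (hi - lo), 0.0, 1.0)
        return pd.DataFrame(out, index=table.index)

    def fit_transform(self, table, columns):
        return self.fit(table, columns).transform(table)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {k: list(v) for k, v in self.bounds_.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        sc = cls()
        sc.bounds_ = {k: (float(v[0]), float(v[1])) for k, v in d.items()}
        return sc


def composite_score(normalized: pd.DataFrame, weights: dict | None = None):
    """Convex combination of normalized scored features.

    ``weights`` maps feature name to a nonnegative weight; weights must sum
    to 1 and cover exactly the scored columns present in ``normalized``.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    cols = list(weights)
    missing = [c for c in cols if c not in normalized.columns]
    if missing:
        raise ValueError(f"weight/feature mismatch; missing columns {missing}")
    w = np.asarray([weights[c] for c in cols], dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    return normalized[cols].to_numpy(dtype=float) @ w


def assign_class(mu, outcome, bands: RiskBands = RiskBands()):
    """Map membership values (and diagnosed outcomes) to classes A-D.

    ``outcome == 1`` overrides to class D regardless of the score; otherwise
    A for mu < moderate, B below high, C below 1, and D at exactly 1.
    """
    mu_arr = np.asarray(mu, dtype=float)
    scalar = mu_arr.ndim == 0
    mu_arr = np.atleast_1d(mu_arr)
    outcome = np.atleast_1d(np.asarray(outcome, dtype=int))
    if ((mu_arr < 0) | (mu_arr > 1)).any():
        raise ValueError("membership values must lie in [0, 1]")
    cls = np.where(
        outcome == 1,
        "D",
        np.where(
            mu_arr < bands.moderate,
            "A",
            np.where(mu_arr < bands.high, "B", np.where(mu_arr < 1.0, "C", "D")),
        ),
    )
    return cls.item() if scalar else cls


def label_table(
    table: pd.DataFrame,
    smf_params: SMFParams = SMFParams(),
    weights: dict | None = None,
    bands: RiskBands = RiskBands(),
) -> tuple[pd.DataFrame, FeatureScaler]:
    """Full labeling pass: normalize, score, fuzzify, assign classes.

    Returns the labeled table (normalized scored features, outcome,
    ``fuzzified_value``, ``risk_class``) together with the fitted scaler.
    Diagnosed records are forced to membership 1 / class D after scoring.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    scaler = FeatureScaler().fit(table, list(weights))
    normalized = scaler.transform(table)
    x = composite_score(normalized, weights)
    mu = smf(x, smf_params)
    outcome = table["outcome"].to_numpy(dtype=int)
    mu = np.where(outcome == 1, 1.0, mu)
    cls = assign_class(mu, outcome, bands)
    out = normalized.copy()
    out["outcome"] = outcome
    out["fuzzified_value"] = mu
    out["risk_class"] = cls
    return out, scaler
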