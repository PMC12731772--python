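"""Exploratory analysis of a lifestyle cohort.

Descriptive statistics (count / mean / SD / quartiles / extremes per column),
age-band prevalence, data-quality checks (missing cells, duplicate rows,
out-of-range values), IQR outlier screening, and chi-square / Cramér's V
association analysis against the diabetes outcome.

Conventions: percentiles use linear interpolation, SD uses the n-1
denominator, chi-square is computed without continuity correction and
Cramér's V without bias correction, and numeric variables are discretized
into quartile bins before the contingency analysis.  Raw p-values are
compared against α = 0.05 with no multiple-testing correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import VALUE_RANGES

__all__ = [
    "summarize",
    "cohort_prevalence",
    "quality_checks",
    "iqr_outliers",
    "cramers_v",
    "associations",
    "cramers_v_matrix",
]

ALPHA = 0.05

#: Numeric columns discretized into quartile bins for contingency analysis.
NUMERIC_COLUMNS = ("age", "thirst", "urination", "height", "weight")


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column descriptive statistics.

    Returns one row per column with ``count, mean, std, min, 25%, 50%,
    75%, max``.  Quantiles interpolate linearly; ``std`` is the sample
    (n-1) standard deviation.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    return table.describe().T


def cohort_prevalence(table: pd.DataFrame, bands=None) -> pd.DataFrame:
    """Participants, share of total, case count and prevalence per age band.

    ``prevalence`` and ``pct_of_total`` are percentages rounded to one
    decimal.  Bands must be non-overlapping and jointly cover every observed
    age.
    """
    if bands is None:
        from .cohort import CohortConfig

        bands = CohortConfig().age_bands
    bands = sorted(bands)
    for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
        if hi1 >= lo2:
            raise ValueError(f"overlapping age bands ({lo1},{hi1}) and ({lo2},{hi2})")
    age = table["age"].to_numpy()
    outcome = table["outcome"].to_numpy()
    assigned = np.zeros(len(age), dtype=bool)
    rows = []
    n_total = len(table)
    for lo, hi in bands:
        mask = (age >= lo) & (age <= hi)
        assigned |= mask
        participants = int(mask.sum())
        cases = int(outcome[mask].sum())
        rows.append(
            {
                "age_lo": lo,
                "age_hi": hi,
                "participants": participants,
                "pct_of_total": round(100.0 * participants / n_total, 1),
                "cases": cases,
                "prevalence": round(100.0 * cases / participants, 1)
                if participants
                else 0.0,
            }
        )
    if not assigned.all():
        stray = np.unique(age[~assigned])
        raise ValueError(f"ages not covered by any band: {stray.tolist()}")
    return pd.DataFrame(rows)


def quality_checks(table: pd.DataFrame, ranges: dict | None = None) -> dict:
    """Missing-cell, duplicate-row and out-of-range counts.

    Returns ``{"missing": {col: count}, "n_duplicates": int,
    "out_of_range": {col: count}, "clean": bool}``.
    """
    if ranges is None:
        ranges = VALUE_RANGES
    missing = table.isna().sum().to_dict()
    n_dup = int(table.duplicated().sum())
    out_of_range = {}
    for col, (lo, hi) in ranges.items():
        if col not in table.columns:
            continue
        vals = table[col].dropna()
        out_of_range[col] = int(((vals < lo) | (vals > hi)).sum())
    clean = (
        sum(missing.values()) == 0
        and n_dup == 0
        and sum(out_of_range.values()) == 0
    )
    return {
        "missing": {k: int(v) for k, v in missing.items()},
        "n_duplicates": n_dup,
        "out_of_range": out_of_range,
        "clean": bool(clean),
    }


def iqr_outliers(values, k: float = 1.5) -> np.ndarray:
    """Boolean flags for values outside the quartile fences.

    A value is flagged when it lies outside ``[q25 - k*IQR, q75 + k*IQR]``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("IQR screening needs at least 4 values")
    q25, q75 = np.percentile(values, [25, 75])
    iqr = q75 - q25
    return (values < q25 - k * iqr) | (values > q75 + k * iqr)


def cramers_v(x, y) -> tuple[float, float, float]:
    """Cramér's V, chi-square statistic and p-value for two categorical vectors.

    ``V = sqrt(chi2 / (n * min(r-1, c-1)))`` on the contingency table of
    ``x`` and ``y``, chi-square without continuity correction.  A variable
    with a single observed level yields ``V = 0`` with a warning.
    """
    ct = pd.crosstab(pd.Series(x), pd.Series(y))
    if min(ct.shape) < 2:
        warnings.warn("degenerate variable with a single observed level; V=0")
        return 0.0, 0.0, 1.0
    chi2, p, _, _ = chi2_contingency(ct.to_numpy(), correction=False)
    n = ct.to_numpy().sum()
    v = float(np.sqrt(chi2 / (n * (min(ct.shape) - 1))))
    return v, float(chi2), float(p)


def _discretize(series: pd.Series) -> pd.Series:
    """Quartile-bin a numeric column; binary/categorical pass through."""
    if series.name in NUMERIC_COLUMNS:
        return pd.qcut(series, 4, duplicates="drop", labels=False)
    return series


def associations(table: pd.DataFrame, outcome: str = "outcome") -> pd.DataFrame:
    """Per-feature association with the outcome.

    One row per predictor: ``cramers_v, chi2, p_value, significant, trend``.
    ``trend`` compares case/control means descriptively
    (``higher-in-cases`` / ``lower-in-cases`` / ``none``) because V carries
    no direction.
    """
    y = table[outcome]
    rows = []
    for col in table.columns:
        if col == outcome:
            continue
        v, chi2, p = cramers_v(_discretize(table[col]), y)
        mean_case = table.loc[y == 1, col].mean()
        mean_ctrl = table.loc[y == 0, col].mean()
        if np.isclose(mean_case, mean_ctrl):
            trend = "none"
        else:
            trend = "higher-in-cases" if mean_case > mean_ctrl else "lower-in-cases"
        rows.append(
            {
                "feature": col,
                "cramers_v": v,
                "chi2": chi2,
                "p_value": p,
                "significant": bool(p < ALPHA),
                "trend": trend,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def cramers_v_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric pairwise Cramér's V matrix over all columns."""
    cols = list(table.columns)
    disc = {c: _discretize(table[c]) for c in cols}
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            v, _, _ = cramers_v(disc[a], disc[b])
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat
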