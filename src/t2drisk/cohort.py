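"""Seeded synthetic lifestyle-cohort generator.

The study cohort behind this package (1939 North Indian participants, 11
lifestyle columns) is private, so all downstream stages are exercised on a
synthetic stand-in whose structure is calibrated to the published summary
statistics: the five-band age allocation with fixed per-band T2DM case
counts, the pooled marginal means for age / thirst / urination / weight, and
the case-vs-control shifts that drive the reported association ordering
(urination, fatigue and age strong; sex and smoking null).

Design of the generator:

* Per-band sample sizes and case counts are **fixed**, not Bernoulli-sampled,
  so band prevalences reproduce exactly; which rows within a band are cases
  is randomized.
* Ages are discretized truncated normals within each band. The band location
  parameters form a one-parameter family ``loc_b(t) = lo_b + t * width_b``
  with scale ``width_b / 4``; the shared ``t`` is solved so the pooled
  *truncated* mean hits the configured target (default 41.77 y).
* Symptom columns are conditional on outcome: rounded truncated normals for
  thirst and urination, a normal mixture for weight whose control mean is
  solved so the pooled mean hits its target at the configured prevalence,
  and Bernoulli draws for the binary columns.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

__all__ = [
    "COLUMNS",
    "VALUE_RANGES",
    "CohortConfig",
    "CohortConfigError",
    "calibrate_band_means",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Column order of a lifestyle table (last column is the diabetes outcome).
COLUMNS = (
    "age",
    "sex",
    "family_history",
    "smoking",
    "drinking",
    "thirst",
    "urination",
    "height",
    "weight",
    "fatigue",
    "outcome",
)

#: Admissible value range per column.  Height uses the observed 61-195 cm
#: range (the nominal upper bound printed elsewhere is physically impossible).
VALUE_RANGES = {
    "age": (5, 83),
    "sex": (0, 1),
    "family_history": (0, 1),
    "smoking": (0, 1),
    "drinking": (0, 1),
    "thirst": (1, 15),
    "urination": (2, 15),
    "height": (61, 195),
    "weight": (15, 96),
    "fatigue": (0, 1),
    "outcome": (0, 1),
}

BINARY_COLUMNS = ("sex", "family_history", "smoking", "drinking", "fatigue", "outcome")


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the published cohort: n=1939 over five age bands with
    fixed case counts (542 cases overall, prevalence ≈ 28%), pooled age mean
    41.77 y and weight mean 61.65 kg, and case/control symptom shifts that
    reproduce the reported association strengths.
    """

    n_total: int = 1939
    age_bands: tuple = ((5, 17), (18, 30), (31, 45), (46, 60), (61, 83))
    band_sizes: tuple = (112, 384, 612, 517, 314)
    band_cases: tuple = (3, 41, 148, 201, 149)
    age_mean_target: float = 41.77
    weight_mean_target: float = 61.65
    # (case mean, control mean, common SD)
    thirst_params: tuple = (8.5, 5.3, 2.0)
    urination_params: tuple = (10.5, 4.8, 2.2)
    weight_case_shift: float = 8.8
    weight_sd: float = 10.0
    height_mean: float = 161.6
    height_sd: float = 10.0
    # (case probability, control probability)
    fatigue_p: tuple = (0.88, 0.62)
    family_history_p: tuple = (0.45, 0.20)
    smoking_p: tuple = (0.15, 0.15)
    drinking_p: tuple = (0.25, 0.15)
    sex_p: float = 0.47
    seed: int = 0

    def validate(self) -> None:
        if len(self.age_bands) != len(self.band_sizes) or len(self.age_bands) != len(
            self.band_cases
        ):
            raise CohortConfigError(
                "age_bands, band_sizes and band_cases must have equal length"
            )
        if sum(self.band_sizes) != self.n_total:
            raise CohortConfigError(
                f"band sizes sum to {sum(self.band_sizes)}, expected n_total={self.n_total}"
            )
        for b, ((lo, hi), size, cases) in enumerate(
            zip(self.age_bands, self.band_sizes, self.band_cases)
        ):
            if lo >= hi:
                raise CohortConfigError(f"band {b}: empty age interval ({lo}, {hi})")
            if cases > size:
                raise CohortConfigError(
                    f"band {b}: {cases} cases exceed band size {size}"
                )
            if cases < 0 or size < 0:
                raise CohortConfigError(f"band {b}: negative count")
        age_lo, age_hi = VALUE_RANGES["age"]
        if self.age_bands[0][0] < age_lo or self.age_bands[-1][1] > age_hi:
            raise CohortConfigError("age bands exceed the admissible age range")

    @property
    def n_cases(self) -> int:
        return int(sum(self.band_cases))

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n_total

    def to_dict(self) -> dict:
        return asdict(self)


def _truncnorm_mean(loc: float, scale: float, lo: float, hi: float) -> float:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return float(truncnorm.mean(a, b, loc=loc, scale=scale))


def calibrate_band_means(config: CohortConfig) -> pd.DataFrame:
    """Solve band-level age-distribution parameters against the pooled target.

    Band locations are ``lo_b + t * width_b`` with a single shared ``t`` in
    [0, 1]; ``t`` is found by a bracketed root solve so that the size-weighted
    mean of the analytic truncated-normal band means equals
    ``config.age_mean_target``.

    Returns a DataFrame with one row per band: ``age_lo, age_hi, loc, scale,
    mean`` where ``mean`` is the effective (truncated) band mean.

    Raises
    ------
    CohortConfigError
        If the target pooled mean is unreachable inside the band boundaries.
    """
    config.validate()
    weights = np.asarray(config.band_sizes, dtype=float) / config.n_total
    bands = config.age_bands
    scales = np.array([(hi - lo) / 4.0 for lo, hi in bands])

    def pooled_mean(t: float) -> float:
        means = [
            _truncnorm_mean(lo + t * (hi - lo), s, lo, hi)
            for (lo, hi), s in zip(bands, scales)
        ]
        return float(np.dot(weights, means))

    lo_mean, hi_mean = pooled_mean(0.0), pooled_mean(1.0)
    target = config.age_mean_target
    if not (lo_mean <= target <= hi_mean):
        raise CohortConfigError(
            f"age mean target {target} unreachable within bands "
            f"(attainable range [{lo_mean:.2f}, {hi_mean:.2f}])"
        )
    t = optimize.brentq(lambda u: pooled_mean(u) - target, 0.0, 1.0, xtol=1e-10)
    rows = []
    for (lo, hi), s in zip(bands, scales):
        loc = lo + t * (hi - lo)
        rows.append(
            {
                "age_lo": lo,
                "age_hi": hi,
                "loc": loc,
                "scale": s,
                "mean": _truncnorm_mean(loc, s, lo, hi),
            }
        )
    return pd.DataFrame(rows)


def _draw_truncnorm(rng, loc, scale, lo, hi, size):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a seeded synthetic lifestyle table.

    The output has exactly ``band_sizes[b]`` rows with age inside band ``b``
    and exactly ``band_cases[b]`` of them with outcome 1; identical
    config (including seed) yields an identical table.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7D2]))
    band_params = calibrate_band_means(config)

    ages, outcomes = [], []
    for (lo, hi), size, cases, (_, row) in zip(
        config.age_bands, config.band_sizes, config.band_cases, band_params.iterrows()
    ):
        a = np.rint(_draw_truncnorm(rng, row["loc"], row["scale"], lo, hi, size))
        ages.append(np.clip(a, lo, hi).astype(int))
        y = np.zeros(size, dtype=int)
        y[:cases] = 1
        rng.shuffle(y)
        outcomes.append(y)
    age = np.concatenate(ages)
    outcome = np.concatenate(outcomes)
    n = config.n_total
    case = outcome == 1

    def conditional_truncnorm(params, lo, hi):
        mean_case, mean_ctrl, sd = params
        loc = np.where(case, mean_case, mean_ctrl)
        vals = np.rint(np.clip(rng.normal(loc, sd), lo, hi))
        return np.clip(vals, lo, hi).astype(int)

    thirst = conditional_truncnorm(config.thirst_params, *VALUE_RANGES["thirst"])
    urination = conditional_truncnorm(
        config.urination_params, *VALUE_RANGES["urination"]
    )

    # control weight mean solved so the prevalence-weighted mixture hits target
    prev = config.prevalence
    w_ctrl = config.weight_mean_target - prev * config.weight_case_shift
    w_case = w_ctrl + config.weight_case_shift
    w_lo, w_hi = VALUE_RANGES["weight"]
    weight = np.round(
        np.clip(rng.normal(np.where(case, w_case, w_ctrl), config.weight_sd, n), w_lo, w_hi),
        1,
    )
    h_lo, h_hi = VALUE_RANGES["height"]
    height = np.round(
        np.clip(rng.normal(config.height_mean, config.height_sd, n), h_lo, h_hi), 1
    )

    def bernoulli(p_case, p_ctrl):
        p = np.where(case, p_case, p_ctrl)
        return (rng.random(n) < p).astype(int)

    table = pd.DataFrame(
        {
            "age": age,
            "sex": (rng.random(n) < config.sex_p).astype(int),
            "family_history": bernoulli(*config.family_history_p),
            "smoking": bernoulli(*config.smoking_p),
            "drinking": bernoulli(*config.drinking_p),
            "thirst": thirst,
            "urination": urination,
            "height": height,
            "weight": weight,
            "fatigue": bernoulli(*config.fatigue_p),
            "outcome": outcome,
        }
    )
    # guarantee the no-duplicate-rows invariant by re-jittering height on dups
    while True:
        dup = table.duplicated()
        if not dup.any():
            break
        idx = np.flatnonzero(dup.to_numpy())
        table.loc[table.index[idx], "height"] = np.round(
            np.clip(rng.normal(config.height_mean, config.height_sd, idx.size), h_lo, h_hi),
            1,
        )
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a lifestyle table as comma-separated UTF-8 with a header row."""
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a lifestyle table written by :func:`write_cohort`."""
    table = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    return table[list(COLUMNS)]
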