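"""Deterministic rule-based lifestyle recommender.

Maps a predicted risk class (A-D) and an optional profile to a
recommendation plan: diet, physical-activity, monitoring and referral items,
plus a class-appropriate exercise chart.  Rules live in an editable YAML
file shipped with the package (``data/recommendation_rules.yaml``); a static
offline catalog stub stands in for live grocery price feeds.

Diet restriction and monitoring intensity are encoded as an ordinal on each
class rule and are non-decreasing from A to D; class D plans always include
a clinician referral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .fuzzy import CLASS_ORDER

__all__ = [
    "RecommendationPlan",
    "load_rules",
    "recommend",
    "exercise_chart",
    "economy_catalog",
]


@dataclass(frozen=True)
class RecommendationPlan:
    """Ordered plan for one risk class."""

    risk_class: str
    label: str
    intensity: int
    items: tuple
    exercise_chart: tuple
    provenance: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "risk_class": self.risk_class,
            "label": self.label,
            "intensity": self.intensity,
            "items": [dict(i) for i in self.items],
            "exercise_chart": [dict(e) for e in self.exercise_chart],
            "provenance": list(self.provenance),
        }


@lru_cache(maxsize=1)
def load_rules(path=None) -> dict:
    """Load the rule base (package default or an external YAML file)."""
    if path is None:
        text = (
            resources.files("t2drisk").joinpath("data/recommendation_rules.yaml")
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = yaml.safe_load(text)
    for cls in CLASS_ORDER:
        if cls not in rules["classes"] or not rules["classes"][cls]["items"]:
            raise ValueError(f"rule base must define at least one item for class {cls}")
    return rules


def _check_class(risk_class: str) -> str:
    if risk_class not in CLASS_ORDER:
        raise ValueError(f"unknown risk class {risk_class!r}; expected one of {CLASS_ORDER}")
    return risk_class


def exercise_chart(risk_class: str, rules: dict | None = None) -> tuple:
    """Ordered activity list for a class: diabetic chart for D, extended chart otherwise."""
    _check_class(risk_class)
    rules = rules or load_rules()
    key = "diabetic" if risk_class == "D" else "non_diabetic"
    return tuple(dict(e) for e in rules["exercise_charts"][key])


def recommend(risk_class: str, profile: dict | None = None, rules: dict | None = None) -> RecommendationPlan:
    """Render the rule set for a class into a recommendation plan.

    ``profile`` (age, weight, symptoms ...) is currently informational; the
    rules are class-total, so every class always yields a non-empty plan.
    """
    _check_class(risk_class)
    rules = rules or load_rules()
    entry = rules["classes"][risk_class]
    items = tuple(dict(i) for i in entry["items"])
    return RecommendationPlan(
        risk_class=risk_class,
        label=entry["label"],
        intensity=int(entry["intensity"]),
        items=items,
        exercise_chart=exercise_chart(risk_class, rules),
        provenance=tuple(f"{risk_class}:{i}" for i in range(len(items))),
    )


def economy_catalog(rules: dict | None = None) -> tuple:
    """Static offline catalog of budget-friendly diet items."""
    rules = rules or load_rules()
    return tuple(dict(i) for i in rules["economy_catalog"])
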