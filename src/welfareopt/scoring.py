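"""Multi-criteria scoring of welfare indicators.

Each indicator i in a species/class view is scored on five factors:

* hazard coverage        -- number of distinct hazards it is linked to;
* consequence coverage   -- number of distinct consequences it is linked to;
* easiness               -- transformed ease of indicator use, (L+1) - value
  with L = 3 levels, so Easy -> 3, Moderate -> 2, Difficult -> 1 (higher is
  always better);
* impact                 -- mean impact (Low=1, High=2) over the indicator's
  distinct linked consequences;
* mitigation             -- mean of (L+1) - ease_of_mitigation over the
  indicator's distinct linked hazards.

Every factor is max-min normalised *within the view* to [0, 1]; a constant
factor normalises to 0 everywhere (it carries no discriminative information,
and any constant choice is selection-equivalent).  The per-indicator
composite objective is the weighted sum

    objective_i = w_coverage * (alpha * hc_i + beta * cc_i)
                + w_easiness * e_i + w_impact * m_i + w_mitigation * g_i

over the normalised factors, with user weights from :class:`WeightConfig`.
Because normalisation removes affine offsets, any transform of the form
a*x + b (a > 0) of a raw factor -- e.g. using 5 - value instead of
4 - value for the ease transforms -- yields identical normalised values and
hence identical selections.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .db import DatabaseView
from .errors import DataValidationError

#: number of levels of the ease ordinals (Easy/Moderate/Difficult)
N_EASE_LEVELS = 3

FACTOR_NAMES = ("hazard_coverage", "consequence_coverage", "easiness", "impact", "mitigation")

#: the four tunable objective weights, by the dimension they govern
WEIGHT_FIELDS = {
    "coverage": "w_coverage",
    "easiness": "w_easiness",
    "impact": "w_impact",
    "mitigation": "w_mitigation",
}


@dataclass(frozen=True)
class WeightConfig:
    """User-defined weighting of the objective function.

    ``alpha``/``beta`` balance hazard vs consequence coverage inside the
    composite coverage term; the four ``w_*`` weights tune the relative
    importance of coverage, ease of indicator use, impact of welfare
    consequence and ease of hazard mitigation.  ``max_indicators`` is the
    selection budget K and ``time_limit_seconds`` bounds the exact solver's
    wall-clock time (default 10 s, after which the incumbent is returned).
    """

    alpha: float = 1.0
    beta: float = 1.0
    w_coverage: float = 1.0
    w_easiness: float = 1.0
    w_impact: float = 1.0
    w_mitigation: float = 1.0
    max_indicators: int = 6
    time_limit_seconds: float = 10.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "w_coverage", "w_easiness", "w_impact", "w_mitigation"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise DataValidationError(f"{name} must be finite and >= 0, got {value!r}")
        if not isinstance(self.max_indicators, int) or self.max_indicators < 1:
            raise DataValidationError("max_indicators must be an integer >= 1")
        if not self.time_limit_seconds > 0:
            raise DataValidationError("time_limit_seconds must be > 0")

    def replace(self, **changes) -> "WeightConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "WeightConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DataValidationError(f"unknown weight field(s): {', '.join(sorted(unknown))}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WeightConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise DataValidationError(f"{path} does not contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class FactorVector:
    """One factor's raw and max-min-normalised values across a view."""

    factor_name: str
    raw_values: Mapping[str, float]
    x_min: float
    x_max: float
    normalised_values: Mapping[str, float]


@dataclass(frozen=True)
class IndicatorScore:
    """All per-indicator factor values and the composite objective."""

    indicator: str
    hazard_coverage: int
    consequence_coverage: int
    impact_score: float
    mitigation_score: float
    easiness_score: float
    norm_hazard_coverage: float
    norm_consequence_coverage: float
    norm_impact: float
    norm_mitigation: float
    norm_easiness: float
    composite_coverage: float
    objective: float


def minmax_normalise(raw_values: Mapping[str, float], factor_name: str = "factor") -> FactorVector:
    """Max-min normalise ``raw_values`` to [0, 1].

    A degenerate (constant) factor maps to 0 everywhere.
    """
    if not raw_values:
        raise DataValidationError(f"{factor_name}: cannot normalise an empty factor")
    for key, v in raw_values.items():
        if not math.isfinite(v):
            raise DataValidationError(f"{factor_name}: non-finite value {v!r} for {key!r}")
    x_min = min(raw_values.values())
    x_max = max(raw_values.values())
    span = x_max - x_min
    if span == 0:
        normalised = {k: 0.0 for k in raw_values}
    else:
        normalised = {k: (v - x_min) / span for k, v in raw_values.items()}
    return FactorVector(
        factor_name=factor_name,
        raw_values=dict(raw_values),
        x_min=x_min,
        x_max=x_max,
        normalised_values=normalised,
    )


def ease_transform(value: int, n_levels: int = N_EASE_LEVELS) -> float:
    """Reverse an 'ease' ordinal so that higher is better: (L+1) - value."""
    return float(n_levels + 1 - value)


def aggregate_impact(view: DatabaseView, indicator: str) -> float:
    """Mean impact (Low=1, High=2) over the indicator's distinct linked
    consequences."""
    consequences = view.consequences_of(indicator)
    return sum(view.impact_of(c) for c in sorted(consequences)) / len(consequences)


def aggregate_mitigation(view: DatabaseView, indicator: str) -> float:
    """Mean transformed ease of mitigation over distinct linked hazards."""
    hazards = view.hazards_of(indicator)
    return sum(ease_transform(view.mitigation_of(h)) for h in sorted(hazards)) / len(hazards)


def easiness_score(view: DatabaseView, indicator: str) -> float:
    """Transformed ease of use of the indicator itself."""
    return ease_transform(view.ease_of_use(indicator))


def factor_vectors(view: DatabaseView) -> dict[str, FactorVector]:
    """All five factors of a view, raw and normalised."""
    inds = view.indicators
    raw = {
        "hazard_coverage": {i: float(view.coverage_counts(i).n_hazards) for i in inds},
        "consequence_coverage": {i: float(view.coverage_counts(i).n_consequences) for i in inds},
        "easiness": {i: easiness_score(view, i) for i in inds},
        "impact": {i: aggregate_impact(view, i) for i in inds},
        "mitigation": {i: aggregate_mitigation(view, i) for i in inds},
    }
    return {name: minmax_normalise(values, name) for name, values in raw.items()}


def score_indicators(view: DatabaseView, weights: WeightConfig) -> list[IndicatorScore]:
    """Score every indicator in the view; returned in lexicographic order."""
    factors = factor_vectors(view)
    scores = []
    for ind in view.indicators:
        nh = factors["hazard_coverage"].normalised_values[ind]
        nc = factors["consequence_coverage"].normalised_values[ind]
        ne = factors["easiness"].normalised_values[ind]
        ni = factors["impact"].normalised_values[ind]
        nm = factors["mitigation"].normalised_values[ind]
        composite = weights.alpha * nh + weights.beta * nc
        objective = (
            weights.w_coverage * composite
            + weights.w_easiness * ne
            + weights.w_impact * ni
            + weights.w_mitigation * nm
        )
        counts = view.coverage_counts(ind)
        scores.append(
            IndicatorScore(
                indicator=ind,
                hazard_coverage=counts.n_hazards,
                consequence_coverage=counts.n_consequences,
                impact_score=factors["impact"].raw_values[ind],
                mitigation_score=factors["mitigation"].raw_values[ind],
                easiness_score=factors["easiness"].raw_values[ind],
                norm_hazard_coverage=nh,
                norm_consequence_coverage=nc,
                norm_impact=ni,
                norm_mitigation=nm,
                norm_easiness=ne,
                composite_coverage=composite,
                objective=objective,
            )
        )
    return scores


def scores_to_dataframe(scores: list[IndicatorScore]) -> pd.DataFrame:
    """One row per indicator with every raw/normalised factor and the
    objective; suitable for CSV export."""
    return pd.DataFrame([dataclasses.asdict(s) for s in scores])
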