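"""Analysis harnesses around the selectors.

* cumulative coverage curves (greedy vs exact) over hazards, consequences or
  the hazard x consequence "combination space";
* scenario testing against a shipped set of named weighting presets whose
  four weights always sum to the same fixed total;
* a univariate +/-50% weight-perturbation robustness check reporting
  pairwise shared-indicator counts (the numbers a Venn diagram would show);
* a systematic sweep of the coverage weight with a per-factor decomposition
  of the selected set's objective;
* a repeated-run wall-clock benchmark (mean and 95% t-interval per K).
  Timings are reported, never asserted against: they are hardware-bound.
"""

from __future__ import annotations

import importlib.resources
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import pandas as pd
import scipy.stats
import yaml

from .db import DatabaseView
from .errors import DataValidationError, UnknownEntityError
from .scoring import WEIGHT_FIELDS, WeightConfig
from .selection import Mode, SelectionResult, exact_select, greedy_topk, objective_breakdown

Dimension = Literal["hazards", "consequences", "pairs"]


@dataclass
class CoverageCurve:
    """Cumulative union-coverage percentage as the selection budget grows."""

    dimension: Dimension
    algorithm: Literal["greedy", "exact"]
    points: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_plateaus(self) -> int:
        """Number of budget increments that added no new coverage."""
        return sum(1 for (_, a), (_, b) in zip(self.points, self.points[1:]) if b <= a)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["n_indicators", "cumulative_percent"])


def _dimension_percent(result: SelectionResult, dimension: Dimension) -> float:
    counts = {
        "hazards": (result.union_hazards, result.total_hazards),
        "consequences": (result.union_consequences, result.total_consequences),
        "pairs": (result.union_pairs, result.total_pairs),
    }
    covered, total = counts[dimension]
    return 100.0 * covered / total


def cumulative_curve(
    view: DatabaseView,
    weights: WeightConfig,
    dimension: Dimension = "consequences",
    algorithm: Literal["greedy", "exact"] = "greedy",
    max_k: int | None = None,
) -> CoverageCurve:
    """Union coverage of the k-selection for k = 1..max_k.

    Greedy curves may plateau where the next-ranked indicator adds no new
    coverage; the exact (union-mode) selector only admits an indicator when
    it increases the objective, so its curve rises monotonically to the
    whole-set asymptote.
    """
    if max_k is None:
        max_k = len(view.indicators)
    if max_k < 1:
        raise DataValidationError("max_k must be >= 1")
    select: Callable[..., SelectionResult] = greedy_topk if algorithm == "greedy" else exact_select
    curve = CoverageCurve(dimension=dimension, algorithm=algorithm)
    for k in range(1, max_k + 1):
        result = select(view, weights.replace(max_indicators=k), mode="union")
        curve.points.append((k, _dimension_percent(result, dimension)))
    return curve


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioTable:
    scenarios: list[tuple[str, WeightConfig, SelectionResult]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, weights, result in self.scenarios:
            rows.append(
                {
                    "scenario": name,
                    "w_coverage": weights.w_coverage,
                    "w_easiness": weights.w_easiness,
                    "w_impact": weights.w_impact,
                    "w_mitigation": weights.w_mitigation,
                    "selected": "+".join(result.selected),
                    "objective": result.objective_value,
                    "union_hazards_pct": result.union_hazards_pct,
                    "union_consequences_pct": result.union_consequences_pct,
                    "status": result.status,
                }
            )
        return pd.DataFrame(rows)


def load_presets(path: str | Path | None = None, **overrides) -> list[tuple[str, WeightConfig]]:
    """The five shipped weighting scenarios (or a user preset YAML)."""
    if path is None:
        text = (
            importlib.resources.files("welfareopt").joinpath("presets.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    presets = []
    for entry in data["scenarios"]:
        fields = {k: v for k, v in entry.items() if k not in ("name", "comment")}
        fields.update(overrides)
        presets.append((entry["name"], WeightConfig.from_mapping(fields)))
    return presets


def run_scenarios(
    view: DatabaseView,
    presets: Sequence[tuple[str, WeightConfig]] | None = None,
    k: int = 6,
    mode: Mode = "union",
) -> ScenarioTable:
    """Run the exact selector under each named weighting scenario."""
    if presets is None:
        presets = load_presets()
    if not presets:
        raise DataValidationError("presets must be non-empty")
    table = ScenarioTable(scenarios=[])
    for name, weights in presets:
        weights = weights.replace(max_indicators=k)
        table.scenarios.append((name, weights, exact_select(view, weights, mode=mode)))
    return table


# ---------------------------------------------------------------------------
# robustness (univariate weight perturbation)
# ---------------------------------------------------------------------------


@dataclass
class RobustnessReport:
    """Selections at -50% / 0 / +50% on one weight, plus the pairwise
    shared-indicator counts a Venn diagram would display."""

    perturbed_factor: str
    deltas: tuple[float, ...]
    selections: dict[float, tuple[str, ...]]
    pairwise_shared: dict[tuple[float, float], int]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"delta_a": a, "delta_b": b, "shared": n}
            for (a, b), n in sorted(self.pairwise_shared.items())
        ]
        return pd.DataFrame(rows)


def perturb_weights(
    view: DatabaseView,
    factor: str,
    base: WeightConfig | None = None,
    k: int = 10,
    deltas: tuple[float, ...] = (-0.5, 0.0, 0.5),
    mode: Mode = "union",
) -> RobustnessReport:
    """Univariate robustness: scale one weight by 1+delta, re-solve, and
    count shared indicators between every pair of perturbed runs.

    The default base sets all four weights to 1.0.
    """
    if factor not in WEIGHT_FIELDS:
        raise UnknownEntityError(
            f"unknown factor {factor!r}; choose from {', '.join(WEIGHT_FIELDS)}"
        )
    if base is None:
        base = WeightConfig(w_coverage=1.0, w_easiness=1.0, w_impact=1.0, w_mitigation=1.0)
    field_name = WEIGHT_FIELDS[factor]
    selections: dict[float, tuple[str, ...]] = {}
    for delta in deltas:
        weights = base.replace(
            **{field_name: getattr(base, field_name) * (1.0 + delta)}, max_indicators=k
        )
        selections[delta] = exact_select(view, weights, mode=mode).selected
    shared = {
        (a, b): len(set(selections[a]) & set(selections[b]))
        for a in deltas
        for b in deltas
    }
    return RobustnessReport(
        perturbed_factor=factor, deltas=tuple(deltas), selections=selections,
        pairwise_shared=shared,
    )


# ---------------------------------------------------------------------------
# coverage-weight sweep
# ---------------------------------------------------------------------------


def sweep_coverage_weight(
    view: DatabaseView,
    base: WeightConfig,
    grid: Sequence[float],
    k: int = 6,
    mode: Mode = "union",
) -> pd.DataFrame:
    """Vary the coverage weight over ``grid``; per grid point report the
    selected set and the objective decomposed by factor (contributions sum
    to the total)."""
    if not len(grid):
        raise DataValidationError("grid must be non-empty")
    rows = []
    for w_cov in grid:
        weights = base.replace(w_coverage=float(w_cov), max_indicators=k)
        result = exact_select(view, weights, mode=mode)
        parts = objective_breakdown(view, result.selected, weights, mode=mode)
        rows.append(
            {
                "w_coverage": float(w_cov),
                "selected": "+".join(result.selected),
                "coverage_contribution": parts["coverage"],
                "easiness_contribution": parts["easiness"],
                "impact_contribution": parts["impact"],
                "mitigation_contribution": parts["mitigation"],
                "total_objective": parts["total"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------


def benchmark(
    view: DatabaseView,
    weights: WeightConfig,
    k_values: Sequence[int] = tuple(range(5, 51, 5)),
    repetitions: int = 15,
    mode: Mode = "union",
    clock: Callable[[], float] = time.perf_counter,
) -> pd.DataFrame:
    """Repeated-run wall-clock statistics per selection budget K.

    Returns one row per K with the mean runtime in seconds and its 95%
    confidence interval from the t-distribution over ``repetitions`` runs.
    """
    if repetitions < 2:
        raise DataValidationError("repetitions must be >= 2")
    rows = []
    for k in k_values:
        w = weights.replace(max_indicators=int(k))
        times = []
        for _ in range(repetitions):
            start = clock()
            exact_select(view, w, mode=mode)
            times.append(clock() - start)
        mean = sum(times) / len(times)
        sem = scipy.stats.sem(times)
        if sem > 0:
            low, high = scipy.stats.t.interval(0.95, len(times) - 1, loc=mean, scale=sem)
        else:
            low = high = mean
        rows.append(
            {"k": int(k), "mean_seconds": mean, "ci95_low": low, "ci95_high": high,
             "repetitions": repetitions}
        )
    return pd.DataFrame(rows)
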