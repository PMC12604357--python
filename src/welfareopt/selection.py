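"""Indicator subset selection.

Three selectors share one set-objective contract:

* :func:`greedy_topk` ranks indicators by their individual composite
  objective and takes the best K.  Fast, but blind to overlap: two top-ranked
  indicators covering the same consequences are both selected, producing the
  characteristic plateaus in cumulative-coverage curves.
* :func:`exact_select` is a depth-first branch-and-bound with backtracking
  over include/exclude decisions.  Indicators are explored in descending
  individual-objective order, the incumbent is initialised with the greedy
  solution, and each node is bounded by an admissible optimistic completion
  (best remaining additive terms plus the remaining union-coverage headroom).
  A wall-clock limit (default 10 s) returns the incumbent with status
  ``time_limited``.
* :func:`exhaustive_select` enumerates every non-empty subset of size <= K
  (guarded at 20 indicators) and serves as the brute-force oracle.

Two set-objective modes exist because per-indicator objectives are not
additive in coverage:

* ``additive``: Objective(S) = sum over S of the per-indicator objectives.
* ``union`` (default for the exact solver): the coverage term counts each
  hazard/consequence at most once across S, normalised by the view totals --
  only *new* coverage is rewarded -- while the easiness/impact/mitigation
  terms remain additive.

Equal-valued optima resolve to the smallest, then lexicographically
earliest, indicator set -- so an indicator contributing nothing to the
objective is never forced into the solution.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .db import DatabaseView, percent
from .errors import CapacityError, DataValidationError, UnknownEntityError
from .scoring import IndicatorScore, WeightConfig, score_indicators

logger = logging.getLogger(__name__)

Mode = Literal["additive", "union"]

#: absolute tolerance for comparing floating-point objective values
OBJ_EPS = 1e-9

#: progress is logged every this many search nodes
LOG_INTERVAL = 10_000


def subset_count(n_items: int) -> int:
    """Number of non-empty subsets of ``n_items`` items: 2^n - 1."""
    if n_items < 0:
        raise DataValidationError("n_items must be >= 0")
    return 2**n_items - 1


@dataclass
class SelectionResult:
    """Outcome of one selection run, re-derivable from the view."""

    selected: tuple[str, ...]
    k_requested: int
    mode: Mode
    objective_value: float
    objective_additive: float
    objective_union: float
    union_hazards: int
    union_consequences: int
    union_pairs: int
    total_hazards: int
    total_consequences: int
    total_pairs: int
    per_indicator: list[IndicatorScore]
    status: Literal["optimal", "time_limited", "heuristic"]
    elapsed_seconds: float
    nodes_explored: int = 0

    @property
    def union_hazards_pct(self) -> float:
        return percent(self.union_hazards, self.total_hazards)

    @property
    def union_consequences_pct(self) -> float:
        return percent(self.union_consequences, self.total_consequences)

    @property
    def union_pairs_pct(self) -> float:
        return percent(self.union_pairs, self.total_pairs)

    def to_dict(self) -> dict:
        """JSON-ready summary; percentages to one decimal place."""
        return {
            "selected": list(self.selected),
            "k_requested": self.k_requested,
            "mode": self.mode,
            "objective_value": self.objective_value,
            "objective_additive": self.objective_additive,
            "objective_union": self.objective_union,
            "union_hazards": self.union_hazards,
            "union_hazards_pct": self.union_hazards_pct,
            "union_consequences": self.union_consequences,
            "union_consequences_pct": self.union_consequences_pct,
            "union_pairs": self.union_pairs,
            "union_pairs_pct": self.union_pairs_pct,
            "status": self.status,
            "elapsed_seconds": self.elapsed_seconds,
            "nodes_explored": self.nodes_explored,
        }


class _Problem:
    """Bitmask encoding of a view plus per-indicator scores."""

    def __init__(self, view: DatabaseView, weights: WeightConfig):
        self.view = view
        self.weights = weights
        self.labels = list(view.indicators)  # lexicographic
        self.n = len(self.labels)
        self.n_hazards = len(view.hazards)
        self.n_consequences = len(view.consequences)
        self.n_pairs = len(view.all_pairs)
        h_bit = {h: 1 << i for i, h in enumerate(view.hazards)}
        c_bit = {c: 1 << i for i, c in enumerate(view.consequences)}
        p_bit = {p: 1 << i for i, p in enumerate(sorted(view.all_pairs))}
        self.hmask = []
        self.cmask = []
        self.pmask = []
        for label in self.labels:
            pairs = view.pairs_of(label)
            hm = cm = pm = 0
            for pair in pairs:
                hm |= h_bit[pair[0]]
                cm |= c_bit[pair[1]]
                pm |= p_bit[pair]
            self.hmask.append(hm)
            self.cmask.append(cm)
            self.pmask.append(pm)
        self.scores = {s.indicator: s for s in score_indicators(view, weights)}
        self.obj = [self.scores[label].objective for label in self.labels]
        s = weights
        self.noncov = [
            s.w_easiness * sc.norm_easiness
            + s.w_impact * sc.norm_impact
            + s.w_mitigation * sc.norm_mitigation
            for sc in (self.scores[label] for label in self.labels)
        ]

    # -- set objective -----------------------------------------------------

    def coverage_term(self, uh: int, uc: int) -> float:
        w = self.weights
        return w.w_coverage * (
            w.alpha * uh.bit_count() / self.n_hazards
            + w.beta * uc.bit_count() / self.n_consequences
        )

    def value(self, indices: Iterable[int], mode: Mode) -> float:
        indices = list(indices)
        if mode == "additive":
            return sum(self.obj[i] for i in indices)
        uh = uc = 0
        for i in indices:
            uh |= self.hmask[i]
            uc |= self.cmask[i]
        return self.coverage_term(uh, uc) + sum(self.noncov[i] for i in indices)

    def subset_value(self, labels: Iterable[str], mode: Mode) -> float:
        pos = {label: i for i, label in enumerate(self.labels)}
        return self.value((pos[label] for label in labels), mode)

    def result(
        self,
        indices: Sequence[int],
        mode: Mode,
        status: str,
        elapsed: float,
        nodes: int = 0,
        rank_order: bool = False,
    ) -> SelectionResult:
        uh = uc = up = 0
        for i in indices:
            uh |= self.hmask[i]
            uc |= self.cmask[i]
            up |= self.pmask[i]
        labels = [self.labels[i] for i in indices]
        if not rank_order:
            labels = sorted(labels)
        return SelectionResult(
            selected=tuple(labels),
            k_requested=self.weights.max_indicators,
            mode=mode,
            objective_value=self.value(indices, mode),
            objective_additive=self.value(indices, "additive"),
            objective_union=self.value(indices, "union"),
            union_hazards=uh.bit_count(),
            union_consequences=uc.bit_count(),
            union_pairs=up.bit_count(),
            total_hazards=self.n_hazards,
            total_consequences=self.n_consequences,
            total_pairs=self.n_pairs,
            per_indicator=[self.scores[label] for label in labels],
            status=status,
            elapsed_seconds=elapsed,
            nodes_explored=nodes,
        )

    def search_order(self) -> list[int]:
        """Indices in descending individual-objective order, ties
        lexicographic by label."""
        return sorted(range(self.n), key=lambda i: (-self.obj[i], self.labels[i]))


def _better(value: float, chosen: Sequence[str], best_value: float, best_set: tuple) -> bool:
    if value > best_value + OBJ_EPS:
        return True
    if abs(value - best_value) <= OBJ_EPS:
        cand = tuple(sorted(chosen))
        return (len(cand), cand) < (len(best_set), best_set)
    return False


def greedy_topk(view: DatabaseView, weights: WeightConfig, mode: Mode = "union") -> SelectionResult:
    """Take the K indicators with the highest individual objectives."""
    t0 = time.perf_counter()
    prob = _Problem(view, weights)
    order = prob.search_order()
    chosen = order[: weights.max_indicators]
    return prob.result(chosen, mode, "heuristic", time.perf_counter() - t0, rank_order=True)


class _TimeUp(Exception):
    pass


def exact_select(
    view: DatabaseView, weights: WeightConfig, mode: Mode = "union"
) -> SelectionResult:
    """Branch-and-bound with backtracking; provably optimal unless the time
    limit intervenes, in which case the best incumbent is returned."""
    t0 = time.perf_counter()
    deadline = t0 + weights.time_limit_seconds
    prob = _Problem(view, weights)
    k = min(weights.max_indicators, prob.n)
    order = prob.search_order()
    n = prob.n

    # per-suffix optimistic data: sorted descending additive gains (cumsummed)
    # and the union of remaining hazard/consequence masks
    gains = prob.obj if mode == "additive" else prob.noncov
    suffix_cum: list[list[float]] = [[] for _ in range(n + 1)]
    suffix_h = [0] * (n + 1)
    suffix_c = [0] * (n + 1)
    for t in range(n - 1, -1, -1):
        i = order[t]
        vals = sorted((gains[order[j]] for j in range(t, n)), reverse=True)
        cum = [0.0]
        for v in vals:
            cum.append(cum[-1] + v)
        suffix_cum[t] = cum
        suffix_h[t] = suffix_h[t + 1] | prob.hmask[i]
        suffix_c[t] = suffix_c[t + 1] | prob.cmask[i]

    # incumbent: greedy solution under the same mode
    greedy_idx = order[:k]
    best_value = prob.value(greedy_idx, mode)
    best_set = tuple(sorted(prob.labels[i] for i in greedy_idx))
    best_idx = list(greedy_idx)

    nodes = 0
    state = {"nodes": 0}

    def optimistic(t: int, r: int, value_now: float, uh: int, uc: int) -> float:
        cum = suffix_cum[t]
        bound = value_now + cum[min(r, len(cum) - 1)]
        if mode == "union":
            new_h = (suffix_h[t] & ~uh).bit_count()
            new_c = (suffix_c[t] & ~uc).bit_count()
            w = prob.weights
            bound += w.w_coverage * (
                w.alpha * new_h / prob.n_hazards + w.beta * new_c / prob.n_consequences
            )
        return bound

    def dfs(start: int, r: int, uh: int, uc: int, acc: float, chosen: list[int]) -> None:
        nonlocal best_value, best_set, best_idx
        if r == 0 or start == n:
            return
        value_now = acc if mode == "additive" else acc + prob.coverage_term(uh, uc)
        for t in range(start, n):
            # masks and sorted gains only shrink with t, so the bound is
            # non-increasing along this loop: once it falls below the
            # incumbent the whole remaining suffix is pruned
            if optimistic(t, r, value_now, uh, uc) < best_value - OBJ_EPS:
                return
            state["nodes"] += 1
            if state["nodes"] % 2048 == 0 and time.perf_counter() > deadline:
                raise _TimeUp
            if state["nodes"] % LOG_INTERVAL == 0:
                logger.info(
                    "explored %d nodes, incumbent objective %.6f", state["nodes"], best_value
                )
            i = order[t]
            chosen.append(i)
            uh2, uc2 = uh | prob.hmask[i], uc | prob.cmask[i]
            acc2 = acc + (prob.obj[i] if mode == "additive" else prob.noncov[i])
            value = acc2 if mode == "additive" else acc2 + prob.coverage_term(uh2, uc2)
            labels = [prob.labels[j] for j in chosen]
            if _better(value, labels, best_value, best_set):
                best_value = value
                best_set = tuple(sorted(labels))
                best_idx = list(chosen)
            dfs(t + 1, r - 1, uh2, uc2, acc2, chosen)
            chosen.pop()

    status = "optimal"
    if time.perf_counter() > deadline:
        status = "time_limited"  # budget already spent: return the incumbent
    else:
        try:
            dfs(0, k, 0, 0, 0.0, [])
        except _TimeUp:
            status = "time_limited"
    nodes = state["nodes"]
    return prob.result(best_idx, mode, status, time.perf_counter() - t0, nodes=nodes)


def exhaustive_select(
    view: DatabaseView, weights: WeightConfig, mode: Mode = "union"
) -> SelectionResult:
    """Enumerate every non-empty subset of size <= K (brute-force oracle)."""
    t0 = time.perf_counter()
    prob = _Problem(view, weights)
    if prob.n > 20:
        raise CapacityError(
            f"exhaustive enumeration is capped at 20 indicators (view has {prob.n})"
        )
    k = min(weights.max_indicators, prob.n)
    n = prob.n
    best_value = float("-inf")
    best_set: tuple = ()
    best_idx: list[int] = []
    counter = {"subsets": 0}

    def dfs(start: int, r: int, uh: int, uc: int, acc: float, chosen: list[int]) -> None:
        nonlocal best_value, best_set, best_idx
        if r == 0 or start == n:
            return
        for i in range(start, n):
            chosen.append(i)
            counter["subsets"] += 1
            uh2, uc2 = uh | prob.hmask[i], uc | prob.cmask[i]
            acc2 = acc + (prob.obj[i] if mode == "additive" else prob.noncov[i])
            value = acc2 if mode == "additive" else acc2 + prob.coverage_term(uh2, uc2)
            labels = [prob.labels[j] for j in chosen]
            if not best_idx or _better(value, labels, best_value, best_set):
                best_value = value
                best_set = tuple(sorted(labels))
                best_idx = list(chosen)
            dfs(i + 1, r - 1, uh2, uc2, acc2, chosen)
            chosen.pop()

    dfs(0, k, 0, 0, 0.0, [])
    return prob.result(
        best_idx, mode, "optimal", time.perf_counter() - t0, nodes=counter["subsets"]
    )


@dataclass
class CombinationTable:
    """Union coverage of every non-empty subset of a shortlist of indicators.

    ``minimal_full_coverage`` lists the minimal subsets whose union coverage
    equals that of the full shortlist -- the smallest combinations with the
    same explanatory power as using every indicator.
    """

    indicators: tuple[str, ...]
    rows: list[dict] = field(default_factory=list)
    max_union_hazards: int = 0
    max_union_consequences: int = 0
    minimal_full_coverage: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_subsets(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df["subset"] = df["subset"].map(lambda s: "+".join(s))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def enumerate_combinations(
    view: DatabaseView, indicators: Sequence[str] | None = None
) -> CombinationTable:
    """Tabulate union hazard/consequence coverage of all 2^n - 1 subsets."""
    if indicators is None:
        indicators = view.indicators
    indicators = sorted(dict.fromkeys(indicators))
    unknown = [i for i in indicators if i not in view.indicators]
    if unknown:
        raise UnknownEntityError(f"indicator(s) not in view: {', '.join(unknown)}")
    if len(indicators) > 20:
        raise CapacityError(
            f"combination enumeration is capped at 20 indicators (got {len(indicators)})"
        )
    hsets = {i: frozenset(view.hazards_of(i)) for i in indicators}
    csets = {i: frozenset(view.consequences_of(i)) for i in indicators}
    full_h = frozenset().union(*hsets.values())
    full_c = frozenset().union(*csets.values())
    table = CombinationTable(
        indicators=tuple(indicators),
        max_union_hazards=len(full_h),
        max_union_consequences=len(full_c),
    )
    attaining: set[frozenset[str]] = set()
    for size in range(1, len(indicators) + 1):
        for combo in itertools.combinations(indicators, size):
            uh = frozenset().union(*(hsets[i] for i in combo))
            uc = frozenset().union(*(csets[i] for i in combo))
            table.rows.append(
                {"subset": combo, "union_hazards": len(uh), "union_consequences": len(uc)}
            )
            if len(uh) == len(full_h) and len(uc) == len(full_c):
                attaining.add(frozenset(combo))
    # attainment is upward closed, so dropping one member decides minimality
    for combo_set in attaining:
        if not any(combo_set - {member} in attaining for member in combo_set):
            table.minimal_full_coverage.append(tuple(sorted(combo_set)))
    table.minimal_full_coverage.sort(key=lambda s: (len(s), s))
    return table


def objective_breakdown(
    view: DatabaseView, subset: Sequence[str], weights: WeightConfig, mode: Mode = "union"
) -> dict[str, float]:
    """Split Objective(S) into its coverage / easiness / impact / mitigation
    contributions (they sum to the total)."""
    prob = _Problem(view, weights)
    pos = {label: i for i, label in enumerate(prob.labels)}
    try:
        indices = [pos[label] for label in subset]
    except KeyError as exc:
        raise UnknownEntityError(f"indicator {exc.args[0]!r} not in view") from None
    w = weights
    scores = [prob.scores[label] for label in subset]
    if mode == "union":
        uh = uc = 0
        for i in indices:
            uh |= prob.hmask[i]
            uc |= prob.cmask[i]
        coverage = prob.coverage_term(uh, uc)
    else:
        coverage = w.w_coverage * sum(s.composite_coverage for s in scores)
    parts = {
        "coverage": coverage,
        "easiness": w.w_easiness * sum(s.norm_easiness for s in scores),
        "impact": w.w_impact * sum(s.norm_impact for s in scores),
        "mitigation": w.w_mitigation * sum(s.norm_mitigation for s in scores),
    }
    parts["total"] = sum(parts.values())
    return parts
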