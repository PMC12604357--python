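"""Synthetic linkage-database generation.

Real hazard-consequence-indicator databases for farmed species are built
from expert-elicited risk assessments and are typically proprietary, so this
module generates structurally faithful stand-ins:

* a bipartite hazard <-> consequence layer sampled first (every hazard and
  every consequence is linked at least once, extra pairs added with a
  density parameter), mirroring the risk-assessment logic chain in which a
  hazard leads to one or more consequences;
* indicators then attach to hazard-consequence *pairs*, so an indicator's
  hazard and consequence coverage are coupled;
* a mixture of "broad" indicators (many linked pairs -- iceberg-like, high
  coverage) and "narrow" indicators (few pairs) whose proportions drive the
  saturating shape of cumulative-coverage curves;
* ordinal metadata sampled per entity, so no rating conflicts can arise;
* optionally a *planted* subset of indicators whose union covers every pair,
  giving instances with a known full-coverage solution.

Default sizes follow the largest species view in the motivating case
studies: 92 indicators, 58 hazards, 16 consequences.

Deterministic proof-of-concept fixtures with a known minimal-subset
structure are produced by :func:`plant_poc_fixture`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .db import LinkageDatabase, LinkageRecord
from .errors import SyntheticSpecError
from .selection import enumerate_combinations

#: ordinal level names in rating order
IMPACT_NAMES = ("Low", "High")
EASE_NAMES = ("Easy", "Moderate", "Difficult")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic database.

    ``broad_degree``/``narrow_degree`` are inclusive ranges of the number of
    hazard-consequence pairs an indicator links to.  ``metadata_distribution``
    maps ``impact`` to two probabilities (Low, High) and ``mitigation`` /
    ``ease_of_use`` to three (Easy, Moderate, Difficult).
    """

    n_hazards: int = 58
    n_consequences: int = 16
    n_indicators: int = 92
    broad_fraction: float = 0.25
    broad_degree: tuple[int, int] = (8, 24)
    narrow_degree: tuple[int, int] = (1, 4)
    hazard_consequence_density: float = 0.08
    metadata_distribution: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "impact": (0.5, 0.5),
            "mitigation": (1 / 3, 1 / 3, 1 / 3),
            "ease_of_use": (1 / 3, 1 / 3, 1 / 3),
        }
    )
    planted_subset: tuple[str, ...] | None = None
    species: str = "synthetic species"
    production_class: str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hazards, self.n_consequences, self.n_indicators) < 1:
            raise SyntheticSpecError("entity counts must all be >= 1")
        if not 0.0 <= self.broad_fraction <= 1.0:
            raise SyntheticSpecError("broad_fraction must lie in [0, 1]")
        if not 0.0 < self.hazard_consequence_density <= 1.0:
            raise SyntheticSpecError("hazard_consequence_density must lie in (0, 1]")
        for name in ("broad_degree", "narrow_degree"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise SyntheticSpecError(f"{name} must satisfy 1 <= lo <= hi, got ({lo}, {hi})")
            if hi > self.n_hazards * self.n_consequences:
                raise SyntheticSpecError(
                    f"{name} upper bound {hi} exceeds the number of possible "
                    f"hazard-consequence pairs ({self.n_hazards * self.n_consequences})"
                )
        for key, probs in self.metadata_distribution.items():
            if key not in ("impact", "mitigation", "ease_of_use"):
                raise SyntheticSpecError(f"unknown metadata key {key!r}")
            want = 2 if key == "impact" else 3
            if len(probs) != want or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise SyntheticSpecError(f"metadata_distribution[{key!r}] must be {want} "
                                         "non-negative probabilities summing to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise SyntheticSpecError(f"{path} does not contain a mapping")
        data = dict(data)
        for key in ("broad_degree", "narrow_degree", "planted_subset"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "metadata_distribution" in data:
            data["metadata_distribution"] = {
                k: tuple(v) for k, v in data["metadata_distribution"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SyntheticSpecError(f"unknown spec field(s): {', '.join(sorted(unknown))}")
        return cls(**data)


def _sample_pairs(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Bipartite hazard-consequence layer: no orphan entities, extra pairs
    with probability `hazard_consequence_density`."""
    pairs: set[tuple[int, int]] = set()
    for h in range(spec.n_hazards):
        pairs.add((h, int(rng.integers(spec.n_consequences))))
    for c in range(spec.n_consequences):
        pairs.add((int(rng.integers(spec.n_hazards)), c))
    extra = rng.random((spec.n_hazards, spec.n_consequences)) < spec.hazard_consequence_density
    pairs.update(zip(*np.nonzero(extra)))
    return sorted((int(h), int(c)) for h, c in pairs)


def generate(spec: SyntheticSpec) -> LinkageDatabase:
    """Generate a database from ``spec``; the same seed yields an identical
    database."""
    rng = np.random.default_rng(spec.seed)
    pairs = _sample_pairs(spec, rng)
    n_pairs = len(pairs)
    if max(spec.broad_degree[1], spec.narrow_degree[1]) > n_pairs:
        raise SyntheticSpecError(
            f"degree range exceeds the {n_pairs} hazard-consequence pairs realised; "
            "raise hazard_consequence_density or lower the degree bounds"
        )

    ind_labels = [f"ind_{i:03d}" for i in range(spec.n_indicators)]
    planted = list(spec.planted_subset or ())
    unknown = [p for p in planted if p not in ind_labels]
    if unknown:
        raise SyntheticSpecError(
            f"planted_subset labels must be generated indicator labels "
            f"(ind_000 ... ind_{spec.n_indicators - 1:03d}); unknown: {', '.join(unknown)}"
        )

    # membership: indicator -> set of pair indices
    membership: dict[str, set[int]] = {}
    n_broad = round(spec.broad_fraction * spec.n_indicators)
    for idx, label in enumerate(ind_labels):
        lo, hi = spec.broad_degree if idx < n_broad else spec.narrow_degree
        degree = int(rng.integers(lo, hi + 1))
        membership[label] = set(map(int, rng.choice(n_pairs, size=degree, replace=False)))

    if planted:
        # distribute every pair over the planted members so their union is
        # total coverage by construction
        assignment = rng.integers(len(planted), size=n_pairs)
        for j, label in enumerate(planted):
            membership[label] = set(map(int, np.nonzero(assignment == j)[0]))
            if not membership[label]:  # tiny instances: guarantee non-emptiness
                membership[label] = {int(rng.integers(n_pairs))}

    impact_p = spec.metadata_distribution["impact"]
    mit_p = spec.metadata_distribution["mitigation"]
    ease_p = spec.metadata_distribution["ease_of_use"]
    impact = {c: int(rng.choice(2, p=impact_p)) + 1 for c in range(spec.n_consequences)}
    mitigation = {h: int(rng.choice(3, p=mit_p)) + 1 for h in range(spec.n_hazards)}
    ease = {label: int(rng.choice(3, p=ease_p)) + 1 for label in ind_labels}

    records = []
    for label in ind_labels:
        for pair_idx in sorted(membership[label]):
            h, c = pairs[pair_idx]
            records.append(
                LinkageRecord(
                    species=spec.species,
                    production_class=spec.production_class,
                    hazard=f"hazard_{h:03d}",
                    consequence=f"consequence_{c:02d}",
                    indicator=label,
                    impact_of_consequence=impact[c],
                    ease_of_mitigation=mitigation[h],
                    ease_of_indicator_use=ease[label],
                )
            )
    return LinkageDatabase(records)


# ---------------------------------------------------------------------------
# proof-of-concept fixtures with a known minimal-subset structure
# ---------------------------------------------------------------------------

# Six indicators A..F.  "laying_hen" style: 14 hazards x 6 consequences with
# exactly ONE minimal 3-subset {A, B, F} matching the full 6-indicator
# coverage (hazards h04-h06 appear only under A, h09-h11 only under B and
# h14 only under F, so all three are forced).  "broiler" style: 18 hazards x
# 9 consequences with exactly TWO minimal 4-subsets {A,C,E,F} and {B,C,E,F}
# sharing C, E, F (A and B are interchangeable duplicates; C, E, F each own
# unique hazards).
_POC_STRUCTURE: dict[str, dict] = {
    "laying_hen": {
        "n_hazards": 14,
        "n_consequences": 6,
        "links": {
            "A": ([1, 2, 3, 4, 5, 6], [1, 2, 3]),
            "B": ([7, 8, 9, 10, 11], [4, 5]),
            "C": ([1, 2, 7], [1, 4]),
            "D": ([3, 12], [2, 6]),
            "E": ([8, 13], [3, 5]),
            "F": ([12, 13, 14], [6]),
        },
        "minimal": [("A", "B", "F")],
    },
    "broiler": {
        "n_hazards": 18,
        "n_consequences": 9,
        "links": {
            "A": ([1, 2, 3, 4, 5], [1, 2, 3]),
            "B": ([1, 2, 3, 4, 5], [1, 2, 3]),
            "C": ([6, 7, 8, 9, 10], [4, 5]),
            "D": ([1, 6, 11], [1, 4]),
            "E": ([11, 12, 13, 14], [6, 7]),
            "F": ([15, 16, 17, 18], [8, 9]),
        },
        "minimal": [("A", "C", "E", "F"), ("B", "C", "E", "F")],
    },
}


def plant_poc_fixture(style: str, seed: int = 0) -> LinkageDatabase:
    """A six-indicator database with a known minimal full-coverage subset
    structure, verified by brute force before it is returned.

    ``style='laying_hen'``: 14 hazards, 6 consequences, exactly one minimal
    3-subset with full coverage.  ``style='broiler'``: 18 hazards,
    9 consequences, exactly two minimal 4-subsets sharing three members.
    Metadata is sampled from ``seed``; the linkage structure is fixed.
    """
    if style not in _POC_STRUCTURE:
        raise SyntheticSpecError(
            f"unknown fixture style {style!r}; choose from {sorted(_POC_STRUCTURE)}"
        )
    layout = _POC_STRUCTURE[style]
    rng = np.random.default_rng(seed)
    impact = {c: int(rng.choice(2)) + 1 for c in range(1, layout["n_consequences"] + 1)}
    mitigation = {h: int(rng.choice(3)) + 1 for h in range(1, layout["n_hazards"] + 1)}
    ease = {label: int(rng.choice(3)) + 1 for label in layout["links"]}

    records = []
    for label, (hazards, consequences) in layout["links"].items():
        # pair each hazard with a consequence of the same indicator,
        # cycling so every listed entity appears
        for j, h in enumerate(hazards):
            c = consequences[j % len(consequences)]
            records.append(
                LinkageRecord(
                    species=style,
                    production_class="default",
                    hazard=f"h{h:02d}",
                    consequence=f"c{c}",
                    indicator=label,
                    impact_of_consequence=impact[c],
                    ease_of_mitigation=mitigation[h],
                    ease_of_indicator_use=ease[label],
                )
            )
        for c in consequences:  # guarantee every listed consequence is linked
            records.append(
                LinkageRecord(
                    species=style,
                    production_class="default",
                    hazard=f"h{hazards[0]:02d}",
                    consequence=f"c{c}",
                    indicator=label,
                    impact_of_consequence=impact[c],
                    ease_of_mitigation=mitigation[hazards[0]],
                    ease_of_indicator_use=ease[label],
                )
            )
    db = LinkageDatabase(records)
    _verify_poc(db, style, layout)
    return db


def _verify_poc(db: LinkageDatabase, style: str, layout: dict) -> None:
    view = db.view(style)
    if len(view.hazards) != layout["n_hazards"] or len(view.consequences) != layout[
        "n_consequences"
    ]:
        raise SyntheticSpecError(
            f"fixture {style!r} realised {len(view.hazards)} hazards / "
            f"{len(view.consequences)} consequences, expected "
            f"{layout['n_hazards']} / {layout['n_consequences']}"
        )
    table = enumerate_combinations(view)
    if table.minimal_full_coverage != sorted(layout["minimal"], key=lambda s: (len(s), s)):
        raise SyntheticSpecError(
            f"fixture {style!r} failed brute-force verification: minimal "
            f"full-coverage subsets {table.minimal_full_coverage}"
        )
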