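"""Shared fixtures: small hand-built linkage databases and synthetic views."""

from __future__ import annotations

import pandas as pd
import pytest

from welfareopt import LinkageDatabase, SyntheticSpec, WeightConfig, generate
from welfareopt.db import COLUMNS


def make_db(rows: list[tuple]) -> LinkageDatabase:
    """Build a database from (species, class, hazard, consequence, indicator,
    impact, mitigation, ease) tuples with string ordinals."""
    return LinkageDatabase.from_dataframe(pd.DataFrame(rows, columns=list(COLUMNS)))


# the worked growing/finishing-pig example: one hazard (high stocking
# density, Easy to mitigate) linked to three consequences and, through them,
# to eight indicators
PIG_ROWS = [
    ("pigs", "meat pigs", "high stocking density", "soft tissue lesions and integument damage",
     ind, "High", "Easy", ease)
    for ind, ease in [
        ("body lesions", "Easy"),
        ("calluses and bursitis", "Moderate"),
        ("ear lesions", "Easy"),
        ("leg injuries", "Easy"),
        ("tail lesions", "Easy"),
    ]
] + [
    ("pigs", "meat pigs", "high stocking density", "general disruption of behavior",
     "impaired social behavior", "Low", "Easy", "Difficult"),
    ("pigs", "meat pigs", "high stocking density", "resting problems",
     "restlessness", "Low", "Easy", "Moderate"),
    ("pigs", "meat pigs", "high stocking density", "resting problems",
     "pig cleanliness", "Low", "Easy", "Easy"),
]


@pytest.fixture
def pig_db() -> LinkageDatabase:
    return make_db(PIG_ROWS)


@pytest.fixture
def pig_view(pig_db):
    return pig_db.view("pigs", "meat pigs")


# plateau fixture: A and B cover the same three consequences, C covers the
# fourth; ranking by individual coverage picks {A, B} and plateaus, while the
# optimum {A, C} covers everything
PLATEAU_ROWS = [
    ("sp", "cl", "hA", c, "A", "High", "Easy", "Easy") for c in ("c1", "c2", "c3")
] + [
    ("sp", "cl", "hB", c, "B", "High", "Easy", "Easy") for c in ("c1", "c2", "c3")
] + [
    ("sp", "cl", "hC", "c4", "C", "High", "Easy", "Easy")
]


@pytest.fixture
def plateau_view():
    return make_db(PLATEAU_ROWS).view("sp")


@pytest.fixture
def consequence_only_weights() -> WeightConfig:
    """Reward only (consequence) coverage."""
    return WeightConfig(alpha=0.0, beta=1.0, w_coverage=1.0, w_easiness=0.0,
                        w_impact=0.0, w_mitigation=0.0, max_indicators=2)


def small_view(seed: int, n_indicators: int = 12):
    """A small random synthetic view suitable for exhaustive enumeration."""
    spec = SyntheticSpec(
        n_hazards=12,
        n_consequences=8,
        n_indicators=n_indicators,
        broad_fraction=0.3,
        broad_degree=(4, 8),
        narrow_degree=(1, 3),
        hazard_consequence_density=0.2,
        seed=seed,
    )
    db = generate(spec)
    return db.view(spec.species)
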