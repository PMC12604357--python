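"""Hazard -> consequence -> indicator linkage databases.

The data model mirrors the logic chain used in risk-based welfare assessment:
a welfare *hazard* (an exposure variable, e.g. high stocking density) causes
one or more welfare *consequences* (impairments, e.g. resting problems), each
of which is measured by one or more welfare *indicators* (observations, e.g.
tail lesions).  A database is a deduplicated set of
(species, production class, hazard, consequence, indicator) records enriched
with categorical metadata:

* impact of the welfare consequence  -- Low (1) or High (2), attached to the
  consequence;
* ease of hazard mitigation          -- Easy (1), Moderate (2) or
  Difficult (3), attached to the hazard;
* ease of indicator use              -- Easy (1), Moderate (2) or
  Difficult (3), attached to the indicator.

Within one species/class view an entity carries exactly one rating;
conflicting ratings are a validation error.  The same entity rated
differently in *different* views only triggers a warning (ratings are scoped
to a production context).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataValidationError, SchemaError, UnknownEntityError

logger = logging.getLogger(__name__)

#: wildcard production class selecting every class of a species
ALL = "ALL"

#: canonical long-format CSV header, in order
COLUMNS = (
    "species",
    "production_class",
    "hazard",
    "consequence",
    "indicator",
    "impact_of_consequence",
    "ease_of_mitigation",
    "ease_of_indicator_use",
)

IMPACT_LEVELS: Mapping[str, int] = {"Low": 1, "High": 2}
EASE_LEVELS: Mapping[str, int] = {"Easy": 1, "Moderate": 2, "Difficult": 3}

_IMPACT_NAMES = {v: k for k, v in IMPACT_LEVELS.items()}
_EASE_NAMES = {v: k for k, v in EASE_LEVELS.items()}


def percent(count: int, total: int) -> float:
    """Percentage to one decimal place, rounding half up (17/26 -> 65.4)."""
    if total <= 0:
        raise DataValidationError("percentage denominator must be positive")
    q = Decimal(count) * 100 / Decimal(total)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True, order=True)
class LinkageRecord:
    """One deduplicated hazard-consequence-indicator link with its metadata."""

    species: str
    production_class: str
    hazard: str
    consequence: str
    indicator: str
    impact_of_consequence: int  # Low=1, High=2
    ease_of_mitigation: int  # Easy=1, Moderate=2, Difficult=3
    ease_of_indicator_use: int  # Easy=1, Moderate=2, Difficult=3

    def __post_init__(self) -> None:
        for name in ("species", "production_class", "hazard", "consequence", "indicator"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value.strip():
                raise DataValidationError(f"{name} label must be a non-empty string")
            object.__setattr__(self, name, value.strip())
        if self.impact_of_consequence not in _IMPACT_NAMES:
            raise DataValidationError(
                f"impact_of_consequence must be one of {sorted(_IMPACT_NAMES)}, "
                f"got {self.impact_of_consequence!r}"
            )
        for name in ("ease_of_mitigation", "ease_of_indicator_use"):
            if getattr(self, name) not in _EASE_NAMES:
                raise DataValidationError(
                    f"{name} must be one of {sorted(_EASE_NAMES)}, got {getattr(self, name)!r}"
                )

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        """The five label fields that define record identity."""
        return (self.species, self.production_class, self.hazard, self.consequence, self.indicator)


@dataclass(frozen=True)
class CoverageCounts:
    """Distinct hazards, consequences and hazard x consequence pairs linked to
    one indicator within a view."""

    indicator: str
    n_hazards: int
    n_consequences: int
    n_pairs: int


class LinkageDatabase:
    """Deduplicated collection of :class:`LinkageRecord`."""

    def __init__(self, records: Iterable[LinkageRecord]):
        seen: dict[tuple, LinkageRecord] = {}
        for rec in records:
            seen.setdefault(rec.key, rec)
        self.records: tuple[LinkageRecord, ...] = tuple(sorted(seen.values()))
        if not self.records:
            raise DataValidationError("database contains no records")
        self._warn_cross_view_conflicts()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LinkageDatabase":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if df.empty:
            raise DataValidationError("input table is empty")
        records = []
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            records.append(
                LinkageRecord(
                    species=_label(row.species, "species", row_no),
                    production_class=_label(row.production_class, "production_class", row_no),
                    hazard=_label(row.hazard, "hazard", row_no),
                    consequence=_label(row.consequence, "consequence", row_no),
                    indicator=_label(row.indicator, "indicator", row_no),
                    impact_of_consequence=_ordinal(
                        row.impact_of_consequence, IMPACT_LEVELS, "impact_of_consequence", row_no
                    ),
                    ease_of_mitigation=_ordinal(
                        row.ease_of_mitigation, EASE_LEVELS, "ease_of_mitigation", row_no
                    ),
                    ease_of_indicator_use=_ordinal(
                        row.ease_of_indicator_use, EASE_LEVELS, "ease_of_indicator_use", row_no
                    ),
                )
            )
        db = cls(records)
        n_dupes = len(records) - len(db.records)
        logger.info(
            "loaded %d rows (%d duplicates dropped); %s",
            len(records),
            n_dupes,
            "; ".join(
                f"{sp}: {len({r.indicator for r in db.records if r.species == sp})} indicators"
                for sp in sorted(db.species_index)
            ),
        )
        return db

    @classmethod
    def from_csv(cls, path: str | Path, **read_csv_kwargs) -> "LinkageDatabase":
        path = Path(path)
        if not path.exists():
            raise SchemaError(f"no such file: {path}")
        try:
            df = pd.read_csv(path, dtype=str, **read_csv_kwargs)
        except pd.errors.EmptyDataError as exc:
            raise DataValidationError(f"{path} is empty") from exc
        return cls.from_dataframe(df)

    # -- export ------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "species": r.species,
                "production_class": r.production_class,
                "hazard": r.hazard,
                "consequence": r.consequence,
                "indicator": r.indicator,
                "impact_of_consequence": _IMPACT_NAMES[r.impact_of_consequence],
                "ease_of_mitigation": _EASE_NAMES[r.ease_of_mitigation],
                "ease_of_indicator_use": _EASE_NAMES[r.ease_of_indicator_use],
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    # -- inspection --------------------------------------------------------

    @property
    def species_index(self) -> dict[str, set[str]]:
        """Mapping species -> set of production classes present."""
        index: dict[str, set[str]] = {}
        for r in self.records:
            index.setdefault(r.species, set()).add(r.production_class)
        return index

    def validation_report(self) -> dict:
        """Per species/class entity counts, serialisable to JSON."""
        report: dict = {"n_records": len(self.records), "species": {}}
        for sp, classes in sorted(self.species_index.items()):
            per_class = {}
            for cl in sorted(classes):
                recs = [r for r in self.records if r.species == sp and r.production_class == cl]
                per_class[cl] = {
                    "n_records": len(recs),
                    "n_indicators": len({r.indicator for r in recs}),
                    "n_hazards": len({r.hazard for r in recs}),
                    "n_consequences": len({r.consequence for r in recs}),
                }
            report["species"][sp] = per_class
        return report

    def view(self, species: str, production_class: str = ALL) -> "DatabaseView":
        """Filter to one species and (optionally) one production class."""
        index = self.species_index
        if species not in index:
            raise UnknownEntityError(
                f"unknown species {species!r}; available: {', '.join(sorted(index))}"
            )
        if production_class != ALL and production_class not in index[species]:
            raise UnknownEntityError(
                f"unknown production class {production_class!r} for species {species!r}; "
                f"available: {', '.join(sorted(index[species]))}"
            )
        records = tuple(
            r
            for r in self.records
            if r.species == species
            and (production_class == ALL or r.production_class == production_class)
        )
        return DatabaseView(self, species, production_class, records)

    def _warn_cross_view_conflicts(self) -> None:
        # ratings are scoped to a (species, class) view; divergence across
        # views is legal but worth flagging
        for attr, entity in (
            ("impact_of_consequence", "consequence"),
            ("ease_of_mitigation", "hazard"),
            ("ease_of_indicator_use", "indicator"),
        ):
            ratings: dict[str, set[int]] = {}
            for r in self.records:
                ratings.setdefault(getattr(r, entity), set()).add(getattr(r, attr))
            for label, vals in ratings.items():
                if len(vals) > 1:
                    warnings.warn(
                        f"{entity} {label!r} carries different {attr} ratings "
                        f"across views: {sorted(vals)}",
                        stacklevel=3,
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LinkageDatabase) and self.records == other.records


@dataclass
class DatabaseView:
    """A species/class slice of a database with deterministic entity ordering.

    Entity lists are sorted lexicographically; all downstream tie-breaking
    inherits this order.  Metadata is validated on construction: within a view
    each hazard, consequence and indicator must carry exactly one rating.
    """

    parent: LinkageDatabase
    species: str
    production_class: str
    records: tuple[LinkageRecord, ...]
    indicators: list[str] = field(init=False)
    hazards: list[str] = field(init=False)
    consequences: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise DataValidationError(
                f"view ({self.species!r}, {self.production_class!r}) contains no records"
            )
        self.indicators = sorted({r.indicator for r in self.records})
        self.hazards = sorted({r.hazard for r in self.records})
        self.consequences = sorted({r.consequence for r in self.records})
        self._impact = _unique_rating(self.records, "consequence", "impact_of_consequence")
        self._mitigation = _unique_rating(self.records, "hazard", "ease_of_mitigation")
        self._ease = _unique_rating(self.records, "indicator", "ease_of_indicator_use")
        self._links: dict[str, set[tuple[str, str]]] = {}
        for r in self.records:
            self._links.setdefault(r.indicator, set()).add((r.hazard, r.consequence))

    # -- metadata accessors (one rating per entity, guaranteed above) ------

    def impact_of(self, consequence: str) -> int:
        try:
            return self._impact[consequence]
        except KeyError:
            raise UnknownEntityError(f"unknown consequence {consequence!r}") from None

    def mitigation_of(self, hazard: str) -> int:
        try:
            return self._mitigation[hazard]
        except KeyError:
            raise UnknownEntityError(f"unknown hazard {hazard!r}") from None

    def ease_of_use(self, indicator: str) -> int:
        try:
            return self._ease[indicator]
        except KeyError:
            raise UnknownEntityError(f"unknown indicator {indicator!r}") from None

    # -- linkage accessors -------------------------------------------------

    def pairs_of(self, indicator: str) -> set[tuple[str, str]]:
        """Distinct (hazard, consequence) pairs linked to *indicator*."""
        try:
            return set(self._links[indicator])
        except KeyError:
            raise UnknownEntityError(
                f"indicator {indicator!r} not in view ({self.species!r}, "
                f"{self.production_class!r})"
            ) from None

    def hazards_of(self, indicator: str) -> set[str]:
        return {h for h, _ in self.pairs_of(indicator)}

    def consequences_of(self, indicator: str) -> set[str]:
        return {c for _, c in self.pairs_of(indicator)}

    def coverage_counts(self, indicator: str) -> CoverageCounts:
        pairs = self.pairs_of(indicator)
        return CoverageCounts(
            indicator=indicator,
            n_hazards=len({h for h, _ in pairs}),
            n_consequences=len({c for _, c in pairs}),
            n_pairs=len(pairs),
        )

    @property
    def all_pairs(self) -> set[tuple[str, str]]:
        """Every distinct (hazard, consequence) pair in the view."""
        return {(r.hazard, r.consequence) for r in self.records}


def _label(value, name: str, row_no: int) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise DataValidationError(f"row {row_no}: missing {name}")
    text = str(value).strip()
    if not text:
        raise DataValidationError(f"row {row_no}: blank {name}")
    return text


def _ordinal(value, levels: Mapping[str, int], name: str, row_no: int) -> int:
    text = _label(value, name, row_no)
    try:
        return levels[text]
    except KeyError:
        raise DataValidationError(
            f"row {row_no}: unknown {name} value {text!r}; expected one of "
            f"{', '.join(levels)}"
        ) from None


def _unique_rating(records, entity_attr: str, rating_attr: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in records:
        label = getattr(r, entity_attr)
        rating = getattr(r, rating_attr)
        if label in out and out[label] != rating:
            raise DataValidationError(
                f"conflicting {rating_attr} ratings for {entity_attr} {label!r} "
                f"within one view: {out[label]} vs {rating}"
            )
        out[label] = rating
    return out


# convenience functional aliases matching the module-level operation names


def load_database(path: str | Path, **read_csv_kwargs) -> LinkageDatabase:
    """Load, validate and deduplicate a canonical linkage CSV."""
    return LinkageDatabase.from_csv(path, **read_csv_kwargs)


def filter_view(db: LinkageDatabase, species: str, production_class: str = ALL) -> DatabaseView:
    return db.view(species, production_class)


def coverage_counts(view: DatabaseView, indicator: str) -> CoverageCounts:
    return view.coverage_counts(indicator)


def write_validation_report(db: LinkageDatabase, path: str | Path) -> None:
    Path(path).write_text(json.dumps(db.validation_report(), indent=2))
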