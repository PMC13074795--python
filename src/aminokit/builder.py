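"""Assemble assignment records into a database; coverage and source reports.

TAA and EAA are materialized at build time as skip-missing sums over their
key sets, so coverage semantics treat them as report variables in their own
right: they count as populated for every non-deferred item even when some
constituent amino acids are missing.  Percentages are stored unrounded;
half-up one-decimal rounding is applied only when a report is serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

from .datamodel import (
    AssignmentCategory,
    AssignmentRecord,
    ConversionFactorTable,
    FoodItem,
    ReferenceFood,
    SimilarityMap,
    ValidationError,
    EAA_KEYS,
    TAA_KEYS,
)
from .matching import DEFAULT_TOLERANCE, DEFAULT_ZERO_BAND, classify_assignment

__all__ = [
    "DEFAULT_VARIABLES",
    "round_half_up",
    "compute_taa",
    "compute_eaa",
    "DatabaseEntry",
    "AminoAcidDatabase",
    "build_database",
    "CoverageReport",
    "coverage_report",
    "SourceCompositionReport",
    "source_composition_report",
]

#: Default report variable set: the two indices, the 18 total-sum keys and
#: taurine — 21 variables.  This is the denominator of overall coverage.
DEFAULT_VARIABLES: tuple[str, ...] = ("TAA", "EAA", *TAA_KEYS, "TAU")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used by all report serialization."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def compute_taa(profile: Mapping[str, float], keys: Sequence[str] = TAA_KEYS) -> float:
    """Sum of available values over the total-amino-acid key set (mg/100 g).

    Missing keys are skipped; taurine never contributes under the default
    key set; an empty intersection yields 0.
    """
    return float(sum(profile[k] for k in keys if k in profile))


def compute_eaa(profile: Mapping[str, float], keys: Sequence[str] = EAA_KEYS) -> float:
    """Sum of available values over the essential key set (mg/100 g)."""
    return compute_taa(profile, keys)


@dataclass(frozen=True)
class DatabaseEntry:
    profile: Optional[Mapping[str, float]]
    taa: Optional[float]
    eaa: Optional[float]
    record: AssignmentRecord


@dataclass(frozen=True)
class AminoAcidDatabase:
    """item_id -> (profile, TAA, EAA, provenance record)."""

    entries: Mapping[str, DatabaseEntry]
    variable_set: tuple[str, ...] = DEFAULT_VARIABLES

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for item_id, entry in self.entries.items():
            if entry.taa is not None and entry.eaa is not None:
                if entry.eaa > entry.taa + 1e-9:
                    raise ValidationError(f"{item_id}: EAA exceeds TAA")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_deferred(self) -> int:
        return sum(
            1
            for e in self.entries.values()
            if e.record.category is AssignmentCategory.DEFERRED
        )


def build_database(
    items: Sequence[FoodItem],
    ref_sets: Sequence[Sequence[ReferenceFood]] | Sequence[ReferenceFood],
    simmap: SimilarityMap,
    factors: ConversionFactorTable,
    tol: float = DEFAULT_TOLERANCE,
    absolute_zero_band: float = DEFAULT_ZERO_BAND,
    taa_keys: Sequence[str] = TAA_KEYS,
    eaa_keys: Sequence[str] = EAA_KEYS,
    variable_set: Sequence[str] = DEFAULT_VARIABLES,
) -> tuple[AminoAcidDatabase, list[AssignmentRecord]]:
    """Classify every item and assemble the database plus provenance ledger.

    ``ref_sets`` may be one reference set or a list of them; later sets are
    extra passes that re-classify only the items still deferred, modelling
    staged expansion of data sources.  Reference sets accumulate across
    passes (pass k sees the union of sets 1..k).  Deterministic for
    identical inputs.
    """
    if ref_sets and isinstance(ref_sets[0], ReferenceFood):
        passes: list[Sequence[ReferenceFood]] = [ref_sets]  # type: ignore[list-item]
    else:
        passes = list(ref_sets)  # type: ignore[arg-type]

    records: dict[str, AssignmentRecord] = {}
    pending = list(items)
    refs: list[ReferenceFood] = []
    for extra in passes:
        refs = refs + list(extra)
        index = {r.id: r for r in refs}
        still_deferred: list[FoodItem] = []
        for item in pending:
            record = classify_assignment(
                item, refs, simmap, factors, tol, absolute_zero_band, _ref_index=index
            )
            records[item.id] = record
            if record.category is AssignmentCategory.DEFERRED:
                still_deferred.append(item)
        pending = still_deferred
        if not pending:
            break

    entries: dict[str, DatabaseEntry] = {}
    ledger: list[AssignmentRecord] = []
    for item in items:
        record = records[item.id]
        ledger.append(record)
        if record.profile is not None:
            entries[item.id] = DatabaseEntry(
                profile=record.profile,
                taa=compute_taa(record.profile, taa_keys),
                eaa=compute_eaa(record.profile, eaa_keys),
                record=record,
            )
        else:
            entries[item.id] = DatabaseEntry(
                profile=None, taa=None, eaa=None, record=record
            )
    return AminoAcidDatabase(entries=entries, variable_set=tuple(variable_set)), ledger


@dataclass(frozen=True)
class CoverageReport:
    """Per-variable non-missing counts/percents and the overall cell percent."""

    n_items: int
    per_variable: Mapping[str, tuple[int, float]]  # var -> (n_nonmissing, percent)
    overall_percent: float

    def percent(self, variable: str) -> float:
        return self.per_variable[variable][1]

    def rounded_percent(self, variable: str) -> float:
        return round_half_up(self.per_variable[variable][1])

    @property
    def rounded_overall(self) -> float:
        return round_half_up(self.overall_percent)

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "variable": var,
                "n_nonmissing": n,
                "percent": round_half_up(pct),
            }
            for var, (n, pct) in self.per_variable.items()
        ]
        rows.append(
            {
                "variable": "OVERALL",
                "n_nonmissing": sum(n for n, _ in self.per_variable.values()),
                "percent": round_half_up(self.overall_percent),
            }
        )
        return rows


def _is_populated(entry: DatabaseEntry, variable: str) -> bool:
    if variable == "TAA":
        return entry.taa is not None
    if variable == "EAA":
        return entry.eaa is not None
    return entry.profile is not None and variable in entry.profile


def coverage_report(db: AminoAcidDatabase) -> CoverageReport:
    """Per-variable and overall coverage over the database's variable set.

    Overall coverage is populated cells / (n_items x n_variables) x 100,
    which equals the equal-weight mean of per-variable percents.
    """
    n_items = len(db.entries)
    if n_items == 0:
        raise ValidationError("empty database: nothing to report")
    per_variable: dict[str, tuple[int, float]] = {}
    populated_cells = 0
    for variable in db.variable_set:
        n = sum(1 for e in db.entries.values() if _is_populated(e, variable))
        per_variable[variable] = (n, n / n_items * 100.0)
        populated_cells += n
    total_cells = n_items * len(db.variable_set)
    return CoverageReport(
        n_items=n_items,
        per_variable=per_variable,
        overall_percent=populated_cells / total_cells * 100.0,
    )


@dataclass(frozen=True)
class SourceCompositionReport:
    """Item counts and percents per (category, source), with subtotals."""

    n_items: int
    by_category_source: Mapping[tuple[str, str], tuple[int, float]]
    by_category: Mapping[str, tuple[int, float]]

    def category_count(self, category: str) -> int:
        return self.by_category.get(category, (0, 0.0))[0]

    def category_percent(self, category: str) -> float:
        return self.by_category.get(category, (0, 0.0))[1]

    def rounded_category_percent(self, category: str) -> float:
        return round_half_up(self.category_percent(category))

    def to_rows(self) -> list[dict]:
        rows = []
        for (category, source), (n, pct) in self.by_category_source.items():
            rows.append(
                {
                    "category": category,
                    "source": source,
                    "n_items": n,
                    "percent": round_half_up(pct),
                }
            )
        for category, (n, pct) in self.by_category.items():
            rows.append(
                {
                    "category": category,
                    "source": "SUBTOTAL",
                    "n_items": n,
                    "percent": round_half_up(pct),
                }
            )
        rows.append(
            {
                "category": "TOTAL",
                "source": "",
                "n_items": self.n_items,
                "percent": 100.0,
            }
        )
        return rows


def source_composition_report(
    ledger: Sequence[AssignmentRecord],
    ref_sources: Optional[Mapping[str, str]] = None,
) -> SourceCompositionReport:
    """Tabulate ledger records by category and donor data source.

    ``ref_sources`` maps reference-food id -> source label; without it the
    source column falls back to the reference id itself (category subtotals
    are unaffected).
    """
    if not ledger:
        raise ValidationError("empty ledger: nothing to report")
    n_items = len(ledger)
    counts: dict[tuple[str, str], int] = {}
    category_counts: dict[str, int] = {}
    for record in ledger:
        category = record.category.value
        if record.source_ref is None:
            source = ""
        elif ref_sources is not None:
            source = ref_sources.get(record.source_ref, record.source_ref)
        else:
            source = record.source_ref
        counts[(category, source)] = counts.get((category, source), 0) + 1
        category_counts[category] = category_counts.get(category, 0) + 1
    by_category_source = {
        key: (n, n / n_items * 100.0) for key, n in sorted(counts.items())
    }
    by_category = {
        cat: (n, n / n_items * 100.0) for cat, n in sorted(category_counts.items())
    }
    return SourceCompositionReport(
        n_items=n_items,
        by_category_source=by_category_source,
        by_category=by_category,
    )
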