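"""Domain types, controlled vocabularies and shared validation.

All composition values are expressed per 100 g edible portion: energy in
kcal, macronutrients and moisture in g, amino acids in mg.  A missing amino
acid value is represented by an *absent key* in the profile mapping, never
by 0, so that skip-missing sums and coverage counting stay unambiguous.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AA_KEYS",
    "TAA_KEYS",
    "EAA_KEYS",
    "NUTRIENT_FIELDS",
    "ValidationError",
    "ConfigError",
    "normalize_name",
    "NutrientVector",
    "validate_profile",
    "ReferenceFood",
    "FoodItem",
    "AssignmentCategory",
    "AssignmentRecord",
    "ConversionFactorTable",
    "SimilarityMap",
    "ParticipantRecord",
    "EARTable",
    "validate_reference_set",
    "validate_items",
]

#: Closed vocabulary of amino acid identifiers (19 tokens).
AA_KEYS: tuple[str, ...] = (
    "ILE", "LEU", "LYS", "MET", "PHE", "THR", "TRP", "VAL", "HIS", "ARG",
    "TYR", "CYS", "ALA", "ASP", "GLU", "GLY", "PRO", "SER", "TAU",
)

#: Keys entering the total-amino-acid sum.  Taurine is carried in profiles
#: but never contributes to the total (its coverage is reported separately).
TAA_KEYS: tuple[str, ...] = tuple(k for k in AA_KEYS if k != "TAU")

#: Keys entering the essential-amino-acid sum (histidine and arginine are
#: retained for consistency with the national composition table).
EAA_KEYS: tuple[str, ...] = (
    "ILE", "LEU", "LYS", "MET", "PHE", "THR", "TRP", "VAL", "HIS", "ARG",
)

NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy", "carbohydrate", "protein", "fat", "moisture",
)

_WS = re.compile(r"\s+")


class ValidationError(ValueError):
    """Invalid input data (maps to CLI exit code 1)."""


class ConfigError(Exception):
    """Invalid or incomplete configuration (maps to CLI exit code 2)."""


def normalize_name(raw: str) -> str:
    """Canonicalize a food name or preparation-form token.

    Case-folds, strips leading/trailing whitespace and collapses internal
    whitespace runs to single spaces.  Idempotent.

    Raises
    ------
    ValidationError
        If the result is empty.
    """
    canonical = _WS.sub(" ", str(raw).strip()).casefold()
    if not canonical:
        raise ValidationError(f"name empty after normalization: {raw!r}")
    return canonical


@dataclass(frozen=True)
class NutrientVector:
    """Macronutrient vector per 100 g edible portion.

    All five fields are mandatory; matching never operates on incomplete
    macronutrient data.
    """

    energy: float       # kcal/100 g
    carbohydrate: float  # g/100 g
    protein: float       # g/100 g
    fat: float           # g/100 g
    moisture: float      # g/100 g

    def __post_init__(self) -> None:
        for name in NUTRIENT_FIELDS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValidationError(f"nutrient {name} is missing")
            if value < 0:
                raise ValidationError(f"nutrient {name} is negative: {value}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in NUTRIENT_FIELDS}


def validate_profile(profile: Mapping[str, float]) -> dict[str, float]:
    """Validate an amino acid profile mapping (mg/100 g).

    Keys must belong to the closed vocabulary; values must be >= 0.
    Returns a plain dict copy.
    """
    out: dict[str, float] = {}
    for key, value in profile.items():
        if key not in AA_KEYS:
            raise ValidationError(f"unknown amino acid key: {key!r}")
        v = float(value)
        if math.isnan(v) or v < 0:
            raise ValidationError(f"invalid value for {key}: {value!r}")
        out[key] = v
    return out


@dataclass(frozen=True)
class ReferenceFood:
    """A composition-table entry that may donate an amino acid profile."""

    id: str
    name: str
    preparation: str
    food_group: str
    similarity_key: str
    nutrients: NutrientVector
    profile: Optional[Mapping[str, float]] = None
    source: str = ""
    is_analytical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "preparation", normalize_name(self.preparation))
        if self.profile is not None:
            object.__setattr__(self, "profile", validate_profile(self.profile))
        if self.is_analytical and self.profile is None:
            raise ValidationError(
                f"reference {self.id}: analytical flag set but profile absent"
            )


@dataclass(frozen=True)
class FoodItem:
    """An FFQ food item awaiting a profile assignment."""

    id: str
    name: str
    preparation: str
    food_group: str
    similarity_key: str
    nutrients: NutrientVector

    def __post_init__(self) -> None:
        object.__setattr__(self, "preparation", normalize_name(self.preparation))


class AssignmentCategory(str, Enum):
    ANALYTICAL = "ANALYTICAL"
    CALCULATED = "CALCULATED"
    SUBSTITUTED = "SUBSTITUTED"
    DEFERRED = "DEFERRED"


@dataclass(frozen=True)
class AssignmentRecord:
    """Provenance outcome of the decision tree for one item.

    ``trace`` is the ordered list of (decision-node label, boolean outcome)
    pairs actually visited; it is the auditable path through the tree.
    """

    item_id: str
    category: AssignmentCategory
    profile: Optional[Mapping[str, float]]
    source_ref: Optional[str]
    trace: tuple[tuple[str, bool], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trace", tuple((str(n), bool(v)) for n, v in self.trace))
        if not self.trace:
            raise ValidationError(f"{self.item_id}: empty decision trace")
        deferred = self.category is AssignmentCategory.DEFERRED
        if deferred != (self.profile is None):
            raise ValidationError(
                f"{self.item_id}: profile must be absent iff category is DEFERRED"
            )
        if self.profile is not None:
            object.__setattr__(self, "profile", validate_profile(self.profile))

    def to_json_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "category": self.category.value,
            "profile": dict(self.profile) if self.profile is not None else None,
            "source_ref": self.source_ref,
            "trace": [[node, outcome] for node, outcome in self.trace],
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "AssignmentRecord":
        return cls(
            item_id=d["item_id"],
            category=AssignmentCategory(d["category"]),
            profile=d.get("profile"),
            source_ref=d.get("source_ref"),
            trace=tuple((n, bool(v)) for n, v in d["trace"]),
        )


@dataclass(frozen=True)
class ConversionFactorTable:
    """Nitrogen-to-protein conversion factors keyed by food group."""

    factors: Mapping[str, float] = field(default_factory=dict)
    default: Optional[float] = 6.25

    def __post_init__(self) -> None:
        for group, factor in self.factors.items():
            if factor <= 0:
                raise ConfigError(f"conversion factor for {group!r} must be > 0")
        if self.default is not None and self.default <= 0:
            raise ConfigError("default conversion factor must be > 0")
        object.__setattr__(self, "factors", dict(self.factors))

    def get(self, food_group: str) -> float:
        if food_group in self.factors:
            return self.factors[food_group]
        if self.default is None:
            raise ConfigError(
                f"no conversion factor for food group {food_group!r} and no default"
            )
        return self.default


@dataclass(frozen=True)
class SimilarityMap:
    """Ordered similar-food candidates per item, most similar first.

    Each candidate carries a rationale tag: TAXONOMIC for natural foods
    (species/genus/family comparison) or FOOD_TYPE for processed foods.
    """

    candidates_by_item: Mapping[str, Sequence[tuple[str, str]]] = field(
        default_factory=dict
    )

    _RATIONALES = frozenset({"TAXONOMIC", "FOOD_TYPE"})

    def __post_init__(self) -> None:
        clean: dict[str, tuple[tuple[str, str], ...]] = {}
        for item_id, cands in self.candidates_by_item.items():
            seen: set[str] = set()
            out = []
            for ref_id, rationale in cands:
                if rationale not in self._RATIONALES:
                    raise ValidationError(
                        f"similarity map {item_id}: unknown rationale {rationale!r}"
                    )
                if ref_id in seen:
                    raise ValidationError(
                        f"similarity map {item_id}: duplicate candidate {ref_id!r}"
                    )
                seen.add(ref_id)
                out.append((ref_id, rationale))
            clean[item_id] = tuple(out)
        object.__setattr__(self, "candidates_by_item", clean)

    def candidates(self, item_id: str) -> tuple[str, ...]:
        """Ordered candidate reference ids for an item (may be empty)."""
        return tuple(rid for rid, _ in self.candidates_by_item.get(item_id, ()))

    def check_resolvable(self, ref_ids: Iterable[str]) -> None:
        known = set(ref_ids)
        for item_id, cands in self.candidates_by_item.items():
            for rid, _ in cands:
                if rid not in known:
                    raise ConfigError(
                        f"similarity map {item_id}: unknown reference id {rid!r}"
                    )


@dataclass(frozen=True)
class ParticipantRecord:
    """Cohort participant with per-item consumption responses.

    ``responses`` maps item_id -> (frequency events/day, portion g/event).
    """

    id: str
    sex: str
    age: float
    body_weight: float
    responses: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"participant {self.id}: sex must be M or F")
        if self.age < 0:
            raise ValidationError(f"participant {self.id}: negative age")
        if self.body_weight <= 0:
            raise ValidationError(f"participant {self.id}: body weight must be > 0")
        clean = {}
        for item_id, (freq, portion) in self.responses.items():
            if freq < 0 or portion < 0:
                raise ValidationError(
                    f"participant {self.id}: negative response for {item_id}"
                )
            clean[item_id] = (float(freq), float(portion))
        object.__setattr__(self, "responses", clean)


# Protein EAR coefficient: requirement of 0.66 g/kg/day divided by a 0.9
# digestibility-quality adjustment, applied per kg body weight.
DEFAULT_PROTEIN_COEFFICIENT = 0.66 / 0.9

DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = ((30, 49), (50, 64), (65, 74))


@dataclass(frozen=True)
class EARTable:
    """Estimated Average Requirement configuration.

    ``aa_requirements`` maps a requirement key to mg/kg/day; a key may be a
    single amino acid token or a declared combination joined with '+'
    (e.g. ``PHE+TYR``, compared against the summed intake of its parts).
    """

    protein_coefficient: float = DEFAULT_PROTEIN_COEFFICIENT
    aa_requirements: Mapping[str, float] = field(default_factory=dict)
    age_bins: tuple[tuple[float, float], ...] = DEFAULT_AGE_BINS

    def __post_init__(self) -> None:
        if self.protein_coefficient <= 0:
            raise ConfigError("protein coefficient must be > 0")
        for key, value in self.aa_requirements.items():
            if value <= 0:
                raise ConfigError(f"EAR requirement for {key!r} must be > 0")
            for part in key.split("+"):
                if part not in AA_KEYS:
                    raise ConfigError(f"EAR key {key!r}: unknown amino acid {part!r}")
        bins = tuple((float(lo), float(hi)) for lo, hi in self.age_bins)
        prev_hi = -math.inf
        for lo, hi in bins:
            if lo > hi:
                raise ConfigError(f"age bin [{lo}, {hi}] is inverted")
            if lo <= prev_hi:
                raise ConfigError("age bins must be ordered and non-overlapping")
            prev_hi = hi
        object.__setattr__(self, "aa_requirements", dict(self.aa_requirements))
        object.__setattr__(self, "age_bins", bins)

    def age_bin_of(self, age: float) -> Optional[tuple[float, float]]:
        """Closed-interval age bin containing ``age``, or None."""
        for lo, hi in self.age_bins:
            if lo <= age <= hi:
                return (lo, hi)
        return None


def validate_reference_set(refs: Sequence[ReferenceFood]) -> list[dict]:
    """Report invariant violations across a reference set.

    Returns one dict per violation with keys ``id``, ``field`` and
    ``message``; an empty list means the set is valid.  Reports rather than
    raises so callers can aggregate.
    """
    violations: list[dict] = []
    seen: set[str] = set()
    for ref in refs:
        if ref.id in seen:
            violations.append(
                {"id": ref.id, "field": "id", "message": "duplicate reference id"}
            )
        seen.add(ref.id)
        # Constructor-level invariants are re-checked defensively here for
        # records built by bypassing the constructor (e.g. deserialization).
        if ref.is_analytical and ref.profile is None:
            violations.append(
                {
                    "id": ref.id,
                    "field": "is_analytical",
                    "message": "analytical flag set but profile absent",
                }
            )
        if ref.profile is not None:
            for key, value in ref.profile.items():
                if value < 0:
                    violations.append(
                        {
                            "id": ref.id,
                            "field": key,
                            "message": f"negative amino acid value {value}",
                        }
                    )
    return violations


def validate_items(items: Sequence[FoodItem]) -> list[dict]:
    """Report duplicate ids within an item list."""
    violations: list[dict] = []
    seen: set[str] = set()
    for item in items:
        if item.id in seen:
            violations.append(
                {"id": item.id, "field": "id", "message": "duplicate item id"}
            )
        seen.add(item.id)
    return violations
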