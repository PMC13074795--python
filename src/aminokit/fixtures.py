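"""Deterministic synthetic fixtures with embedded ground truth.

For each item the generator constructs reference candidates that force
exactly one decision path, so the matching engine's output can be scored
against a known category.  Cohorts are generated so the realized fraction
of participants below the protein requirement is a Bernoulli draw at the
configured target, enabling parameter-recovery tests without external data.

One integer seed drives a single numpy Generator stream; fixtures are
byte-identical across runs for a fixed spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .builder import AminoAcidDatabase
from .datamodel import (
    AA_KEYS,
    TAA_KEYS,
    AssignmentCategory,
    ConversionFactorTable,
    FoodItem,
    NutrientVector,
    ParticipantRecord,
    ReferenceFood,
    SimilarityMap,
    ValidationError,
)
from .intake import protein_ear

__all__ = [
    "FixtureSpec",
    "ReferenceFixture",
    "largest_remainder",
    "generate_reference_set",
    "generate_cohort",
]

_CATEGORY_ORDER = (
    AssignmentCategory.ANALYTICAL,
    AssignmentCategory.CALCULATED,
    AssignmentCategory.SUBSTITUTED,
    AssignmentCategory.DEFERRED,
)

# Placeholder nitrogen-to-protein factors; real national-table values are
# user data, not shipped.
_FOOD_GROUPS = ("cereal", "legume", "vegetable", "meat", "fish", "dairy")
_FACTORS = {
    "cereal": 5.95,
    "legume": 5.71,
    "vegetable": 6.25,
    "meat": 6.25,
    "fish": 6.25,
    "dairy": 6.38,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling fixture generation."""

    seed: int = 0
    n_items: int = 475
    #: target proportions over (ANALYTICAL, CALCULATED, SUBSTITUTED, DEFERRED)
    path_mix: tuple[float, float, float, float] = (0.31, 0.64, 0.05, 0.0)
    #: per-key probability that a generated profile lacks that key
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    #: exact per-key missing counts (overrides missing_rates when given)
    missing_counts: Optional[Mapping[str, int]] = None
    cohort_size: int = 500
    items_per_participant: tuple[int, int] = (10, 30)
    #: lognormal sigma of the intake-to-requirement ratio
    intake_sigma: float = 0.4
    #: multiplicative per-sex intake scale (1.0 = calibrated to the target)
    sex_scale: Mapping[str, float] = field(
        default_factory=lambda: {"M": 1.0, "F": 1.0}
    )
    below_ear_target: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.path_mix) - 1.0) > 1e-9:
            raise ValidationError("path_mix proportions must sum to 1")
        if any(p < 0 for p in self.path_mix):
            raise ValidationError("path_mix proportions must be >= 0")
        for key, rate in self.missing_rates.items():
            if key not in AA_KEYS or not (0.0 <= rate <= 1.0):
                raise ValidationError(f"invalid missing rate {key}={rate}")
        if not (0.0 < self.below_ear_target < 1.0):
            raise ValidationError("below_ear_target must be in (0, 1)")


@dataclass(frozen=True)
class ReferenceFixture:
    """Generated inputs plus the embedded ground-truth categories."""

    items: tuple[FoodItem, ...]
    refs: tuple[ReferenceFood, ...]
    simmap: SimilarityMap
    factors: ConversionFactorTable
    expected: Mapping[str, AssignmentCategory]

    @property
    def protein_db(self) -> dict[str, float]:
        return {item.id: item.nutrients.protein for item in self.items}


def largest_remainder(proportions: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to n, closest to n*proportions (largest remainder)."""
    exact = [p * n for p in proportions]
    counts = [math.floor(x) for x in exact]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(exact)), key=lambda i: (exact[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def _nutrients(rng: np.random.Generator) -> NutrientVector:
    # All components bounded away from zero so relative tolerance is well
    # defined everywhere.
    return NutrientVector(
        energy=float(rng.uniform(80, 400)),
        carbohydrate=float(rng.uniform(5, 60)),
        protein=float(rng.uniform(4, 30)),
        fat=float(rng.uniform(1, 20)),
        moisture=float(rng.uniform(20, 80)),
    )


def _scaled(nv: NutrientVector, factors: np.ndarray) -> NutrientVector:
    return NutrientVector(
        energy=nv.energy * factors[0],
        carbohydrate=nv.carbohydrate * factors[1],
        protein=nv.protein * factors[2],
        fat=nv.fat * factors[3],
        moisture=nv.moisture * factors[4],
    )


def _profile(
    rng: np.random.Generator, protein: float, missing: frozenset[str]
) -> dict[str, float]:
    """Profile with sum over total-sum keys <= 0.95 x protein mg."""
    total = protein * 1000.0 * rng.uniform(0.80, 0.95)
    weights = rng.dirichlet(np.ones(len(TAA_KEYS)))
    profile = {k: float(total * w) for k, w in zip(TAA_KEYS, weights)}
    profile["TAU"] = float(protein * 1000.0 * rng.uniform(0.005, 0.02))
    for key in missing:
        profile.pop(key, None)
    if not profile:
        profile["GLU"] = float(total)  # never emit an empty analytical profile
    return profile


def _missing_flags(spec: FixtureSpec, rng: np.random.Generator) -> list[frozenset[str]]:
    """Per-item sets of amino acid keys to drop from the donated profile."""
    flags: list[set[str]] = [set() for _ in range(spec.n_items)]
    if spec.missing_counts is not None:
        for key, count in spec.missing_counts.items():
            if key not in AA_KEYS:
                raise ValidationError(f"unknown key in missing_counts: {key}")
            if not 0 <= count <= spec.n_items:
                raise ValidationError(f"missing count out of range for {key}: {count}")
            chosen = rng.choice(spec.n_items, size=count, replace=False)
            for idx in chosen:
                flags[int(idx)].add(key)
    else:
        for key, rate in spec.missing_rates.items():
            hits = rng.random(spec.n_items) < rate
            for idx in np.nonzero(hits)[0]:
                flags[int(idx)].add(key)
    return [frozenset(f) for f in flags]


def generate_reference_set(spec: FixtureSpec) -> ReferenceFixture:
    """Construct items, references, similarity map and ground-truth labels.

    Decision paths are forced per item:

    - ANALYTICAL: same-name, same-form analytical reference with every
      macronutrient offset at most 15% (inside the 20% tolerance).
    - CALCULATED: either a non-concordant analytical similar food offset by
      25-45% (out of tolerance), or — every third such item — a same-name,
      same-form analytical reference out of tolerance plus an other-form
      analytical similar food, exercising the other calculated branch.
    - SUBSTITUTED: non-concordant analytical similar food inside tolerance.
    - DEFERRED: similar candidates exist but none is analytical.
    """
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder(spec.path_mix, spec.n_items)
    categories: list[AssignmentCategory] = []
    for category, count in zip(_CATEGORY_ORDER, counts):
        categories.extend([category] * count)
    categories = [categories[i] for i in rng.permutation(spec.n_items)]
    missing = _missing_flags(spec, rng)

    items: list[FoodItem] = []
    refs: list[ReferenceFood] = []
    simmap_entries: dict[str, list[tuple[str, str]]] = {}
    expected: dict[str, AssignmentCategory] = {}

    for i, category in enumerate(categories):
        item_id = f"F{i:04d}"
        group = _FOOD_GROUPS[i % len(_FOOD_GROUPS)]
        simkey = f"sim{i:04d}"
        name = f"food {i:04d}"
        prep = "raw" if i % 2 == 0 else "boiled"
        nutrients = _nutrients(rng)
        item = FoodItem(
            id=item_id,
            name=name,
            preparation=prep,
            food_group=group,
            similarity_key=simkey,
            nutrients=nutrients,
        )
        items.append(item)
        expected[item_id] = category
        ref_id = f"R{i:04d}"
        rationale = "TAXONOMIC" if i % 2 == 0 else "FOOD_TYPE"

        if category is AssignmentCategory.ANALYTICAL:
            offsets = rng.uniform(0.85, 1.15, size=5)
            refs.append(
                ReferenceFood(
                    id=ref_id,
                    name=name,
                    preparation=prep,
                    food_group=group,
                    similarity_key=simkey,
                    nutrients=_scaled(nutrients, offsets),
                    profile=_profile(rng, nutrients.protein, missing[i]),
                    source="synthetic national table",
                    is_analytical=True,
                )
            )
            simmap_entries[item_id] = [(ref_id, rationale)]
        elif category is AssignmentCategory.CALCULATED:
            signs = rng.choice([-1.0, 1.0], size=5)
            offsets = 1.0 + signs * rng.uniform(0.25, 0.45, size=5)
            similar_nutrients = _scaled(nutrients, offsets)
            profile = _profile(rng, similar_nutrients.protein, missing[i])
            if i % 3 == 0:
                # Same-name, same-form analytical reference out of tolerance
                # plus an analytical similar food with a different form.
                other_prep = "boiled" if prep == "raw" else "raw"
                refs.append(
                    ReferenceFood(
                        id=f"{ref_id}d",
                        name=name,
                        preparation=prep,
                        food_group=group,
                        similarity_key=simkey,
                        nutrients=similar_nutrients,
                        profile=_profile(rng, similar_nutrients.protein, missing[i]),
                        source="synthetic national table",
                        is_analytical=True,
                    )
                )
                refs.append(
                    ReferenceFood(
                        id=ref_id,
                        name=f"similar {i:04d}",
                        preparation=other_prep,
                        food_group=group,
                        similarity_key=simkey,
                        nutrients=similar_nutrients,
                        profile=profile,
                        source="synthetic foreign table",
                        is_analytical=True,
                    )
                )
            else:
                refs.append(
                    ReferenceFood(
                        id=ref_id,
                        name=f"similar {i:04d}",
                        preparation=prep,
                        food_group=group,
                        similarity_key=simkey,
                        nutrients=similar_nutrients,
                        profile=profile,
                        source="synthetic foreign table",
                        is_analytical=True,
                    )
                )
            simmap_entries[item_id] = [(ref_id, rationale)]
        elif category is AssignmentCategory.SUBSTITUTED:
            offsets = rng.uniform(0.85, 1.15, size=5)
            refs.append(
                ReferenceFood(
                    id=ref_id,
                    name=f"similar {i:04d}",
                    preparation=prep,
                    food_group=group,
                    similarity_key=simkey,
                    nutrients=_scaled(nutrients, offsets),
                    profile=_profile(rng, nutrients.protein, missing[i]),
                    source="synthetic seafood table",
                    is_analytical=True,
                )
            )
            simmap_entries[item_id] = [(ref_id, rationale)]
        else:  # DEFERRED: a similar candidate exists but lacks analytical data
            refs.append(
                ReferenceFood(
                    id=ref_id,
                    name=f"similar {i:04d}",
                    preparation=prep,
                    food_group=group,
                    similarity_key=simkey,
                    nutrients=_nutrients(rng),
                    profile=None,
                    source="synthetic national table",
                    is_analytical=False,
                )
            )
            simmap_entries[item_id] = [(ref_id, rationale)]

    return ReferenceFixture(
        items=tuple(items),
        refs=tuple(refs),
        simmap=SimilarityMap(simmap_entries),
        factors=ConversionFactorTable(factors=dict(_FACTORS), default=6.25),
        expected=expected,
    )


def generate_cohort(
    spec: FixtureSpec,
    db: AminoAcidDatabase,
    protein_db: Mapping[str, float],
) -> list[ParticipantRecord]:
    """Cohort whose protein intakes straddle the requirement at a known rate.

    Each participant's intake-to-requirement ratio is
    ``exp(sigma * z + m) * sex_scale`` with ``m`` chosen so that, at unit
    sex scale, the probability of falling below the requirement is exactly
    ``below_ear_target``; responses are rescaled so realized protein intake
    hits that ratio, making the below-requirement indicator an exact
    Bernoulli(target) draw per participant.
    """
    if spec.cohort_size == 0:
        return []
    usable = [
        item_id
        for item_id, entry in db.entries.items()
        if entry.profile is not None and protein_db.get(item_id, 0.0) > 0
    ]
    if not usable:
        raise ValidationError("database has no resolvable items with protein data")
    usable = sorted(usable)
    rng = np.random.default_rng(spec.seed + 1)
    sigma = spec.intake_sigma
    m = -sigma * float(norm.ppf(spec.below_ear_target))
    lo, hi = spec.items_per_participant
    participants: list[ParticipantRecord] = []
    for j in range(spec.cohort_size):
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(rng.integers(30, 75))
        weight = float(
            max(35.0, rng.normal(71.0, 8.0) if sex == "M" else rng.normal(58.0, 7.0))
        )
        z = float(rng.standard_normal())
        ratio = math.exp(sigma * z + m) * float(spec.sex_scale.get(sex, 1.0))
        target_protein = protein_ear(weight) * ratio
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        k = min(max(k, 1), len(usable))
        chosen = rng.choice(len(usable), size=k, replace=False)
        responses: dict[str, tuple[float, float]] = {}
        raw_protein = 0.0
        for idx in chosen:
            item_id = usable[int(idx)]
            freq = float(rng.lognormal(mean=-1.0, sigma=0.8))
            portion = float(rng.lognormal(mean=4.0, sigma=0.5))
            responses[item_id] = (freq, portion)
            raw_protein += freq * portion / 100.0 * protein_db[item_id]
        scale = target_protein / raw_protein
        responses = {
            item_id: (freq, portion * scale)
            for item_id, (freq, portion) in responses.items()
        }
        participants.append(
            ParticipantRecord(
                id=f"P{j:05d}",
                sex=sex,
                age=age,
                body_weight=weight,
                responses=responses,
            )
        )
    return participants
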