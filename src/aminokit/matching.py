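"""Sequential decision algorithm assigning a provenance category per item.

The tree, in order:

A.  Exact name concordance (post-normalization) against the reference set.
    A1. Among name matches, restrict to identical preparation form.
        A1a. If the best such candidate carries an analytical profile and
             every macronutrient difference is within tolerance, the profile
             is copied verbatim -> ANALYTICAL.
        A1b. Otherwise, if any similar-map candidate with a *different*
             preparation form carries an analytical profile, the profile is
             rescaled by the nitrogen ratio -> CALCULATED.
        A1c. Otherwise -> DEFERRED.
    A2. Name matches exist but none share the preparation form: fall
        through to B.
B.  Scan similar-map candidates in order for the first with an analytical
    profile.
    B1. Within tolerance -> SUBSTITUTED (profile copied verbatim).
    B2. Out of tolerance -> CALCULATED (nitrogen-ratio rescaling).
    B3. No analytical candidate -> DEFERRED.

"Best" candidate among name/form matches is the first in similar-map order;
candidates absent from the map rank after, in lexicographic id order.
Tolerance is relative to the target item's value, boundary inclusive.
Every node visited is appended to the record's trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .datamodel import (
    AssignmentCategory,
    AssignmentRecord,
    ConfigError,
    ConversionFactorTable,
    FoodItem,
    NutrientVector,
    ReferenceFood,
    SimilarityMap,
    ValidationError,
    NUTRIENT_FIELDS,
    normalize_name,
)
from .nitrogen import nitrogen_corrected_profile, nitrogen_from_protein

__all__ = ["ToleranceReport", "nutrient_tolerance", "classify_assignment"]

DEFAULT_TOLERANCE = 0.20
DEFAULT_ZERO_BAND = 0.5


@dataclass(frozen=True)
class ToleranceReport:
    """Per-nutrient relative differences and the conjunction verdict."""

    differences: Mapping[str, float]
    within: bool
    tolerance: float


def nutrient_tolerance(
    target: NutrientVector,
    candidate: NutrientVector,
    tol: float = DEFAULT_TOLERANCE,
    absolute_zero_band: float = DEFAULT_ZERO_BAND,
) -> ToleranceReport:
    """Compare candidate macronutrients against the target item's.

    Relative difference is ``|candidate - target| / target``; a zero target
    is treated as zero difference when the candidate stays inside the
    absolute zero band, infinite otherwise.  Boundary equality counts as
    within tolerance.
    """
    if tol <= 0:
        raise ConfigError(f"tolerance must be > 0, got {tol}")
    differences: dict[str, float] = {}
    for name in NUTRIENT_FIELDS:
        t = getattr(target, name)
        c = getattr(candidate, name)
        if t > 0:
            differences[name] = abs(c - t) / t
        elif c <= absolute_zero_band:
            differences[name] = 0.0
        else:
            differences[name] = math.inf
    within = all(d <= tol for d in differences.values())
    return ToleranceReport(differences=differences, within=within, tolerance=tol)


def _ordered(
    candidates: Sequence[ReferenceFood], sim_order: Sequence[str]
) -> list[ReferenceFood]:
    rank = {rid: i for i, rid in enumerate(sim_order)}
    mapped = sorted((c for c in candidates if c.id in rank), key=lambda c: rank[c.id])
    rest = sorted((c for c in candidates if c.id not in rank), key=lambda c: c.id)
    return mapped + rest


def _calculated(
    item: FoodItem,
    similar: ReferenceFood,
    factors: ConversionFactorTable,
    trace: list[tuple[str, bool]],
) -> AssignmentRecord:
    n_target = nitrogen_from_protein(item.nutrients.protein, factors.get(item.food_group))
    n_similar = nitrogen_from_protein(
        similar.nutrients.protein, factors.get(similar.food_group)
    )
    if n_similar <= 0:
        raise ValidationError(
            f"{item.id}: similar food {similar.id} has zero nitrogen; cannot scale"
        )
    profile = nitrogen_corrected_profile(similar.profile, n_target, n_similar)
    return AssignmentRecord(
        item_id=item.id,
        category=AssignmentCategory.CALCULATED,
        profile=profile,
        source_ref=similar.id,
        trace=tuple(trace),
    )


def classify_assignment(
    item: FoodItem,
    refs: Sequence[ReferenceFood],
    simmap: SimilarityMap,
    factors: ConversionFactorTable,
    tol: float = DEFAULT_TOLERANCE,
    absolute_zero_band: float = DEFAULT_ZERO_BAND,
    _ref_index: Optional[Mapping[str, ReferenceFood]] = None,
) -> AssignmentRecord:
    """Run the decision tree for one item and return its AssignmentRecord.

    ``_ref_index`` is an optional prebuilt id -> ReferenceFood mapping used
    by batch callers to avoid re-indexing per item.
    """
    index = _ref_index if _ref_index is not None else {r.id: r for r in refs}
    sim_ids = simmap.candidates(item.id)
    for rid in sim_ids:
        if rid not in index:
            raise ConfigError(
                f"{item.id}: similarity candidate {rid!r} not in reference set"
            )

    trace: list[tuple[str, bool]] = []
    item_name = normalize_name(item.name)
    name_matches = [r for r in refs if normalize_name(r.name) == item_name]
    trace.append(("name_match", bool(name_matches)))

    if name_matches:
        same_form = [r for r in name_matches if r.preparation == item.preparation]
        trace.append(("form_match", bool(same_form)))
        if same_form:
            best = _ordered(same_form, sim_ids)[0]
            direct = best.is_analytical and best.profile is not None
            trace.append(("direct_analytical", direct))
            if direct:
                report = nutrient_tolerance(
                    item.nutrients, best.nutrients, tol, absolute_zero_band
                )
                trace.append(("direct_tolerance", report.within))
                if report.within:
                    return AssignmentRecord(
                        item_id=item.id,
                        category=AssignmentCategory.ANALYTICAL,
                        profile=dict(best.profile),
                        source_ref=best.id,
                        trace=tuple(trace),
                    )
            similar = next(
                (
                    index[rid]
                    for rid in sim_ids
                    if index[rid].is_analytical
                    and index[rid].profile is not None
                    and index[rid].preparation != item.preparation
                ),
                None,
            )
            trace.append(("similar_other_form_analytical", similar is not None))
            if similar is not None:
                return _calculated(item, similar, factors, trace)
            return AssignmentRecord(
                item_id=item.id,
                category=AssignmentCategory.DEFERRED,
                profile=None,
                source_ref=None,
                trace=tuple(trace),
            )
        # A2: name matched but no shared preparation form -> fall through.

    similar = next(
        (
            index[rid]
            for rid in sim_ids
            if index[rid].is_analytical and index[rid].profile is not None
        ),
        None,
    )
    trace.append(("similar_analytical", similar is not None))
    if similar is not None:
        report = nutrient_tolerance(
            item.nutrients, similar.nutrients, tol, absolute_zero_band
        )
        trace.append(("similar_tolerance", report.within))
        if report.within:
            return AssignmentRecord(
                item_id=item.id,
                category=AssignmentCategory.SUBSTITUTED,
                profile=dict(similar.profile),
                source_ref=similar.id,
                trace=tuple(trace),
            )
        return _calculated(item, similar, factors, trace)
    return AssignmentRecord(
        item_id=item.id,
        category=AssignmentCategory.DEFERRED,
        profile=None,
        source_ref=None,
        trace=tuple(trace),
    )
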