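"""Per-participant intake estimation and EAR-based adequacy reporting.

Intake arithmetic is standard FFQ linkage: for each reported item,
frequency (events/day) x portion (g/event) / 100 x content (per 100 g).
Adequacy compares intakes strictly below the requirement; an intake exactly
at the EAR counts as adequate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .builder import AminoAcidDatabase, round_half_up
from .datamodel import (
    AA_KEYS,
    EAA_KEYS,
    TAA_KEYS,
    EARTable,
    ParticipantRecord,
    ValidationError,
)

__all__ = [
    "IntakeResult",
    "item_contribution",
    "participant_intakes",
    "protein_ear",
    "AdequacyReport",
    "below_ear_proportions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntakeResult:
    participant_id: str
    protein: float                    # g/day
    per_aa: Mapping[str, float]       # mg/day, key present iff any item contributed
    taa: float                        # mg/day
    eaa: float                        # mg/day
    taa_protein_percent: Optional[float]  # None when protein intake is 0


def item_contribution(
    frequency_per_day: float,
    portion_g: float,
    profile: Mapping[str, float],
) -> dict[str, float]:
    """mg/day contributed by one item; missing profile keys contribute nothing."""
    if frequency_per_day < 0 or portion_g < 0:
        raise ValidationError("frequency and portion must be >= 0")
    scale = frequency_per_day * portion_g / 100.0
    return {key: value * scale for key, value in profile.items()}


def participant_intakes(
    participant: ParticipantRecord,
    db: AminoAcidDatabase,
    protein_db: Mapping[str, float],
    strict: bool = True,
    taa_keys: Sequence[str] = TAA_KEYS,
    eaa_keys: Sequence[str] = EAA_KEYS,
) -> IntakeResult:
    """Aggregate all responses of one participant through the database.

    ``protein_db`` maps item_id -> protein g/100 g (the FFQ recipe values).
    Unknown item ids raise in strict mode and are logged and skipped in
    lenient mode.
    """
    per_aa: dict[str, float] = {}
    protein = 0.0
    for item_id, (freq, portion) in participant.responses.items():
        entry = db.entries.get(item_id)
        if entry is None or item_id not in protein_db:
            if strict:
                raise ValidationError(
                    f"participant {participant.id}: unknown item {item_id!r}"
                )
            logger.warning(
                "participant %s: skipping unknown item %s", participant.id, item_id
            )
            continue
        scale = freq * portion / 100.0
        protein += scale * protein_db[item_id]
        if entry.profile is not None:
            for key, value in entry.profile.items():
                per_aa[key] = per_aa.get(key, 0.0) + value * scale
    taa = sum(per_aa.get(k, 0.0) for k in taa_keys)
    eaa = sum(per_aa.get(k, 0.0) for k in eaa_keys)
    ratio = taa / (protein * 1000.0) * 100.0 if protein > 0 else None
    return IntakeResult(
        participant_id=participant.id,
        protein=protein,
        per_aa=per_aa,
        taa=taa,
        eaa=eaa,
        taa_protein_percent=ratio,
    )


def protein_ear(body_weight: float, coefficient: float = 0.66 / 0.9) -> float:
    """Protein requirement in g/day: coefficient (g/kg/day) x body weight."""
    if body_weight <= 0:
        raise ValidationError(f"body weight must be > 0, got {body_weight}")
    return coefficient * body_weight


#: Requirement key used for protein rows in the adequacy report.
PROTEIN_KEY = "PROTEIN"
ALL_AGES = "all"
TOTAL = "total"


@dataclass(frozen=True)
class AdequacyReport:
    """percent of participants below requirement per (sex, age group, key)."""

    rows: tuple[dict, ...]

    def percent(self, sex: str, age_group: str, key: str) -> float:
        for row in self.rows:
            if (
                row["sex"] == sex
                and row["age_group"] == age_group
                and row["requirement"] == key
            ):
                return row["percent"]
        raise KeyError((sex, age_group, key))

    def to_rows(self) -> list[dict]:
        return [
            {**row, "percent": round_half_up(row["percent"])} for row in self.rows
        ]


def _requirement_intake(intake: IntakeResult, key: str) -> float:
    if key == PROTEIN_KEY:
        return intake.protein
    return sum(intake.per_aa.get(part, 0.0) for part in key.split("+"))


def _is_below(
    participant: ParticipantRecord, intake: IntakeResult, key: str, ears: EARTable
) -> bool:
    if key == PROTEIN_KEY:
        requirement = protein_ear(participant.body_weight, ears.protein_coefficient)
    else:
        requirement = ears.aa_requirements[key] * participant.body_weight
    return _requirement_intake(intake, key) < requirement


def below_ear_proportions(
    cohort: Sequence[tuple[ParticipantRecord, IntakeResult]],
    ears: EARTable,
    strict: bool = True,
) -> AdequacyReport:
    """Proportion of participants below requirement, by sex and age group.

    Rows are emitted for sex strata ``total``/``M``/``F`` crossed with each
    configured age bin plus an ``all`` pseudo-bin, for the protein
    requirement and every configured amino acid requirement (combined keys
    such as ``PHE+TYR`` compare summed intake to the combined value).
    Participants outside every age bin raise in strict mode, and are
    excluded with a log message in lenient mode.
    """
    if not cohort:
        raise ValidationError("empty cohort: nothing to report")
    placed: list[tuple[ParticipantRecord, IntakeResult, str]] = []
    for participant, intake in cohort:
        bin_ = ears.age_bin_of(participant.age)
        if bin_ is None:
            if strict:
                raise ValidationError(
                    f"participant {participant.id}: age {participant.age} outside all bins"
                )
            logger.warning(
                "participant %s: age %s outside all bins, excluded",
                participant.id,
                participant.age,
            )
            continue
        label = f"{bin_[0]:g}-{bin_[1]:g}"
        placed.append((participant, intake, label))
    if not placed:
        raise ValidationError("no participants fall inside the configured age bins")

    keys = [PROTEIN_KEY, *ears.aa_requirements.keys()]
    age_labels = [f"{lo:g}-{hi:g}" for lo, hi in ears.age_bins] + [ALL_AGES]
    rows: list[dict] = []
    for sex in (TOTAL, "M", "F"):
        for age_label in age_labels:
            members = [
                (p, i)
                for p, i, label in placed
                if (sex == TOTAL or p.sex == sex)
                and (age_label == ALL_AGES or label == age_label)
            ]
            if not members:
                continue
            for key in keys:
                n_below = sum(1 for p, i in members if _is_below(p, i, key, ears))
                rows.append(
                    {
                        "sex": sex,
                        "age_group": age_label,
                        "requirement": key,
                        "n": len(members),
                        "n_below": n_below,
                        "percent": n_below / len(members) * 100.0,
                    }
                )
    return AdequacyReport(rows=tuple(rows))
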