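"""Readers/writers for the CSV schemas, YAML config and JSONL ledger.

All tables are UTF-8 CSV with a header row.  Empty amino acid cells map to
missing keys, never to zero.  An ``.xlsx`` reference table is accepted for
convenience (national composition tables ship as spreadsheets); everything
written by this package is plain text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .builder import (
    AminoAcidDatabase,
    DatabaseEntry,
    DEFAULT_VARIABLES,
    round_half_up,
)
from .datamodel import (
    AA_KEYS,
    EAA_KEYS,
    TAA_KEYS,
    AssignmentCategory,
    AssignmentRecord,
    ConfigError,
    ConversionFactorTable,
    EARTable,
    FoodItem,
    NutrientVector,
    ParticipantRecord,
    ReferenceFood,
    SimilarityMap,
    ValidationError,
    DEFAULT_PROTEIN_COEFFICIENT,
)
from .intake import IntakeResult

__all__ = [
    "RunConfig",
    "load_config",
    "write_config",
    "read_items",
    "write_items",
    "read_refs",
    "write_refs",
    "read_simmap",
    "write_simmap",
    "read_cohort",
    "write_cohort",
    "read_database",
    "write_database",
    "read_ledger",
    "write_ledger",
    "write_intakes",
    "read_intakes",
]

_ITEM_COLUMNS = [
    "item_id",
    "name",
    "preparation",
    "food_group",
    "similarity_key",
    "energy_kcal",
    "carb_g",
    "protein_g",
    "fat_g",
    "moisture_g",
]
_NUTRIENT_COLUMNS = ["energy_kcal", "carb_g", "protein_g", "fat_g", "moisture_g"]

# Illustrative adult EAR values (mg/kg/day); the national reference values
# are not shipped and must be supplied by the user for real analyses.
_EXAMPLE_AA_REQUIREMENTS = {
    "ILE": 20.0,
    "LEU": 39.0,
    "LYS": 30.0,
    "MET": 10.4,
    "PHE+TYR": 25.0,
    "THR": 15.0,
    "TRP": 4.0,
    "VAL": 26.0,
    "HIS": 10.0,
}


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration shared by all subcommands."""

    tolerance: float = 0.20
    absolute_zero_band: float = 0.5
    taa_keys: tuple[str, ...] = TAA_KEYS
    eaa_keys: tuple[str, ...] = EAA_KEYS
    coverage_variables: tuple[str, ...] = DEFAULT_VARIABLES
    nitrogen_factors: ConversionFactorTable = field(
        default_factory=ConversionFactorTable
    )
    ear_table: EARTable = field(
        default_factory=lambda: EARTable(aa_requirements=_EXAMPLE_AA_REQUIREMENTS)
    )
    strict: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be > 0")
        for key in (*self.taa_keys, *self.eaa_keys):
            if key not in AA_KEYS:
                raise ConfigError(f"unknown amino acid key in config: {key!r}")
        for var in self.coverage_variables:
            if var not in ("TAA", "EAA") and var not in AA_KEYS:
                raise ConfigError(f"unknown coverage variable: {var!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    try:
        factors_raw = dict(raw.get("nitrogen_factors", {}))
        default = factors_raw.pop("default", 6.25)
        factors = ConversionFactorTable(factors=factors_raw, default=default)
        ear_raw = raw.get("ear", {})
        ear = EARTable(
            protein_coefficient=float(
                ear_raw.get("protein_coefficient", DEFAULT_PROTEIN_COEFFICIENT)
            ),
            aa_requirements=ear_raw.get(
                "aa_requirements_mg_per_kg", _EXAMPLE_AA_REQUIREMENTS
            ),
            age_bins=tuple(
                tuple(b) for b in ear_raw.get("age_bins", EARTable().age_bins)
            ),
        )
        return RunConfig(
            tolerance=float(raw.get("tolerance", 0.20)),
            absolute_zero_band=float(raw.get("absolute_zero_band", 0.5)),
            taa_keys=tuple(raw.get("taa_keys", TAA_KEYS)),
            eaa_keys=tuple(raw.get("eaa_keys", EAA_KEYS)),
            coverage_variables=tuple(
                raw.get("coverage_variables", DEFAULT_VARIABLES)
            ),
            nitrogen_factors=factors,
            ear_table=ear,
            strict=raw.get("linkage_mode", "strict") == "strict",
        )
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    doc = {
        "tolerance": config.tolerance,
        "absolute_zero_band": config.absolute_zero_band,
        "taa_keys": list(config.taa_keys),
        "eaa_keys": list(config.eaa_keys),
        "coverage_variables": list(config.coverage_variables),
        "nitrogen_factors": {
            **config.nitrogen_factors.factors,
            "default": config.nitrogen_factors.default,
        },
        "ear": {
            "protein_coefficient": config.ear_table.protein_coefficient,
            "aa_requirements_mg_per_kg": dict(config.ear_table.aa_requirements),
            "age_bins": [list(b) for b in config.ear_table.age_bins],
        },
        "linkage_mode": "strict" if config.strict else "lenient",
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    read = pd.read_excel if str(path).endswith(".xlsx") else pd.read_csv
    return read(path, dtype=str, keep_default_na=False, na_values=[""])


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _float_cell(row, column: str, rownum: int, path) -> float:
    raw = row[column]
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{path}: row {rownum}, column {column}: malformed numeric {raw!r}"
        ) from None
    if math.isnan(value):
        raise ValidationError(f"{path}: row {rownum}, column {column}: missing value")
    return value


def _nutrients_of(row, rownum: int, path) -> NutrientVector:
    values = [_float_cell(row, c, rownum, path) for c in _NUTRIENT_COLUMNS]
    try:
        return NutrientVector(*values)
    except ValidationError as exc:
        raise ValidationError(f"{path}: row {rownum}: {exc}") from exc


def read_items(path: str | Path) -> list[FoodItem]:
    df = _read_csv(path)
    _require_columns(df, _ITEM_COLUMNS, path)
    items = []
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):
        items.append(
            FoodItem(
                id=row["item_id"],
                name=row["name"],
                preparation=row["preparation"],
                food_group=row["food_group"],
                similarity_key=row["similarity_key"],
                nutrients=_nutrients_of(row, rownum, path),
            )
        )
    ids = [i.id for i in items]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate item ids {sorted(dupes)}")
    return items


def write_items(items: Sequence[FoodItem], path: str | Path) -> None:
    rows = [
        {
            "item_id": i.id,
            "name": i.name,
            "preparation": i.preparation,
            "food_group": i.food_group,
            "similarity_key": i.similarity_key,
            "energy_kcal": i.nutrients.energy,
            "carb_g": i.nutrients.carbohydrate,
            "protein_g": i.nutrients.protein,
            "fat_g": i.nutrients.fat,
            "moisture_g": i.nutrients.moisture,
        }
        for i in items
    ]
    pd.DataFrame(rows, columns=_ITEM_COLUMNS).to_csv(path, index=False)


def read_refs(path: str | Path) -> list[ReferenceFood]:
    df = _read_csv(path)
    _require_columns(df, _ITEM_COLUMNS + ["source", "is_analytical"], path)
    refs = []
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):
        profile: Optional[dict[str, float]] = None
        values = {}
        for key in AA_KEYS:
            if key in df.columns and not pd.isna(row[key]) and row[key] != "":
                values[key] = _float_cell(row, key, rownum, path)
        if values:
            profile = values
        try:
            refs.append(
                ReferenceFood(
                    id=row["item_id"],
                    name=row["name"],
                    preparation=row["preparation"],
                    food_group=row["food_group"],
                    similarity_key=row["similarity_key"],
                    nutrients=_nutrients_of(row, rownum, path),
                    profile=profile,
                    source=row["source"],
                    is_analytical=str(row["is_analytical"]).strip().lower()
                    in ("1", "true", "yes"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {rownum}: {exc}") from exc
    return refs


def write_refs(refs: Sequence[ReferenceFood], path: str | Path) -> None:
    rows = []
    for r in refs:
        row = {
            "item_id": r.id,
            "name": r.name,
            "preparation": r.preparation,
            "food_group": r.food_group,
            "similarity_key": r.similarity_key,
            "energy_kcal": r.nutrients.energy,
            "carb_g": r.nutrients.carbohydrate,
            "protein_g": r.nutrients.protein,
            "fat_g": r.nutrients.fat,
            "moisture_g": r.nutrients.moisture,
            "source": r.source,
            "is_analytical": "true" if r.is_analytical else "false",
        }
        for key in AA_KEYS:
            row[key] = "" if r.profile is None or key not in r.profile else r.profile[key]
        rows.append(row)
    columns = _ITEM_COLUMNS + ["source", "is_analytical"] + list(AA_KEYS)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_simmap(path: str | Path) -> SimilarityMap:
    df = _read_csv(path)
    _require_columns(df, ["item_id", "ref_id", "rank", "rationale"], path)
    entries: dict[str, list[tuple[int, str, str]]] = {}
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):
        rank = int(_float_cell(row, "rank", rownum, path))
        entries.setdefault(row["item_id"], []).append(
            (rank, row["ref_id"], row["rationale"])
        )
    by_item: dict[str, list[tuple[str, str]]] = {}
    for item_id, cands in entries.items():
        ranks = [r for r, _, _ in cands]
        if len(set(ranks)) != len(ranks):
            raise ValidationError(f"{path}: tied ranks for item {item_id}")
        by_item[item_id] = [(rid, rat) for _, rid, rat in sorted(cands)]
    return SimilarityMap(by_item)


def write_simmap(simmap: SimilarityMap, path: str | Path) -> None:
    rows = []
    for item_id, cands in simmap.candidates_by_item.items():
        for rank, (ref_id, rationale) in enumerate(cands, start=1):
            rows.append(
                {
                    "item_id": item_id,
                    "ref_id": ref_id,
                    "rank": rank,
                    "rationale": rationale,
                }
            )
    pd.DataFrame(rows, columns=["item_id", "ref_id", "rank", "rationale"]).to_csv(
        path, index=False
    )


def read_cohort(
    participants_path: str | Path, responses_path: str | Path
) -> list[ParticipantRecord]:
    pdf = _read_csv(participants_path)
    _require_columns(pdf, ["participant_id", "sex", "age", "weight_kg"], participants_path)
    rdf = _read_csv(responses_path)
    _require_columns(
        rdf, ["participant_id", "item_id", "freq_per_day", "portion_g"], responses_path
    )
    responses: dict[str, dict[str, tuple[float, float]]] = {}
    for rownum, (_, row) in enumerate(rdf.iterrows(), start=2):
        responses.setdefault(row["participant_id"], {})[row["item_id"]] = (
            _float_cell(row, "freq_per_day", rownum, responses_path),
            _float_cell(row, "portion_g", rownum, responses_path),
        )
    cohort = []
    for rownum, (_, row) in enumerate(pdf.iterrows(), start=2):
        pid = row["participant_id"]
        cohort.append(
            ParticipantRecord(
                id=pid,
                sex=row["sex"],
                age=_float_cell(row, "age", rownum, participants_path),
                body_weight=_float_cell(row, "weight_kg", rownum, participants_path),
                responses=responses.get(pid, {}),
            )
        )
    return cohort


def write_cohort(
    cohort: Sequence[ParticipantRecord],
    participants_path: str | Path,
    responses_path: str | Path,
) -> None:
    prows = [
        {
            "participant_id": p.id,
            "sex": p.sex,
            "age": p.age,
            "weight_kg": p.body_weight,
        }
        for p in cohort
    ]
    pd.DataFrame(prows, columns=["participant_id", "sex", "age", "weight_kg"]).to_csv(
        participants_path, index=False
    )
    rrows = []
    for p in cohort:
        for item_id, (freq, portion) in p.responses.items():
            rrows.append(
                {
                    "participant_id": p.id,
                    "item_id": item_id,
                    "freq_per_day": freq,
                    "portion_g": portion,
                }
            )
    pd.DataFrame(
        rrows, columns=["participant_id", "item_id", "freq_per_day", "portion_g"]
    ).to_csv(responses_path, index=False)


_DB_COLUMNS = ["item_id", *AA_KEYS, "taa_mg", "eaa_mg", "protein_g", "category", "source_ref"]


def write_database(
    db: AminoAcidDatabase,
    path: str | Path,
    protein_db: Optional[Mapping[str, float]] = None,
) -> None:
    """Serialize the database; ``protein_g`` carries the FFQ recipe protein
    so the intake stage can run from this one file."""
    rows = []
    for item_id, entry in db.entries.items():
        row: dict = {"item_id": item_id}
        for key in AA_KEYS:
            row[key] = (
                entry.profile[key]
                if entry.profile is not None and key in entry.profile
                else ""
            )
        row["taa_mg"] = entry.taa if entry.taa is not None else ""
        row["eaa_mg"] = entry.eaa if entry.eaa is not None else ""
        row["protein_g"] = protein_db.get(item_id, "") if protein_db else ""
        row["category"] = entry.record.category.value
        row["source_ref"] = entry.record.source_ref or ""
        rows.append(row)
    pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(path, index=False)


def read_database(path: str | Path) -> tuple[AminoAcidDatabase, dict[str, float]]:
    """Load a serialized database.

    Returns the database and the item -> protein g/100 g mapping (empty
    values are omitted).  Decision traces are not serialized in the CSV;
    loaded records carry a single synthetic ``loaded`` trace node.
    """
    df = _read_csv(path)
    _require_columns(df, ["item_id", "taa_mg", "eaa_mg", "category"], path)
    entries: dict[str, DatabaseEntry] = {}
    protein_db: dict[str, float] = {}
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):
        item_id = row["item_id"]
        profile: Optional[dict[str, float]] = None
        values = {}
        for key in AA_KEYS:
            if key in df.columns and not pd.isna(row[key]) and row[key] != "":
                values[key] = _float_cell(row, key, rownum, path)
        if values:
            profile = values
        category = AssignmentCategory(row["category"])
        source_ref = row.get("source_ref", "") or None
        record = AssignmentRecord(
            item_id=item_id,
            category=category,
            profile=profile,
            source_ref=source_ref,
            trace=(("loaded", True),),
        )
        taa = None if pd.isna(row["taa_mg"]) or row["taa_mg"] == "" else float(row["taa_mg"])
        eaa = None if pd.isna(row["eaa_mg"]) or row["eaa_mg"] == "" else float(row["eaa_mg"])
        entries[item_id] = DatabaseEntry(profile=profile, taa=taa, eaa=eaa, record=record)
        if "protein_g" in df.columns and not pd.isna(row["protein_g"]) and row["protein_g"] != "":
            protein_db[item_id] = float(row["protein_g"])
    return AminoAcidDatabase(entries=entries), protein_db


def write_ledger(ledger: Sequence[AssignmentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for record in ledger:
            fh.write(json.dumps(record.to_json_dict()) + "\n")


def read_ledger(path: str | Path) -> list[AssignmentRecord]:
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(AssignmentRecord.from_json_dict(json.loads(line)))
    return records


_INTAKE_COLUMNS = [
    "participant_id",
    "protein_g_day",
    *[f"{k}_mg_day" for k in AA_KEYS],
    "taa_mg_day",
    "eaa_mg_day",
    "taa_protein_percent",
]


def write_intakes(intakes: Sequence[IntakeResult], path: str | Path) -> None:
    rows = []
    for r in intakes:
        row = {"participant_id": r.participant_id, "protein_g_day": r.protein}
        for key in AA_KEYS:
            row[f"{key}_mg_day"] = r.per_aa.get(key, "")
        row["taa_mg_day"] = r.taa
        row["eaa_mg_day"] = r.eaa
        row["taa_protein_percent"] = (
            "" if r.taa_protein_percent is None else r.taa_protein_percent
        )
        rows.append(row)
    pd.DataFrame(rows, columns=_INTAKE_COLUMNS).to_csv(path, index=False)


def read_intakes(path: str | Path) -> list[IntakeResult]:
    df = _read_csv(path)
    _require_columns(df, ["participant_id", "protein_g_day"], path)
    out = []
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):
        per_aa = {}
        for key in AA_KEYS:
            col = f"{key}_mg_day"
            if col in df.columns and not pd.isna(row[col]) and row[col] != "":
                per_aa[key] = float(row[col])
        ratio_raw = row.get("taa_protein_percent", "")
        out.append(
            IntakeResult(
                participant_id=row["participant_id"],
                protein=_float_cell(row, "protein_g_day", rownum, path),
                per_aa=per_aa,
                taa=_float_cell(row, "taa_mg_day", rownum, path),
                eaa=_float_cell(row, "eaa_mg_day", rownum, path),
                taa_protein_percent=(
                    None if pd.isna(ratio_raw) or ratio_raw == "" else float(ratio_raw)
                ),
            )
        )
    return out
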