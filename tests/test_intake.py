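import numpy as np
import pytest

from aminokit import (
    AA_KEYS,
    EAA_KEYS,
    TAA_KEYS,
    AminoAcidDatabase,
    AssignmentCategory,
    AssignmentRecord,
    EARTable,
    FixtureSpec,
    ParticipantRecord,
    ValidationError,
    below_ear_proportions,
    build_database,
    generate_cohort,
    generate_reference_set,
    item_contribution,
    participant_intakes,
    protein_ear,
)
from aminokit.builder import DatabaseEntry, compute_eaa, compute_taa


def _db(profiles_by_item):
    entries = {}
    for item_id, profile in profiles_by_item.items():
        record = AssignmentRecord(
            item_id, AssignmentCategory.ANALYTICAL, profile, "R", (("name_match", True),)
        )
        entries[item_id] = DatabaseEntry(
            profile=profile,
            taa=compute_taa(profile),
            eaa=compute_eaa(profile),
            record=record,
        )
    return AminoAcidDatabase(entries=entries)


class TestItemContribution:
    def test_worked_example(self):
        out = item_contribution(2.0, 50.0, {"LYS": 300.0})
        assert out == {"LYS": pytest.approx(300.0)}

    def test_zero_frequency(self):
        out = item_contribution(0.0, 50.0, {"LYS": 300.0, "LEU": 10.0})
        assert all(v == 0.0 for v in out.values())

    def test_linearity_in_frequency(self):
        single = item_contribution(1.0, 80.0, {"LYS": 300.0, "TRP": 40.0})
        double = item_contribution(2.0, 80.0, {"LYS": 300.0, "TRP": 40.0})
        for key in single:
            assert double[key] == pytest.approx(2 * single[key])

    def test_missing_keys_contribute_nothing(self):
        out = item_contribution(1.0, 100.0, {"LYS": 300.0})
        assert "TRP" not in out

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            item_contribution(-1.0, 50.0, {})


class TestParticipantIntakes:
    def test_ratio_echoes_worked_example(self):
        # protein 60 g/day and TAA 52,020 mg/day -> 86.7%
        db = _db({"I1": {"GLU": 52020.0}})
        participant = ParticipantRecord(
            id="P1", sex="M", age=40, body_weight=70,
            responses={"I1": (1.0, 100.0)},
        )
        result = participant_intakes(participant, db, {"I1": 60.0})
        assert result.protein == pytest.approx(60.0)
        assert result.taa == pytest.approx(52020.0)
        assert result.taa_protein_percent == pytest.approx(86.7)

    def test_empty_responses(self):
        db = _db({"I1": {"LYS": 1.0}})
        participant = ParticipantRecord(id="P1", sex="F", age=40, body_weight=55)
        result = participant_intakes(participant, db, {"I1": 10.0})
        assert result.protein == 0.0
        assert result.taa == 0.0
        assert result.taa_protein_percent is None

    def test_unknown_item_strict_vs_lenient(self):
        db = _db({"I1": {"LYS": 1.0}})
        participant = ParticipantRecord(
            id="P1", sex="M", age=40, body_weight=70,
            responses={"NOPE": (1.0, 100.0)},
        )
        with pytest.raises(ValidationError):
            participant_intakes(participant, db, {"I1": 10.0}, strict=True)
        result = participant_intakes(participant, db, {"I1": 10.0}, strict=False)
        assert result.protein == 0.0

    def test_brute_force_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        profiles = {
            f"I{j}": {
                k: float(rng.uniform(0, 500))
                for k in AA_KEYS
                if rng.random() > 0.2
            }
            for j in range(8)
        }
        protein_db = {f"I{j}": float(rng.uniform(2, 30)) for j in range(8)}
        responses = {
            f"I{j}": (float(rng.uniform(0, 3)), float(rng.uniform(10, 200)))
            for j in range(8)
        }
        participant = ParticipantRecord(
            id="P1", sex="F", age=52, body_weight=58, responses=responses
        )
        result = participant_intakes(participant, _db(profiles), protein_db)
        # independent brute force over items x keys
        for key in AA_KEYS:
            expected = 0.0
            for item_id, (freq, portion) in responses.items():
                if key in profiles[item_id]:
                    expected += freq * portion / 100.0 * profiles[item_id][key]
            assert result.per_aa.get(key, 0.0) == pytest.approx(expected, rel=1e-12)
        expected_taa = sum(result.per_aa.get(k, 0.0) for k in TAA_KEYS)
        expected_eaa = sum(result.per_aa.get(k, 0.0) for k in EAA_KEYS)
        assert result.taa == pytest.approx(expected_taa)
        assert result.eaa == pytest.approx(expected_eaa)
        assert result.eaa <= result.taa


class TestProteinEAR:
    def test_sixty_kg(self):
        assert protein_ear(60.0) == pytest.approx(44.0)

    def test_ninety_kg(self):
        assert protein_ear(90.0) == pytest.approx(66.0)

    def test_linearity(self):
        assert protein_ear(120.0) == pytest.approx(2 * protein_ear(60.0))

    def test_nonpositive_weight(self):
        with pytest.raises(ValidationError):
            protein_ear(0.0)


def _cohort_pair(pid, sex, age, weight, protein, lys=0.0, phe=0.0, tyr=0.0):
    from aminokit.intake import IntakeResult

    participant = ParticipantRecord(id=pid, sex=sex, age=age, body_weight=weight)
    per_aa = {"LYS": lys, "PHE": phe, "TYR": tyr}
    intake = IntakeResult(
        participant_id=pid,
        protein=protein,
        per_aa=per_aa,
        taa=sum(per_aa.values()),
        eaa=sum(per_aa.values()),
        taa_protein_percent=None,
    )
    return participant, intake


class TestBelowEAR:
    def test_one_of_four_below(self):
        ears = EARTable(aa_requirements={})
        # EAR at 60 kg = 44 g/day; one participant below
        cohort = [
            _cohort_pair("P1", "M", 40, 60.0, protein=50.0),
            _cohort_pair("P2", "M", 40, 60.0, protein=45.0),
            _cohort_pair("P3", "F", 40, 60.0, protein=44.0),  # at EAR = adequate
            _cohort_pair("P4", "F", 40, 60.0, protein=30.0),
        ]
        report = below_ear_proportions(cohort, ears)
        assert report.percent("total", "30-49", "PROTEIN") == pytest.approx(25.0)
        assert report.percent("total", "all", "PROTEIN") == pytest.approx(25.0)
        assert report.percent("F", "30-49", "PROTEIN") == pytest.approx(50.0)

    def test_exactly_at_ear_is_adequate(self):
        ears = EARTable(aa_requirements={"LYS": 30.0})
        cohort = [_cohort_pair("P1", "M", 40, 60.0, protein=44.0, lys=1800.0)]
        report = below_ear_proportions(cohort, ears)
        assert report.percent("total", "all", "PROTEIN") == 0.0
        assert report.percent("total", "all", "LYS") == 0.0

    def test_combined_pair_requirement(self):
        ears = EARTable(aa_requirements={"PHE+TYR": 25.0})
        # requirement at 60 kg = 1500 mg/day; 800 + 800 = 1600 is adequate
        cohort = [
            _cohort_pair("P1", "M", 40, 60.0, protein=50.0, phe=800.0, tyr=800.0),
            _cohort_pair("P2", "F", 40, 60.0, protein=50.0, phe=700.0, tyr=700.0),
        ]
        report = below_ear_proportions(cohort, ears)
        assert report.percent("total", "all", "PHE+TYR") == pytest.approx(50.0)

    def test_all_above_gives_zero_everywhere(self):
        ears = EARTable(aa_requirements={"LYS": 30.0})
        cohort = [
            _cohort_pair(f"P{i}", "M", 35 + i, 60.0, protein=100.0, lys=9000.0)
            for i in range(5)
        ]
        report = below_ear_proportions(cohort, ears)
        for row in report.rows:
            assert row["percent"] == 0.0

    def test_age_outside_bins(self):
        ears = EARTable(aa_requirements={})
        cohort = [_cohort_pair("P1", "M", 80, 60.0, protein=50.0)]
        with pytest.raises(ValidationError):
            below_ear_proportions(cohort, ears, strict=True)
        cohort.append(_cohort_pair("P2", "M", 40, 60.0, protein=50.0))
        report = below_ear_proportions(cohort, ears, strict=False)
        assert report.rows[0]["n"] == 1  # the 80-year-old is excluded

    def test_strata_partition_cohort(self):
        ears = EARTable(aa_requirements={})
        rng = np.random.default_rng(0)
        cohort = [
            _cohort_pair(
                f"P{i}",
                "M" if rng.random() < 0.5 else "F",
                float(rng.integers(30, 75)),
                60.0,
                protein=float(rng.uniform(20, 80)),
            )
            for i in range(60)
        ]
        report = below_ear_proportions(cohort, ears)
        bin_rows = [
            r
            for r in report.rows
            if r["sex"] == "total" and r["age_group"] != "all"
            and r["requirement"] == "PROTEIN"
        ]
        assert sum(r["n"] for r in bin_rows) == 60
        total_below = sum(r["n_below"] for r in bin_rows)
        assert total_below == report.percent("total", "all", "PROTEIN") / 100.0 * 60

    def test_monotone_in_requirement(self):
        rng = np.random.default_rng(1)
        cohort = [
            _cohort_pair(
                f"P{i}", "F", 45, 60.0, protein=50.0, lys=float(rng.uniform(500, 3000))
            )
            for i in range(40)
        ]
        low = below_ear_proportions(cohort, EARTable(aa_requirements={"LYS": 20.0}))
        high = below_ear_proportions(cohort, EARTable(aa_requirements={"LYS": 40.0}))
        assert high.percent("total", "all", "LYS") >= low.percent("total", "all", "LYS")


class TestEndToEndOnSyntheticCohort:
    def test_taa_protein_ratio_in_band(self, small_build):
        fx, db, _ = small_build
        spec = FixtureSpec(seed=7, n_items=60, cohort_size=40)
        cohort = generate_cohort(spec, db, fx.protein_db)
        for p in cohort:
            result = participant_intakes(p, db, fx.protein_db)
            assert result.taa_protein_percent is not None
            # generator enforces TAA <= 0.95 x protein per 100 g
            assert result.taa_protein_percent <= 95.0 + 1e-9
            assert result.eaa <= result.taa

    def test_additivity_over_cohort(self, small_build):
        fx, db, _ = small_build
        spec = FixtureSpec(seed=7, n_items=60, cohort_size=30)
        cohort = generate_cohort(spec, db, fx.protein_db)
        results = [participant_intakes(p, db, fx.protein_db) for p in cohort]
        total_lys = sum(r.per_aa.get("LYS", 0.0) for r in results)
        brute = 0.0
        for p in cohort:
            for item_id, (freq, portion) in p.responses.items():
                profile = db.entries[item_id].profile
                if profile and "LYS" in profile:
                    brute += freq * portion / 100.0 * profile["LYS"]
        assert total_lys == pytest.approx(brute, rel=1e-9)
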