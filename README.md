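# aminokit

Rule-based construction of food amino acid composition databases for
FFQ-style (food frequency questionnaire) dietary instruments, and a
downstream pipeline that estimates per-participant amino acid intakes and
the prevalence of intakes below the Estimated Average Requirement (EAR).

## What it does

1. **Matching engine** — a sequential decision algorithm assigns each food
   item an amino acid profile and a provenance category:
   - `ANALYTICAL`: exact name + preparation-form match to a reference food
     with analytically measured values, all five macronutrients (energy,
     carbohydrate, protein, fat, moisture) within a ±20% tolerance —
     profile copied verbatim;
   - `SUBSTITUTED`: a similar food's analytical profile copied verbatim
     when macronutrients are within tolerance;
   - `CALCULATED`: a similar food's analytical profile rescaled by the
     nitrogen ratio of target to similar food, where nitrogen = protein /
     food-group conversion factor;
   - `DEFERRED`: no analytical data available; resolvable in later passes
     with additional reference tables.
   Every decision node visited is recorded in a per-item trace (JSONL
   ledger).
2. **Database builder** — materializes total (TAA, 18 keys, taurine
   excluded) and essential (EAA, 10 keys) amino acid sums with a
   skip-missing rule, and produces provenance-composition and coverage
   reports (per-variable and overall populated-cell percentage over a
   21-variable set).
3. **Intake pipeline** — links cohort FFQ responses
   (frequency × portion/100 × content) to the database, computes protein,
   per-amino-acid, TAA and EAA intakes, the TAA-to-protein ratio, and
   below-EAR proportions stratified by sex and age group (protein EAR =
   (0.66/0.9) g/kg/day × body weight; amino acid EARs in mg/kg/day from
   config — the shipped values are **illustrative placeholders**, as are
   the default nitrogen-to-protein factors).
4. **Synthetic fixtures** — a deterministic generator that embeds
   ground-truth categories, exact per-variable missingness, and a known
   below-EAR fraction, so the whole pipeline is testable without
   access-restricted cohort data.

Missing amino acid values are represented as absent keys (empty CSV
cells), never as zero. Report percentages use half-up rounding to one
decimal, applied only at serialization.

## CLI

```sh
aminokit gen-fixtures --seed 1 --n-items 100 --cohort-size 50 --outdir fixtures/
aminokit build-db --items fixtures/items.csv --refs fixtures/refs.csv \
    --simmap fixtures/simmap.csv --config fixtures/config.yaml \
    --out db.csv --ledger ledger.jsonl
aminokit coverage-report --db db.csv --config fixtures/config.yaml --out coverage.csv
aminokit source-report --ledger ledger.jsonl --refs fixtures/refs.csv --out sources.csv
aminokit estimate-intake --db db.csv --cohort fixtures/cohort.csv \
    --responses fixtures/responses.csv --config fixtures/config.yaml --out intakes.csv
aminokit adequacy-report --intakes intakes.csv --cohort fixtures/cohort.csv \
    --responses fixtures/responses.csv --config fixtures/config.yaml --out adequacy.csv
aminokit validate --items fixtures/items.csv --refs fixtures/refs.csv
```

Exit codes: 0 success, 1 input validation error, 2 configuration/usage
error. `build-db` accepts `--refs` multiple times; later tables form
additional passes that re-classify only deferred items.

Input schemas (CSV, header row): items
(`item_id,name,preparation,food_group,similarity_key,energy_kcal,carb_g,protein_g,fat_g,moisture_g`),
references (same plus one column per amino acid key `ILE…TAU`, `source`,
`is_analytical`; `.xlsx` also accepted), similarity map
(`item_id,ref_id,rank,rationale`), cohort (`participant_id,sex,age,weight_kg`)
with long-format responses (`participant_id,item_id,freq_per_day,portion_g`).

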