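import pytest

from aminokit import (
    ConversionFactorTable,
    FixtureSpec,
    FoodItem,
    NutrientVector,
    ReferenceFood,
    SimilarityMap,
    build_database,
    generate_reference_set,
)


def make_nutrients(scale: float = 1.0) -> NutrientVector:
    return NutrientVector(
        energy=200.0 * scale,
        carbohydrate=30.0 * scale,
        protein=10.0 * scale,
        fat=5.0 * scale,
        moisture=50.0 * scale,
    )


def make_item(item_id: str = "F1", name: str = "boiled rice", prep: str = "boiled",
              nutrients: NutrientVector | None = None) -> FoodItem:
    return FoodItem(
        id=item_id,
        name=name,
        preparation=prep,
        food_group="cereal",
        similarity_key="rice",
        nutrients=nutrients or make_nutrients(),
    )


def make_ref(ref_id: str = "R1", name: str = "boiled rice", prep: str = "boiled",
             nutrients: NutrientVector | None = None,
             profile: dict | None = None, analytical: bool = True,
             source: str = "table A") -> ReferenceFood:
    if analytical and profile is None:
        profile = {"LYS": 500.0, "LEU": 800.0, "TRP": 120.0}
    return ReferenceFood(
        id=ref_id,
        name=name,
        preparation=prep,
        food_group="cereal",
        similarity_key="rice",
        nutrients=nutrients or make_nutrients(),
        profile=profile,
        source=source,
        is_analytical=analytical,
    )


@pytest.fixture
def factors() -> ConversionFactorTable:
    return ConversionFactorTable(factors={"cereal": 5.95}, default=6.25)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_reference_set(FixtureSpec(seed=7, n_items=60, cohort_size=0))


@pytest.fixture(scope="session")
def small_build(small_fixture):
    fx = small_fixture
    db, ledger = build_database(fx.items, fx.refs, fx.simmap, fx.factors)
    return fx, db, ledger
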