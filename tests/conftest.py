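import numpy as np
import pandas as pd
import pytest

from nutrired.fnn import FoodNutrientNetwork, build_fnn
from nutrired.io_units import DietRecordSet, FoodCompositionTable
from nutrired.synthetic_data import SyntheticSpec, synth_cohort, synth_fnn


@pytest.fixture
def tiny_table() -> FoodCompositionTable:
    """3 foods x 2 nutrients, all pairs present."""
    rows = []
    for i, food in enumerate(["apple", "bread", "cheese"]):
        for a, nutr in enumerate(["carb", "fat"]):
            rows.append((food, "groupA", nutr, 0.1 * (i + 1) + 0.01 * a))
    return FoodCompositionTable(
        pd.DataFrame(rows, columns=["food_id", "food_group", "nutrient_id", "amount"])
    )


@pytest.fixture
def tiny_net(tiny_table) -> FoodNutrientNetwork:
    return build_fnn(tiny_table)


@pytest.fixture
def nested_net() -> FoodNutrientNetwork:
    """4 foods with nested nutrient sets over 4 nutrients."""
    foods = ["f1", "f2", "f3", "f4"]
    nutrients = ["n1", "n2", "n3", "n4"]
    G = np.array(
        [
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
        ]
    )
    return FoodNutrientNetwork(
        foods=foods, nutrients=nutrients, G=G,
        food_groups={f: "g1" for f in foods},
    )


@pytest.fixture
def small_records() -> DietRecordSet:
    """Two subjects x two timepoints over the nested_net foods."""
    rows = [
        ("s1", 1, "f1", 30.0), ("s1", 1, "f2", 10.0),
        ("s1", 2, "f1", 25.0), ("s1", 2, "f3", 25.0),
        ("s2", 1, "f2", 40.0), ("s2", 1, "f4", 10.0),
        ("s2", 2, "f3", 20.0), ("s2", 2, "f4", 20.0),
    ]
    return DietRecordSet(
        pd.DataFrame(rows, columns=["subject_id", "timepoint", "food_id", "grams"])
    )


@pytest.fixture(scope="session")
def desk_spec() -> SyntheticSpec:
    """Small synthetic study for fast end-to-end tests."""
    return SyntheticSpec(
        n_foods=60, n_nutrients=20, nestedness=0.9,
        n_subjects=10, n_timepoints=3, personalization=0.8,
        richness_mean=8.0, seed=42,
    )


@pytest.fixture(scope="session")
def desk_net(desk_spec):
    return build_fnn(synth_fnn(desk_spec))


@pytest.fixture(scope="session")
def desk_records(desk_spec, desk_net):
    return synth_cohort(desk_spec, desk_net)
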