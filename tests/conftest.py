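import math

import pytest

from agemarkers.data_model import (
    MergedRecord,
    PhenotypeRecord,
    Sex,
    StrainLifespan,
)


@pytest.fixture
def toy_records():
    """Two strains x one sex, two ages, two features (one value missing)."""
    rows = [
        ("A", "a1", 6.0, {"Mg": 2.1, "Fe": 140.0}),
        ("A", "a1", 12.0, {"Mg": 2.0, "Fe": 120.0}),
        ("B", "b1", 6.0, {"Mg": math.nan, "Fe": 150.0}),
        ("B", "b1", 12.0, {"Mg": 1.8, "Fe": 135.0}),
    ]
    return [
        PhenotypeRecord(animal_id=a, strain=s, sex=Sex.female, age_months=age,
                        values=v)
        for s, a, age, v in rows
    ]


@pytest.fixture
def toy_lifespans():
    return [
        StrainLifespan(strain="A", sex=Sex.female, life_expectancy=30.0),
        StrainLifespan(strain="B", sex=Sex.female, life_expectancy=22.0),
    ]


def make_merged(values, lifespans, strains=None, sex=Sex.female, age=6.0,
                feature="x"):
    """Build merged records from parallel value/lifespan vectors."""
    out = []
    for i, (v, le) in enumerate(zip(values, lifespans)):
        strain = strains[i] if strains else f"S{i:03d}"
        out.append(
            MergedRecord(animal_id=f"{strain}-{i}", strain=strain, sex=sex,
                         age_months=age, values={feature: v},
                         life_expectancy=le)
        )
    return out


@pytest.fixture
def merged_factory():
    return make_merged
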