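import numpy as np
import pandas as pd
import pytest

from mobrf import (
    ForestControl,
    MobControl,
    build_forest,
    fixture_spec,
    generate_subgroup_data,
    parse_formula,
)

GAUSSIAN_PARTITION_VARS = [f"z{i:02d}" for i in range(1, 11)]


@pytest.fixture(scope="session")
def gaussian_data():
    """Two-subgroup gaussian fixture: slopes +-1 split on z01, noise SD 0.5."""
    data, truth = generate_subgroup_data(fixture_spec("two_subgroup_gaussian", seed=42))
    return data, truth


@pytest.fixture(scope="session")
def gaussian_forest(gaussian_data):
    data, _ = gaussian_data
    control = ForestControl(ntree=12, mtry=10, seed=3)
    out = build_forest(data, parse_formula("y ~ x"), GAUSSIAN_PARTITION_VARS, control)
    return data, out


@pytest.fixture(scope="session")
def binomial_forest():
    """Small logistic forest on a binomial two-subgroup dataset."""
    from mobrf.fixtures import (
        PartitionVariableSpec,
        PredictorSpec,
        SubgroupDataSpec,
        SubgroupRule,
    )

    spec = SubgroupDataSpec(
        n=400,
        family="binomial",
        predictors=(PredictorSpec("x"),),
        n_treatment_groups=0,
        partition_variables=tuple(PartitionVariableSpec(f"z{i:02d}") for i in range(1, 5)),
        subgroup_rules=(
            SubgroupRule("a", lambda d: np.asarray(d["z01"]) <= 0, (0.0, 2.0)),
            SubgroupRule("b", lambda d: np.asarray(d["z01"]) > 0, (0.0, -2.0)),
        ),
        informative_variables=("z01",),
        seed=5,
    )
    data, _ = generate_subgroup_data(spec)
    control = ForestControl(ntree=8, mtry=4, seed=9, mob=MobControl(minsplit=40))
    out = build_forest(
        data, parse_formula("y ~ x", "binomial"), [f"z{i:02d}" for i in range(1, 5)], control
    )
    return data, out
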