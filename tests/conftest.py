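import numpy as np
import pandas as pd
import pytest

from chondrotime import (
    PlantedBlock,
    SimulationConfig,
    TimeCourseProfileSelector,
    generate_dataset,
)


@pytest.fixture(scope="session")
def planted_config():
    """Study-like mix: sustained variation dominates transient variation."""
    return SimulationConfig(
        n_probes=4000,
        planted=(
            PlantedBlock("sustained_decrease", 120, 2.5),
            PlantedBlock("sustained_increase", 80, 2.5),
            PlantedBlock("transient_peak", 30, 2.5),
            PlantedBlock("transient_dip", 12, 2.5),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return generate_dataset(planted_config)


@pytest.fixture(scope="session")
def fitted_selector(planted_dataset):
    em, design, _, _ = planted_dataset
    return TimeCourseProfileSelector().fit(em, design)


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(42)
    samples = [f"wk{t}_r{r}" for t in range(6) for r in (1, 2)]
    return pd.DataFrame(
        rng.normal(8.0, 1.0, size=(50, 12)),
        index=[f"P{i:03d}" for i in range(50)],
        columns=samples,
    )


def recovery_rate(selection_table, truth, profile_class, subgroup):
    """Fraction of planted probes of one class assigned their subgroup."""
    joined = selection_table.join(truth)
    block = joined[joined["profile_class"] == profile_class]
    return float((block["subgroup"] == subgroup).fillna(False).mean())
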