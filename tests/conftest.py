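import pandas as pd
import pytest

from cernet.io_formats import CountMatrix
from cernet.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def strong_scenario():
    """Well-powered scenario with planted ceRNA triplets: 20 replicates per
    group, tight dispersion, strong miRNA->target coupling."""
    config = ScenarioConfig(
        n_replicates_per_group=20,
        n_mirna=40,
        n_mrna=130,
        n_lncrna=120,
        n_circrna=100,
        n_planted_triplets=30,
        n_planted_de_per_class=5,
        nb_dispersion=0.05,
        coupling_strength=2.0,
        seed=7,
    )
    return generate_scenario(config)


@pytest.fixture(scope="session")
def default_scenario():
    """Scenario at the default 3-vs-3 design."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture
def toy_matrix():
    """2 features x 4 samples, two conditions."""
    counts = pd.DataFrame(
        [[1, 3, 5, 7], [9, 7, 5, 3]],
        index=["f1", "f2"],
        columns=["A1", "A2", "B1", "B2"],
    )
    condition_of = {"A1": "groupA", "A2": "groupA", "B1": "groupB", "B2": "groupB"}
    return CountMatrix(counts, "mRNA", condition_of)
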