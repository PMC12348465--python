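import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from calluscope import simulate
from calluscope.motifs import default_catalog

SEED = 20250

# Cohort count columns: construct -> (genotyped, edited, homozygous, indel lines),
# with the three published per-construct rates they imply.
COHORT_COUNTS = {
    "35S-CBE": (28, 4, 2, 2),
    "P_Ah-H0FE8D_-CBE": (28, 6, 2, 3),
    "P_Ah-WT3AEF_-CBE": (28, 4, 4, 2),
    "P_Ah-I20Q6X_-CBE": (28, 2, 0, 2),
    "P_Ah-ELJ55T_-CBE": (24, 5, 3, 3),
    "P_Ah-N9CMH4_-CBE": (28, 8, 3, 3),
}
COHORT_RATES = {
    "35S-CBE": (14.3, 7.1, 7.1),
    "P_Ah-H0FE8D_-CBE": (21.4, 7.1, 10.7),
    "P_Ah-WT3AEF_-CBE": (14.3, 14.3, 7.1),
    "P_Ah-I20Q6X_-CBE": (7.1, 0.0, 7.1),
    "P_Ah-ELJ55T_-CBE": (20.8, 12.5, 12.5),
    "P_Ah-N9CMH4_-CBE": (28.6, 10.7, 10.7),
}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def demo_targets():
    return simulate.make_demo_targets(seed=SEED)


@pytest.fixture(scope="session")
def synthetic_atlas():
    return simulate.simulate_expression_atlas(
        n_genes=2000, n_specific=20, effect_fold=100.0, seed=SEED
    )
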