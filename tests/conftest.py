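import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species_tree():
    from rgene_evoscan.synthetic_data import fragaria_species_tree

    return fragaria_species_tree()


@pytest.fixture()
def quartet_tree():
    return dendropy.Tree.get(
        data="((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);",
        schema="newick",
        preserve_underscores=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
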