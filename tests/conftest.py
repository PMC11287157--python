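import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def species_tree_20():
    from amtoolkit import simulate_species_tree

    return simulate_species_tree(20, seed=101)


@pytest.fixture(scope="session")
def index_20(species_tree_20):
    from amtoolkit.phylo import SpeciesTreeIndex

    return SpeciesTreeIndex(species_tree_20)


@pytest.fixture(scope="session")
def panel():
    from amtoolkit.synthetic_panel import build_panel

    return build_panel()


@pytest.fixture(scope="session")
def panel_summary(panel):
    from amtoolkit.synthetic_panel import summarize_panel

    return summarize_panel(panel)
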