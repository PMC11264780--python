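import numpy as np
import pytest
from skbio import TreeNode

import ecoassembly as ea
from ecoassembly.core_io import CountTable, Phylogeny


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-niche synthetic study used by several unit tests."""
    scenario = ea.SyntheticScenario(
        n_taxa=80,
        n_farms=6,
        niches=("bulk_soil", "root"),
        samples_per_group=5,
        richness_target=16,
        depth_mean=800,
        seed=5,
    )
    return ea.generate_dataset(scenario)


@pytest.fixture()
def three_taxon_tree():
    return Phylogeny(TreeNode.read(["((A:0.1,B:0.1):0.2,C:0.3);"]))


@pytest.fixture()
def tiny_table():
    return CountTable(
        ["A", "B", "C"],
        ["s1", "s2"],
        np.array([[10, 0], [0, 5], [0, 5]]),
    )
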