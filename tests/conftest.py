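"""Shared fixtures: small hand-built data and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from phylogeokit import synthgen
from phylogeokit.seqdata import Alignment
from phylogeokit.synthgen import (
    BasinTreeNode,
    SimulationConfig,
    SiteSpec,
    VicarianceScenario,
)


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment(
        ["s1", "s2", "s3", "s4"],
        [
            "ACGTACGTAC",
            "ACGTACGTAC",
            "AGGTACGTAT",
            "ACGTTCGTAC",
        ],
    )


@pytest.fixture(scope="session")
def two_basin_dataset() -> synthgen.SyntheticDataset:
    """Two basins split 2 Myr ago, ridge barrier between them."""
    scenario = synthgen.two_basin_scenario(split_myr=2.0, n_per_basin=8)
    config = SimulationConfig(seed=11)
    return synthgen.generate_dataset(
        scenario, config, dem_kwargs=dict(nrows=40, ncols=40, cellsize_m=20_000.0)
    )


@pytest.fixture(scope="session")
def seven_basin_dataset() -> synthgen.SyntheticDataset:
    """The default seven-basin scenario at reduced sampling (4 per site)."""
    scenario = synthgen.default_scenario(samples_per_site=4)
    config = SimulationConfig(seed=7)
    return synthgen.generate_dataset(scenario, config)


@pytest.fixture(scope="session")
def coalescent_chronogram():
    """A 50-tip ultrametric tree for diffusion-model tests."""
    from phylogeokit import dispersal as dp

    scenario = synthgen.two_basin_scenario(2.0, n_per_basin=25, with_ridge=False)
    tree = synthgen.simulate_genealogy(scenario, SimulationConfig(seed=3))
    depth = 0.0
    node = next(tree.leaf_node_iter())
    while node.parent_node is not None:
        depth += node.edge.length
        node = node.parent_node
    return dp.Chronogram(tree=tree, root_age=depth)


@pytest.fixture
def one_basin_scenario() -> VicarianceScenario:
    """A single panmictic population (neutral-coalescent null)."""
    return VicarianceScenario(
        basins=["A"],
        basin_tree=BasinTreeNode("A"),
        sites={"A": [SiteSpec("a1", -2.0, 135.0, 20)]},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
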