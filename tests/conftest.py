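"""Shared fixtures: hand-built trees and small simulated worlds."""

from __future__ import annotations

import numpy as np
import pytest

from arglai.arg_io import (
    MarginalTree,
    Population,
    SampleMeta,
    marginal_tree_from_newick,
)
from arglai.demography import (
    DemographyConfig,
    PopulationSpec,
    SamplingEvent,
    Split,
    default_config,
    simulate,
    true_local_ancestry,
    two_population_toy,
)
from arglai.subgraph import TokenVocabulary


@pytest.fixture(scope="session")
def vocab():
    return TokenVocabulary.default()


#: Six leaves (a..f) with printed branch lengths; internal node times are
#: fixed by the newick depths (deepest leaf at time 0).
SIX_LEAF_NEWICK = (
    "(((a:10,b:12):30,(c:25,d:40):18):60,(e:35,f:22):55);"
)


@pytest.fixture(scope="session")
def six_leaf_tree():
    return marginal_tree_from_newick(SIX_LEAF_NEWICK, span=100.0)


@pytest.fixture(scope="session")
def toy_world():
    """Small easy two-ancestry world with exact truth labels."""
    config = two_population_toy(sequence_length=1e6)
    handle, _ = simulate(config, seed=101, mutations=False)
    truth = true_local_ancestry(handle, config)
    return config, handle, truth


@pytest.fixture(scope="session")
def four_way_world():
    """Scaled-down four-way admixture world (all eight sample classes)."""
    config = default_config()
    config.sequence_length = 5e5
    config.sampling = [
        SamplingEvent("ANA", "ANA", 280.0, 8),
        SamplingEvent("WHG", "WHG", 300.0, 8),
        SamplingEvent("EHG", "EHG", 300.0, 8),
        SamplingEvent("CHG", "CHG", 320.0, 6),
        SamplingEvent("NEO", "NEO", 180.0, 8),
        SamplingEvent("YAM", "YAM", 160.0, 4),
        SamplingEvent("EUR", "POSTNEO", 50.0, 6),
        SamplingEvent("EUR", "PRESENT", 0.0, 6),
    ]
    handle, _ = simulate(config, seed=202, mutations=False)
    truth = true_local_ancestry(handle, config)
    return config, handle, truth


def random_marginal_trees(n_trees: int, seed: int):
    """Independent single-population trees for topology property tests."""
    config = DemographyConfig(
        populations=[PopulationSpec("A", 500.0)],
        splits=[], pulses=[],
        sampling=[SamplingEvent("A", "WHG", 0.0, 10)],
        sequence_length=1e5, ploidy=2)
    out = []
    for i in range(n_trees):
        handle, _ = simulate(config, seed=seed + i, mutations=False)
        out.append(next(handle.trees()))
    return out
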