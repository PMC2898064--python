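"""Shared fixtures: the default synthetic world and derived artifacts.

Session-scoped so the world is generated once for the whole run.
"""

import networkx as nx
import pytest

from finet.network import build_network, largest_component
from finet.synthetic import (
    WorldSpec,
    gen_feature_sources,
    gen_pathway_world,
)
from finet.workflow import run_classifier_study


@pytest.fixture(scope="session")
def world():
    return gen_pathway_world(WorldSpec(seed=1))


@pytest.fixture(scope="session")
def sources(world):
    return gen_feature_sources(world)


@pytest.fixture(scope="session")
def study(world, sources):
    return run_classifier_study(world, sources, ratio=10, seed=1)


@pytest.fixture(scope="session")
def pathway_net(world):
    return build_network(world.fis)


@pytest.fixture(scope="session")
def merged_net(study):
    return study.merged


@pytest.fixture()
def two_cliques_bridge():
    """Two 5-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in (0, 5):
        members = [f"n{base + i}" for i in range(5)]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                g.add_edge(a, b)
    g.add_edge("n0", "n5")
    return g
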