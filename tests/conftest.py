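import numpy as np
import pytest

from netmotif.network_session import Network, Session
from netmotif.synthetic_data import (
    PlantedMotifSpec,
    generate_genome,
    plant_motif,
)


@pytest.fixture
def triangle() -> Network:
    net = Network("k3")
    for n in "ABC":
        net.add_node(n)
    net.add_edge("A", "B", "pp")
    net.add_edge("B", "C", "pp")
    net.add_edge("A", "C", "pp")
    return net


@pytest.fixture
def path_graph() -> Network:
    net = Network("path")
    for n in "ABC":
        net.add_node(n)
    net.add_edge("A", "B", "pp")
    net.add_edge("B", "C", "pp")
    return net


def make_network(name: str, nodes, edges) -> Network:
    net = Network(name)
    for n in nodes:
        net.add_node(n)
    for s, t in edges:
        net.add_edge(s, t, "pp")
    return net


@pytest.fixture
def two_net_session() -> Session:
    a = make_network("human", ["F5", "C1QB", "SOCS3"], [("F5", "C1QB")])
    b = make_network("mouse", ["F5", "Socs3"], [])
    return Session([a, b])


@pytest.fixture(scope="session")
def regulon_fixture():
    """A 30-gene genome with a 12-gene planted regulon (palindromic word)."""
    genome = generate_genome(30, 300, 200, seed=11)
    tags = [g.locus_tag for g in genome.genes]
    regulon = frozenset(tags[:12])
    spec = PlantedMotifSpec(
        consensus="GGGACTTAAGTCCC",
        regulon=regulon,
        offset_range=(10, 80),
        mutation_rate=0.05,
    )
    genome, sites = plant_motif(genome, spec, seed=12)
    return genome, regulon, sites, "GGGACTTAAGTCCC"


def random_simple_graph(n: int, p: float, seed: int) -> Network:
    rng = np.random.default_rng(seed)
    net = Network(f"rand{seed}")
    names = [f"n{i}" for i in range(n)]
    for name in names:
        net.add_node(name)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j], "pp")
    return net
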