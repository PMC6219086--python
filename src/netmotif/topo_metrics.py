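"""Per-node and differential topology: degree, clustering, components,
exclusive-edge partitions, and cross-network comparison tables.

All metrics are computed on the undirected simple view of a network
(parallel edges collapsed, self-loops dropped); direction and interaction
labels play no role here.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from netmotif.network_session import Network, Session


@dataclass
class NodeMetrics:
    shared_name: str
    degree: int
    clustering: float
    component_id: int


def _simple_graph(network: Network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for edge in network.edges:
        if edge.source != edge.target:
            g.add_edge(edge.source, edge.target)
    return g


def node_metrics(network: Network) -> list[NodeMetrics]:
    """Degree, clustering coefficient and component label for every node.

    clustering(v) = 2 * (edges among neighbors of v) / (deg(v) * (deg(v)-1)),
    defined as 0 for degree < 2.  Component ids are arbitrary but consistent
    labels; isolated nodes get their own component.
    """
    g = _simple_graph(network)
    clustering = nx.clustering(g)
    component_of: dict[str, int] = {}
    for comp_id, comp in enumerate(nx.connected_components(g)):
        for name in comp:
            component_of[name] = comp_id
    return [
        NodeMetrics(
            shared_name=name,
            degree=g.degree(name),
            clustering=float(clustering[name]),
            component_id=component_of[name],
        )
        for name in sorted(network.nodes)
    ]


def exclusive_edges(
    a: Network, b: Network
) -> tuple[set[frozenset], set[frozenset], set[frozenset]]:
    """Partition the union of the two edge sets by membership.

    Edge identity is the unordered shared-name pair (simple view, self-loops
    dropped).  Returns (only in a, only in b, shared) -- three disjoint sets.
    """
    edges_a = {frozenset((e.source, e.target)) for e in a.edges if e.source != e.target}
    edges_b = {frozenset((e.source, e.target)) for e in b.edges if e.source != e.target}
    return edges_a - edges_b, edges_b - edges_a, edges_a & edges_b


def compare_table(session: Session, names: set[str]) -> pd.DataFrame:
    """Cross-network per-node comparison: one row per (name, network).

    Columns: network, shared_name, present, degree, clustering, component.
    Metrics are left empty (NA) for absent nodes.
    """
    rows = []
    for net in session.networks:
        metrics = {m.shared_name: m for m in node_metrics(net)}
        for name in sorted(names):
            m = metrics.get(name)
            rows.append(
                {
                    "network": net.name,
                    "shared_name": name,
                    "present": m is not None,
                    "degree": m.degree if m else pd.NA,
                    "clustering": m.clustering if m else pd.NA,
                    "component": m.component_id if m else pd.NA,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["network", "shared_name", "present", "degree", "clustering", "component"],
    )
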