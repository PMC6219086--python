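"""Data model and I/O for multiple networks sharing a node-identity space.

Networks carry nodes keyed by a "shared name" -- the attribute used to decide
that two nodes in different networks denote the same entity.  Supported
interchange formats: SIF (line based), XGMML (XML), and zip session archives
bundling several XGMML documents.
"""

from __future__ import annotations

import io
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import xml.etree.ElementTree as etree

log = logging.getLogger(__name__)

XGMML_NS = "http://www.cs.rpi.edu/XGMML"

AttrValue = Union[int, float, str, bool]


class NetworkFormatError(ValueError):
    """Raised on malformed SIF/XGMML/session input."""


@dataclass
class Node:
    """A network node identified by its shared name.

    ``shared_name`` is the cross-network identity key; ``attributes`` holds
    free-form per-node data (e.g. log2 fold change, significance).
    """

    shared_name: str
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.shared_name:
            raise ValueError("shared_name must be non-empty")


@dataclass
class Edge:
    """An edge between two shared names within one network."""

    source: str
    target: str
    interaction: str = ""
    directed: bool = False
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    def key(self) -> tuple:
        """Identity used for duplicate collapsing: unordered endpoint pair
        plus interaction label (ordered pair when directed)."""
        if self.directed:
            ends = (self.source, self.target)
        else:
            ends = tuple(sorted((self.source, self.target)))
        return (*ends, self.interaction, self.directed)


class Network:
    """A named graph whose nodes are keyed by shared name."""

    def __init__(self, name: str = "network"):
        self.name = name
        self.nodes: dict[str, Node] = {}
        self.edges: list[Edge] = []
        self.metadata: dict[str, AttrValue] = {}
        self._edge_index: dict[tuple, Edge] = {}

    def add_node(self, shared_name: str, **attributes: AttrValue) -> Node:
        node = self.nodes.get(shared_name)
        if node is None:
            node = Node(shared_name, dict(attributes))
            self.nodes[shared_name] = node
        else:
            node.attributes.update(attributes)
        return node

    def add_edge(
        self,
        source: str,
        target: str,
        interaction: str = "",
        directed: bool = False,
        collapse: bool = True,
        **attributes: AttrValue,
    ) -> Edge:
        """Add an edge; endpoints must already be nodes.

        With ``collapse`` (the default, matching SIF import semantics) a
        duplicate of an existing edge only bumps that edge's ``count``
        attribute instead of creating a parallel edge.
        """
        for end in (source, target):
            if end not in self.nodes:
                raise NetworkFormatError(
                    f"edge endpoint {end!r} not a node of network {self.name!r}"
                )
        edge = Edge(source, target, interaction, directed, dict(attributes))
        if len(self._edge_index) != len(self.edges):  # edges mutated directly
            self._edge_index = {e.key(): e for e in self.edges}
        if collapse:
            existing = self._edge_index.get(edge.key())
            if existing is not None:
                existing.attributes["count"] = int(existing.attributes.get("count", 1)) + 1
                return existing
        self.edges.append(edge)
        self._edge_index[edge.key()] = edge
        return edge

    @property
    def node_names(self) -> set[str]:
        return set(self.nodes)

    def edge_multiset(self) -> dict[tuple, int]:
        """Edge identity -> multiplicity (collapsed count included)."""
        out: dict[tuple, int] = {}
        for e in self.edges:
            out[e.key()] = out.get(e.key(), 0) + int(e.attributes.get("count", 1))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network({self.name!r}, {len(self.nodes)} nodes, {len(self.edges)} edges)"


class Session:
    """An ordered collection of networks plus registered identity maps."""

    def __init__(self, networks: Iterable[Network] = ()):
        self.networks: list[Network] = []
        self.identity_maps: dict[tuple[str, str], "object"] = {}
        for net in networks:
            self.add_network(net)

    def add_network(self, network: Network) -> None:
        if any(n.name == network.name for n in self.networks):
            raise ValueError(f"duplicate network name {network.name!r} in session")
        self.networks.append(network)

    def add_identity_map(self, identity_map) -> None:
        self.identity_maps[identity_map.spaces] = identity_map

    def __getitem__(self, name: str) -> Network:
        for net in self.networks:
            if net.name == name:
                return net
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.networks)


# ---------------------------------------------------------------------------
# SIF

def read_sif(path) -> Network:
    """Read a Simple Interaction Format file.

    Lines hold either a single token (isolated node) or
    ``source interaction target [target ...]``; one edge is created per
    (source, target) pair.  Delimiter is tab when the line contains tabs,
    otherwise any whitespace.  Duplicate edges are collapsed with a ``count``
    attribute.  A two-token line is malformed.
    """
    path = Path(path)
    net = Network(name=path.stem)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tokens = [t for t in (line.split("\t") if "\t" in line else line.split()) if t.strip()]
            tokens = [t.strip() for t in tokens]
            if len(tokens) == 1:
                net.add_node(tokens[0])
            elif len(tokens) == 2:
                raise NetworkFormatError(
                    f"{path.name}:{lineno}: SIF line has 2 tokens "
                    "(need 1 for an isolated node or >=3 for edges)"
                )
            else:
                source, interaction, *targets = tokens
                net.add_node(source)
                for target in targets:
                    net.add_node(target)
                    net.add_edge(source, target, interaction)
    return net


def write_sif(network: Network, path) -> None:
    """Write a network as SIF (tab-delimited); collapsed duplicates are
    expanded back to repeated lines so that the edge multiset round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        linked: set[str] = set()
        for edge in network.edges:
            count = int(edge.attributes.get("count", 1))
            for _ in range(count):
                fh.write(f"{edge.source}\t{edge.interaction or 'pp'}\t{edge.target}\n")
            linked.add(edge.source)
            linked.add(edge.target)
        for name in sorted(network.nodes):
            if name not in linked:
                fh.write(f"{name}\n")


# ---------------------------------------------------------------------------
# XGMML

def _coerce(value: str, declared_type: str | None):
    if declared_type in ("real", "double", "float"):
        return float(value)
    if declared_type in ("integer", "int", "long"):
        return int(value)
    if declared_type == "boolean":
        return value.strip().lower() in ("true", "1", "yes")
    return value


def _localname(el) -> str:
    tag = el.tag if hasattr(el, "tag") else el
    return tag.rsplit("}", 1)[-1]


def read_xgmml(source) -> Network:
    """Read a network from an XGMML document (path, file object or bytes).

    Node shared names come from the node ``label`` attribute, falling back to
    a ``shared name`` att child, then to the node id.  ``att`` children become
    node attributes with type coercion per their declared type.
    """
    if isinstance(source, (str, Path)):
        tree = etree.parse(str(source))
    elif isinstance(source, bytes):
        tree = etree.parse(io.BytesIO(source))
    else:
        tree = etree.parse(source)
    graph = tree.getroot()
    if _localname(graph) != "graph":
        raise NetworkFormatError(f"not an XGMML document (root <{graph.tag}>)")
    net = Network(name=graph.get("label") or graph.get("id") or "network")
    directed_default = graph.get("directed") == "1"

    id_to_name: dict[str, str] = {}
    for el in graph:
        if _localname(el) != "node":
            continue
        node_id = el.get("id")
        attrs: dict[str, AttrValue] = {}
        shared_from_att = None
        for att in el:
            name = _localname(att)
            if name == "att":
                att_name = att.get("name")
                att_value = att.get("value")
                if att_name is None or att_value is None:
                    continue
                if att_name == "shared name":
                    shared_from_att = att_value
                attrs[att_name] = _coerce(att_value, att.get("type"))
            elif name == "graphics":
                for coord in ("x", "y"):
                    if att.get(coord) is not None:
                        attrs[coord] = float(att.get(coord))
        shared_name = el.get("label") or shared_from_att or node_id
        if not shared_name:
            raise NetworkFormatError("XGMML node without label, shared name att, or id")
        attrs.pop("shared name", None)
        net.add_node(shared_name, **attrs)
        if node_id is not None:
            id_to_name[node_id] = shared_name
        id_to_name[shared_name] = shared_name

    for el in graph:
        if _localname(el) != "edge":
            continue
        src, tgt = el.get("source"), el.get("target")
        if src not in id_to_name or tgt not in id_to_name:
            raise NetworkFormatError(
                f"XGMML edge references unknown node id ({src!r} -> {tgt!r})"
            )
        attrs = {}
        for att in el:
            if _localname(att) == "att" and att.get("name") and att.get("value") is not None:
                attrs[att.get("name")] = _coerce(att.get("value"), att.get("type"))
        interaction = str(attrs.pop("interaction", el.get("label") or ""))
        net.add_edge(
            id_to_name[src], id_to_name[tgt], interaction,
            directed=directed_default, collapse=False, **attrs,
        )
    return net


def _att_type(value: AttrValue) -> tuple[str, str]:
    if isinstance(value, bool):
        return "boolean", "true" if value else "false"
    if isinstance(value, int):
        return "integer", str(value)
    if isinstance(value, float):
        return "real", repr(value)
    return "string", str(value)


def write_xgmml(network: Network, path) -> None:
    """Write a network as XGMML; round-trips nodes, edges and attributes."""
    etree.register_namespace("", XGMML_NS)
    graph = etree.Element(f"{{{XGMML_NS}}}graph")
    graph.set("label", network.name)
    graph.set("directed", "0")
    for name in sorted(network.nodes):
        node = network.nodes[name]
        el = etree.SubElement(graph, f"{{{XGMML_NS}}}node", id=name, label=name)
        for att_name, att_value in node.attributes.items():
            type_str, value_str = _att_type(att_value)
            etree.SubElement(
                el, f"{{{XGMML_NS}}}att",
                name=att_name, value=value_str, type=type_str,
            )
    for edge in network.edges:
        el = etree.SubElement(
            graph, f"{{{XGMML_NS}}}edge",
            source=edge.source, target=edge.target,
        )
        if edge.interaction:
            el.set("label", edge.interaction)
            etree.SubElement(
                el, f"{{{XGMML_NS}}}att",
                name="interaction", value=edge.interaction, type="string",
            )
        for att_name, att_value in edge.attributes.items():
            type_str, value_str = _att_type(att_value)
            etree.SubElement(
                el, f"{{{XGMML_NS}}}att",
                name=att_name, value=value_str, type=type_str,
            )
    tree = etree.ElementTree(graph)
    etree.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# Session archives (zip of XGMML documents, e.g. Cytoscape .cys files)

def _is_view_doc(graph) -> bool:
    # Cytoscape view documents mark the graph element with cy:view="1";
    # they duplicate a base network's nodes and only add coordinates.
    for attr_name, attr_value in graph.attrib.items():
        if _localname(attr_name) == "view" and attr_value in ("1", "true"):
            return True
    return False


def read_session_archive(path) -> Session:
    """Build a Session from a zip archive containing XGMML documents.

    Any archive entry that parses as XGMML becomes a network; other entries
    are ignored with a log line.  View-only documents (marked ``cy:view`` and
    duplicating a network's node set with coordinates) are folded into the
    matching network as x/y node attributes rather than added as networks.
    """
    networks: list[Network] = []
    views: list[Network] = []
    with zipfile.ZipFile(path) as zf:
        for entry in zf.namelist():
            if entry.endswith("/"):
                continue
            data = zf.read(entry)
            try:
                root = etree.fromstring(data)
            except etree.ParseError:
                log.info("session entry %s is not XML; ignored", entry)
                continue
            if _localname(root) != "graph":
                log.info("session entry %s is XML but not XGMML; ignored", entry)
                continue
            net = read_xgmml(data)
            if net.name in ("network", ""):
                net.name = Path(entry).stem
            if _is_view_doc(root):
                views.append(net)
            else:
                networks.append(net)
    if not networks and not views:
        raise NetworkFormatError(f"session archive {path} contains no XGMML documents")
    if not networks:
        # archive of bare view documents: treat them as the networks
        networks, views = views, []

    used_names: set[str] = set()
    for net in networks:
        base = net.name
        suffix = 1
        while net.name in used_names:
            suffix += 1
            net.name = f"{base}_{suffix}"
        used_names.add(net.name)

    for view in views:
        # match the view to the network with the largest node overlap
        best, best_overlap = None, 0
        for net in networks:
            overlap = len(net.node_names & view.node_names)
            if overlap > best_overlap:
                best, best_overlap = net, overlap
        if best is None:
            log.info("view document %s matches no network; ignored", view.name)
            continue
        for name, vnode in view.nodes.items():
            if name in best.nodes:
                for coord in ("x", "y"):
                    if coord in vnode.attributes:
                        best.nodes[name].attributes[coord] = vnode.attributes[coord]
    return Session(networks)


# ---------------------------------------------------------------------------
# Attribute tables

def attach_attributes(network: Network, table, key_column: str) -> Network:
    """Merge a delimited table (path or DataFrame) into node attributes.

    Rows whose ``key_column`` value matches a node's shared name contribute
    their remaining columns as attributes (overwriting on re-attach, so the
    operation is idempotent).  The number of unmatched rows is reported via
    the log and ``network.metadata['unmatched_rows']``.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    if key_column not in table.columns:
        raise NetworkFormatError(
            f"key column {key_column!r} not in table columns {list(table.columns)}"
        )
    unmatched = 0
    value_columns = [c for c in table.columns if c != key_column]
    for _, row in table.iterrows():
        key = str(row[key_column])
        node = network.nodes.get(key)
        if node is None:
            unmatched += 1
            continue
        for col in value_columns:
            raw = row[col]
            if isinstance(raw, str):
                try:
                    value: AttrValue = int(raw)
                except ValueError:
                    try:
                        value = float(raw)
                    except ValueError:
                        value = raw
            else:
                value = raw
            node.attributes[col] = value
    network.metadata["unmatched_rows"] = unmatched
    if unmatched:
        log.info("attach_attributes: %d unmatched rows on %s", unmatched, network.name)
    return network
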