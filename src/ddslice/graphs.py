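"""Co-occurrence graphs, wheel (star/hub) motifs, and Cytoscape export.

Pair sets become undirected graphs whose nodes are descriptors and whose
edges carry the co-occurrence frequency.  The characteristic structure of
frequency-sliced literature networks is the "wheel": one high-degree center
descriptor with its neighbors as rim.  Two wheels whose rims overlap define a
hub-intersection subnetwork — the centers plus their common neighbors, with
the edges tying the shared nodes to each center.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .cooc import DescriptorPair, FrequencyTable

__all__ = [
    "WheelMotif",
    "to_graph",
    "find_wheels",
    "hub_intersection",
    "export_graph",
    "graph_from_edge_tsv",
    "graph_to_table",
]

EXPORT_FORMATS = ("sif", "graphml", "edge_tsv")


@dataclass(frozen=True)
class WheelMotif:
    """A star sub-network: ``center`` plus its neighbor set ``rim``."""

    center: str
    rim: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.rim)


def to_graph(pairs: FrequencyTable | Iterable[DescriptorPair]) -> nx.Graph:
    """Build an undirected graph from a frequency table or bare pair set.

    Node set is the union of pair endpoints; edges carry a ``frequency``
    attribute (1 when built from a bare pair set).  Insertion order is
    canonical-sorted so downstream exports are deterministic.
    """
    graph = nx.Graph()
    if isinstance(pairs, FrequencyTable):
        edges = sorted(pairs.items())
    else:
        edges = sorted((p, 1) for p in pairs)
    for pair, freq in edges:
        graph.add_edge(pair.a, pair.b, frequency=freq)
    return graph


def graph_to_table(graph: nx.Graph, label: str = "") -> FrequencyTable:
    """Inverse of :func:`to_graph` (isolated nodes, if any, are dropped)."""
    entries = {
        DescriptorPair(u, v): int(data.get("frequency", 1))
        for u, v, data in graph.edges(data=True)
    }
    return FrequencyTable(entries, label)


def find_wheels(graph: nx.Graph, min_rim: int = 5) -> list[WheelMotif]:
    """One motif per node with degree >= min_rim, by descending rim size.

    A wheel is formalized as a star: the center's neighborhood is the rim and
    rim–rim edges are not required.  A node may be a center and also sit on
    another center's rim (the wheel-wheel case).  Ties in rim size break
    lexicographically on the center name.
    """
    if min_rim < 2:
        raise ValueError(f"min_rim must be >= 2, got {min_rim}")
    wheels = [
        WheelMotif(node, frozenset(graph.neighbors(node)))
        for node in graph.nodes
        if graph.degree(node) >= min_rim
    ]
    return sorted(wheels, key=lambda w: (-w.size, w.center))


def hub_intersection(graph: nx.Graph, center_a: str, center_b: str) -> nx.Graph:
    """Subnetwork of two wheel centers and their shared rim.

    Nodes are the two centers plus the common neighbors N(a) ∩ N(b); edges
    are those tying each shared node to a center, plus the center–center edge
    when present in the input.  (Shared-node-to-shared-node edges are not
    part of the motif and are dropped.)
    """
    for center in (center_a, center_b):
        if center not in graph:
            raise KeyError(f"center not in graph: {center!r}")
    common = set(graph.neighbors(center_a)) & set(graph.neighbors(center_b))
    common.discard(center_a)
    common.discard(center_b)
    sub = nx.Graph()
    sub.add_nodes_from([center_a, center_b])
    for node in sorted(common):
        for center in (center_a, center_b):
            sub.add_edge(center, node, **graph.edges[center, node])
    if graph.has_edge(center_a, center_b):
        sub.add_edge(center_a, center_b, **graph.edges[center_a, center_b])
    return sub


def _canonical_edges(graph: nx.Graph) -> list[tuple[str, str, int]]:
    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append((a, b, int(data.get("frequency", 1))))
    return sorted(rows, key=lambda r: (-r[2], r[0], r[1]))


def export_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Write the graph for Cytoscape or re-import.

    ``sif``: ``nodeA<TAB>cooc<TAB>nodeB`` rows plus a bare row per isolated
    node.  ``graphml``: standard GraphML with ``frequency`` as an edge
    attribute.  ``edge_tsv``: the frequency-table TSV (descriptor_a,
    descriptor_b, frequency).  All formats use the canonical pair sort, so
    output is byte-identical across runs.
    """
    path = Path(path)
    if fmt == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for a, b, _ in _canonical_edges(graph):
                fh.write(f"{a}\tcooc\t{b}\n")
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        ordered = nx.Graph()
        ordered.add_nodes_from(sorted(graph.nodes))
        for a, b, f in _canonical_edges(graph):
            ordered.add_edge(a, b, frequency=f)
        nx.write_graphml(ordered, str(path))
    elif fmt == "edge_tsv":
        graph_to_table(graph).to_tsv(path)
    else:
        raise ValueError(
            f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}"
        )


def graph_from_edge_tsv(path: str | Path) -> nx.Graph:
    """Re-import an ``edge_tsv`` export (round-trip inverse of export)."""
    return to_graph(FrequencyTable.from_tsv(path))
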