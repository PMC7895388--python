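"""Adjacency graph of parameter regions and its topology.

Two parameter regions are adjacent when they share a codimension-1
boundary: a hypersurface where exactly one attractor-membership inequality
becomes an equality (one wall value coincides with one threshold), with a
neighborhood meeting the interiors of both regions.  In the arrangement
picture this is a certified boundary between two bin-adjacent cells that
belong to the two regions.

Distances on the graph count edges (adjacent regions are at distance 1);
a shortest path visiting ``d+1`` regions has length ``d``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .sharp import RegionCatalog, ToyAnalysis

__all__ = [
    "RegionGraph",
    "DistanceDistribution",
    "adjacent",
    "build_graph",
    "build_toy_graph",
    "distance_stats",
    "export_graph",
]


@dataclass(frozen=True)
class DistanceDistribution:
    """Histogram of pairwise shortest-path distances between regions."""

    histogram: dict          # distance -> number of unordered pairs
    diameter: int
    n_nodes: int
    connected: bool

    @property
    def n_pairs(self) -> int:
        return sum(self.histogram.values())

    def fraction_within(self, d: int) -> float:
        tot = self.n_pairs
        return sum(v for k, v in self.histogram.items() if k <= d) / tot

    def to_dict(self) -> dict:
        return {
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "diameter": self.diameter,
            "n_nodes": self.n_nodes,
            "n_pairs": self.n_pairs,
            "connected": self.connected,
            "fraction_within_4": self.fraction_within(4),
        }


class RegionGraph:
    """Undirected graph over region labels with shared-boundary edges."""

    def __init__(self, graph: nx.Graph, catalog: RegionCatalog | None = None):
        self.graph = graph
        self.catalog = catalog

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)


def build_graph(catalog: RegionCatalog) -> RegionGraph:
    """Region adjacency from the catalog's certified cell boundaries.

    Every certified cell boundary joining cells of two different regions
    witnesses a codimension-1 interface between them (the threshold involved
    is a free coordinate, so the crossing is transversal).
    """
    g = nx.Graph()
    for region in catalog.regions:
        cfg = region.configuration
        g.add_node(
            region.label,
            bitmask=cfg.bitmask,
            n_symmetric=len(cfg.symmetric_attractors),
            n_asymmetric=len(cfg.asymmetric_attractors),
            component_index=region.component_index,
            attractors="|".join(map(str, sorted(cfg.attractors))),
        )
    for key in catalog.cell_edges:
        a, b = tuple(key)
        ra = catalog._cell_to_region.get(a)
        rb = catalog._cell_to_region.get(b)
        if ra is None or rb is None or ra.label == rb.label:
            continue
        g.add_edge(ra.label, rb.label)
    return RegionGraph(g, catalog)


def build_toy_graph() -> RegionGraph:
    """The three-region path graph D1 - D2 - D3 of the toy model."""
    toy = ToyAnalysis()
    g = nx.Graph()
    patterns = {r: toy.heaviside_state_pattern(r) for r in ("D1", "D2", "D3")}
    for r, (lo, hi) in patterns.items():
        g.add_node(r, n_low=lo, n_high=hi)
    g.add_edges_from(toy.adjacency())
    return RegionGraph(g)


def adjacent(region_a, region_b, catalog: RegionCatalog) -> bool:
    """Do two catalog regions share a certified codimension-1 boundary?"""
    la = region_a if isinstance(region_a, str) else region_a.label
    lb = region_b if isinstance(region_b, str) else region_b.label
    if la == lb:
        return False
    return build_graph(catalog).has_edge(la, lb)


def distance_stats(g: RegionGraph) -> DistanceDistribution:
    """All-pairs shortest-path histogram (unordered pairs) and diameter.

    For a disconnected graph the histogram covers pairs within components
    and the diameter is taken over the largest component.
    """
    graph = g.graph
    hist: dict[int, int] = {}
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    nodes = sorted(graph.nodes)
    diameter = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            d = lengths[a].get(b)
            if d is None:
                continue
            hist[d] = hist.get(d, 0) + 1
            diameter = max(diameter, d)
    return DistanceDistribution(
        histogram=hist,
        diameter=diameter,
        n_nodes=graph.number_of_nodes(),
        connected=nx.is_connected(graph),
    )


def export_graph(g: RegionGraph, path, fmt: str | None = None) -> None:
    """Write the graph as GraphML, DOT or a JSON distance report."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "graphml":
        nx.write_graphml(g.graph, path)
    elif fmt == "dot":
        lines = ["graph regions {"]
        for node, data in sorted(g.graph.nodes(data=True)):
            attrs = ", ".join(f'{k}="{v}"' for k, v in sorted(data.items()))
            lines.append(f'  "{node}" [{attrs}];')
        for a, b in sorted(map(sorted, g.graph.edges)):
            lines.append(f'  "{a}" -- "{b}";')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        path.write_text(json.dumps(distance_stats(g).to_dict(), indent=1) + "\n")
    else:
        raise ValueError(f"unsupported export format {fmt!r}")
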