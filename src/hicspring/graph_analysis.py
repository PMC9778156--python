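"""Pure contact graphs: construction, merging, degree filtering, export.

A contact graph has bins as nodes and Hi-C interactions as weighted edges.
Intra- and interchromosomal graphs are built separately to reduce
complexity, then merged into a combined graph; degree filtering of a
percentile-filtered interchromosomal graph exposes conserved contact paths
("Newton's cradle" chains).  2D layout itself is delegated to external
tools (e.g. Gephi) through GEXF/GraphML export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from .contacts_io import ContactTable, Scope
from .genome_model import GenomeBins, Multigraph

__all__ = [
    "ContactGraph",
    "build_contact_graph",
    "merge_graphs",
    "filter_by_degree",
    "largest_component",
    "export_gexf",
    "export_graphml",
    "export_edgelist",
]


@dataclass
class ContactGraph:
    """Weighted simple graph on global bin indices."""

    bins: GenomeBins
    graph: nx.Graph
    scope: str = "all"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_contact_graph(table: ContactTable, scope: Scope = "all") -> ContactGraph:
    """One node per bin seen in a retained record, one weighted edge per record."""
    rec = table.scoped(scope)
    g = nx.Graph()
    g.add_weighted_edges_from(
        zip(rec["bin_i"].astype(int), rec["bin_j"].astype(int), rec["count"])
    )
    return ContactGraph(table.bins, g, scope)


def merge_graphs(g1: ContactGraph, g2: ContactGraph) -> ContactGraph:
    """Union of nodes and edges; weights of any shared edge are summed.

    Intra- and inter-scope edge sets are disjoint by construction, so for the
    usual merge the edge count is exactly additive.
    """
    if g1.bins != g2.bins:
        raise ValueError("cannot merge contact graphs over different bin universes")
    merged = nx.Graph()
    merged.add_nodes_from(g1.graph.nodes)
    merged.add_nodes_from(g2.graph.nodes)
    for g in (g1.graph, g2.graph):
        for u, v, d in g.edges(data=True):
            w = d.get("weight", 1.0)
            if merged.has_edge(u, v):
                merged[u][v]["weight"] += w
            else:
                merged.add_edge(u, v, weight=w)
    return ContactGraph(g1.bins, merged, "merged")


def filter_by_degree(g: ContactGraph, min_degree: int) -> ContactGraph:
    """Induced subgraph on nodes of degree >= ``min_degree`` (single pass)."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    keep = [v for v, d in g.graph.degree if d >= min_degree]
    return ContactGraph(g.bins, nx.Graph(g.graph.subgraph(keep)), g.scope)


def largest_component(g: ContactGraph) -> ContactGraph:
    """Connected component with the most nodes; ties go to the component
    containing the smallest bin index."""
    if g.n_nodes == 0:
        return ContactGraph(g.bins, nx.Graph(), g.scope)
    comp = max(nx.connected_components(g.graph), key=lambda c: (len(c), -min(c)))
    return ContactGraph(g.bins, nx.Graph(g.graph.subgraph(comp)), g.scope)


def _position_rank(bins: GenomeBins, b: int) -> float:
    """Fractional position of a bin along its chromosome, in [0, 1]."""
    c = bins.bin_chrom[b]
    n = int(bins.bins_per_chrom[c])
    local = b - int(bins.chrom_offsets[c])
    return local / (n - 1) if n > 1 else 0.0


def _to_networkx(obj) -> nx.Graph:
    """Annotated networkx view of a ContactGraph or Multigraph for export."""
    if isinstance(obj, ContactGraph):
        g = nx.Graph()
        bins = obj.bins
        for v in obj.graph.nodes:
            g.add_node(
                int(v),
                chrom=bins.chrom_names[bins.bin_chrom[v]],
                start_bp=int(bins.bin_start[v]),
                color_rank=float(_position_rank(bins, v)),
            )
        for u, v, d in obj.graph.edges(data=True):
            g.add_edge(int(u), int(v), weight=float(d.get("weight", 1.0)), etype="contact")
        return g
    if isinstance(obj, Multigraph):
        g = nx.MultiGraph()
        bins = obj.bins
        per_chrom = bins.bins_per_chrom + 1
        for v in range(obj.n_nodes):
            c = int(obj.node_chrom[v])
            local = v - int(np.concatenate([[0], np.cumsum(per_chrom)[:-1]])[c])
            nmax = int(per_chrom[c]) - 1
            g.add_node(
                v,
                chrom=bins.chrom_names[c],
                start_bp=int(obj.node_bp[v]),
                color_rank=local / nmax if nmax else 0.0,
            )
        for (a, b), rest in zip(obj.genomic_edges, obj.genomic_rest):
            g.add_edge(int(a), int(b), etype="genomic", rest_length=float(rest), weight=1.0)
        for (a, b), w in zip(obj.contact_edges, obj.contact_weight):
            g.add_edge(int(a), int(b), etype="contact", weight=float(w))
        return g
    raise TypeError(f"cannot export object of type {type(obj).__name__}")


def export_gexf(obj, path) -> None:
    """Write a ContactGraph or Multigraph as GEXF (Gephi interchange)."""
    nx.write_gexf(_to_networkx(obj), path)


def export_graphml(obj, path) -> None:
    nx.write_graphml(_to_networkx(obj), path)


def export_edgelist(g: ContactGraph, path) -> None:
    """Three-column TSV edge list (bin_i, bin_j, weight)."""
    with open(path, "w") as fh:
        for u, v, d in g.graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):g}\n")
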