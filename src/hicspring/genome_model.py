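"""Genome-as-graph data model.

A genome binned at a fixed resolution is represented physically as a set of
bead-and-spring chains: the *nodes* are bin boundary points (one per bin
start plus one terminal node per chromosome) and each *genomic edge* is the
elastic segment ("cylinder") spanning one bin.  Hi-C interactions add a
second edge class, *contact edges*: short, stiff springs joining the start
nodes of the two interacting bins.  The union of the two edge classes over
the shared node set is the multigraph that the layout engine embeds in 3D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "Multigraph", "make_bins", "read_chrom_sizes", "build_multigraph"]

DEFAULT_BIN_SIZE = 10_000


@dataclass(frozen=True)
class GenomeBins:
    """Uniform tiling of a genome into fixed-size bins.

    Bins are 0-based, half-open ``[start, end)`` and tile each chromosome
    without gaps; the last bin of a chromosome may be shorter than
    ``bin_size``.  Global bin indices are dense, ordered by chromosome order
    then start coordinate.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    # derived, filled by make_bins
    bin_chrom: np.ndarray = field(repr=False, default=None)  # chrom index per bin
    bin_start: np.ndarray = field(repr=False, default=None)  # bp
    bin_end: np.ndarray = field(repr=False, default=None)  # bp

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_names)

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def bins_per_chrom(self) -> np.ndarray:
        return np.bincount(self.bin_chrom, minlength=self.n_chrom)

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global index of the first bin of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)[:-1]])

    @property
    def bin_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.chrom_names[c] for c in self.bin_chrom],
                "start": self.bin_start,
                "end": self.bin_end,
                "global_index": np.arange(self.n_bins),
            }
        )

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of bp position ``pos`` on chromosome ``chrom``."""
        c = self.chrom_index(chrom)
        if pos < 0 or pos >= self.chrom_lengths[c]:
            raise ValueError(
                f"position {pos} outside chromosome {chrom!r} "
                f"(length {self.chrom_lengths[c]})"
            )
        return int(self.chrom_offsets[c] + pos // self.bin_size)

    def same_chrom(self, bin_i: np.ndarray, bin_j: np.ndarray) -> np.ndarray:
        return self.bin_chrom[np.asarray(bin_i)] == self.bin_chrom[np.asarray(bin_j)]

    def __eq__(self, other) -> bool:  # value semantics for the bin universe
        return (
            isinstance(other, GenomeBins)
            and self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )

    def __hash__(self):
        return hash((self.chrom_names, self.chrom_lengths, self.bin_size))


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1], names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def make_bins(
    chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> GenomeBins:
    """Tile each chromosome into ``ceil(length / bin_size)`` bins.

    Parameters
    ----------
    chrom_sizes
        Mapping (or sequence of pairs) chromosome name -> length in bp, in
        the desired chromosome order.
    bin_size
        Bin width in bp (default 10 kb).
    """
    items = list(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else list(chrom_sizes)
    if not items:
        raise ValueError("chrom_sizes is empty")
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    names, lengths = [], []
    for name, length in items:
        if int(length) <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        names.append(str(name))
        lengths.append(int(length))
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")

    chroms, starts, ends = [], [], []
    for c, length in enumerate(lengths):
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        chroms.append(np.full(len(s), c, dtype=np.int32))
        starts.append(s)
        ends.append(e)
    return GenomeBins(
        chrom_names=tuple(names),
        chrom_lengths=tuple(lengths),
        bin_size=int(bin_size),
        bin_chrom=np.concatenate(chroms),
        bin_start=np.concatenate(starts),
        bin_end=np.concatenate(ends),
    )


@dataclass
class Multigraph:
    """Two-edge-class physical model of a binned genome.

    ``genomic_edges[g]`` spans global bin ``genomic_edge_bin[g]``; a
    chromosome of *n* bins contributes *n+1* nodes and *n* genomic edges, so
    with no contacts the model is a disjoint union of simple paths.  Contact
    edges join the start nodes of interacting bins and by default are "hard"
    springs (stiffness ``k2``) with rest length a quarter of the genomic rest
    length.
    """

    bins: GenomeBins
    node_chrom: np.ndarray  # (n_nodes,) chromosome index
    node_bp: np.ndarray  # (n_nodes,) bp coordinate of the boundary point
    genomic_edges: np.ndarray  # (n_gen, 2) node ids
    genomic_rest: np.ndarray  # (n_gen,) rest lengths, layout units
    genomic_edge_bin: np.ndarray  # (n_gen,) global bin spanned by each edge
    contact_edges: np.ndarray  # (n_con, 2) node ids
    contact_weight: np.ndarray  # (n_con,) summed contact counts
    contact_rest: np.ndarray  # (n_con,) rest lengths
    k1: float = 1.0
    k2: float = 50.0
    contact_stiffness: np.ndarray | None = None  # per-edge override of k2

    @property
    def n_nodes(self) -> int:
        return len(self.node_chrom)

    @property
    def n_genomic_edges(self) -> int:
        return len(self.genomic_edges)

    @property
    def n_contact_edges(self) -> int:
        return len(self.contact_edges)

    def node_offsets(self) -> np.ndarray:
        """First node id of each chromosome."""
        per_chrom = self.bins.bins_per_chrom + 1
        return np.concatenate([[0], np.cumsum(per_chrom)[:-1]])

    def start_node(self, bin_index) -> np.ndarray:
        """Node id of the start boundary point of a (global) bin."""
        b = np.asarray(bin_index)
        return b + self.bins.bin_chrom[b]

    def copy(self) -> "Multigraph":
        return Multigraph(
            bins=self.bins,
            node_chrom=self.node_chrom,
            node_bp=self.node_bp,
            genomic_edges=self.genomic_edges.copy(),
            genomic_rest=self.genomic_rest.copy(),
            genomic_edge_bin=self.genomic_edge_bin.copy(),
            contact_edges=self.contact_edges.copy(),
            contact_weight=self.contact_weight.copy(),
            contact_rest=self.contact_rest.copy(),
            k1=self.k1,
            k2=self.k2,
            contact_stiffness=None if self.contact_stiffness is None else self.contact_stiffness.copy(),
        )

    def total_genomic_rest_length(self) -> float:
        return float(self.genomic_rest.sum())

    def contact_k(self) -> np.ndarray:
        if self.contact_stiffness is not None:
            return self.contact_stiffness
        return np.full(self.n_contact_edges, self.k2)


def _contact_arrays(contacts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (bin_i, bin_j, count) arrays from a ContactTable or graph."""
    if contacts is None:
        z = np.empty(0, dtype=np.int64)
        return z, z, z.astype(float)
    records = getattr(contacts, "records", None)
    if records is not None:  # ContactTable
        return (
            records["bin_i"].to_numpy(np.int64),
            records["bin_j"].to_numpy(np.int64),
            records["count"].to_numpy(float),
        )
    graph = getattr(contacts, "graph", contacts)  # ContactGraph or nx.Graph
    if graph.number_of_edges() == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z.astype(float)
    i, j, w = zip(*((u, v, d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)))
    return np.asarray(i, np.int64), np.asarray(j, np.int64), np.asarray(w, float)


def build_multigraph(
    bins: GenomeBins,
    contacts=None,
    params=None,
    *,
    k1: float | None = None,
    k2: float | None = None,
    L1: float | None = None,
    L2: float | None = None,
    log_weight_stiffness: bool = False,
) -> Multigraph:
    """Fuse genomic adjacency with Hi-C contacts into a multigraph.

    Every bin of ``bins`` is present as a genomic edge even when it carries
    no contact (contact-free regions are part of the pseudo-structure).
    Duplicate and orientation-flipped contact records are merged into a
    single weighted contact edge; self-loop contacts are dropped.

    ``contacts`` may be a :class:`~hicspring.contacts_io.ContactTable`, a
    :class:`~hicspring.graph_analysis.ContactGraph` (or bare networkx graph
    on bin ids), or None.  Spring parameters come from ``params`` (a
    :class:`~hicspring.layout_engine.LayoutParams`) or the keyword overrides;
    rest length of a genomic edge is ``L1`` scaled by the bin's bp length
    relative to the full bin size, contact rest length defaults to ``L1/4``.

    With ``log_weight_stiffness`` the per-edge contact stiffness is scaled by
    ``1 + log(weight)`` instead of being uniform.
    """
    from .layout_engine import LayoutParams  # local import to avoid a cycle

    p = params if params is not None else LayoutParams()
    k1 = p.k1 if k1 is None else k1
    k2 = p.k2 if k2 is None else k2
    L1 = p.L1 if L1 is None else L1
    if L2 is None:
        L2 = p.L2 if params is not None else L1 / 4

    n_bins = bins.n_bins
    offsets = np.concatenate([[0], np.cumsum(bins.bins_per_chrom + 1)[:-1]])

    node_chrom, node_bp, gen_edges, gen_bins = [], [], [], []
    for c in range(bins.n_chrom):
        nb = int(bins.bins_per_chrom[c])
        first_bin = int(bins.chrom_offsets[c])
        starts = bins.bin_start[first_bin : first_bin + nb]
        node_chrom.append(np.full(nb + 1, c, dtype=np.int32))
        node_bp.append(np.concatenate([starts, [bins.chrom_lengths[c]]]))
        base = offsets[c]
        e = np.column_stack([np.arange(base, base + nb), np.arange(base + 1, base + nb + 1)])
        gen_edges.append(e)
        gen_bins.append(np.arange(first_bin, first_bin + nb))
    node_chrom = np.concatenate(node_chrom)
    node_bp = np.concatenate(node_bp)
    gen_edges = np.concatenate(gen_edges)
    gen_bins = np.concatenate(gen_bins)
    bin_bp_len = (bins.bin_end - bins.bin_start).astype(float)
    gen_rest = L1 * bin_bp_len[gen_bins] / bins.bin_size

    bi, bj, cnt = _contact_arrays(contacts)
    if len(bi):
        bad = (bi < 0) | (bi >= n_bins) | (bj < 0) | (bj >= n_bins)
        if bad.any():
            k = int(np.argmax(bad))
            raise ValueError(
                f"contact record ({bi[k]}, {bj[k]}, {cnt[k]:g}) references a bin "
                f"outside the 0..{n_bins - 1} universe"
            )
        loops = bi == bj
        if loops.any():
            warnings.warn(f"dropping {int(loops.sum())} self-loop contact(s)")
            bi, bj, cnt = bi[~loops], bj[~loops], cnt[~loops]
        lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
        key = lo * n_bins + hi
        order = np.argsort(key, kind="stable")
        key, lo, hi, cnt = key[order], lo[order], hi[order], cnt[order]
        uniq, start_idx = np.unique(key, return_index=True)
        weight = np.add.reduceat(cnt, start_idx)
        lo, hi = lo[start_idx], hi[start_idx]
        con_edges = np.column_stack(
            [lo + bins.bin_chrom[lo], hi + bins.bin_chrom[hi]]
        )  # start nodes
    else:
        con_edges = np.empty((0, 2), dtype=np.int64)
        weight = np.empty(0)

    mg = Multigraph(
        bins=bins,
        node_chrom=node_chrom,
        node_bp=node_bp,
        genomic_edges=gen_edges.astype(np.int64),
        genomic_rest=gen_rest,
        genomic_edge_bin=gen_bins.astype(np.int64),
        contact_edges=con_edges,
        contact_weight=weight,
        contact_rest=np.full(len(con_edges), float(L2)),
        k1=float(k1),
        k2=float(k2),
    )
    if log_weight_stiffness and len(weight):
        mg.contact_stiffness = mg.k2 * (1.0 + np.log(weight)) / (1.0 + np.log(weight).max())
    return mg
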