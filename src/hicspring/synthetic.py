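"""Synthetic ground-truth configurations and Hi-C-like contact sampling.

The generators build idealized 3D chromosome arrangements with known
properties so that every pipeline stage — binning, filtering, multigraph
construction, layout, territory and telomere statistics — can be validated
without sequencing data:

* **Rabl-like**: each chromosome is a hairpin with both telomeres near the
  +z pole and the centromere near the -z pole, chromosomes fanned out in
  azimuth (the polarized interphase arrangement of large cereal genomes
  such as barley and wheat).
* **Rosette-like**: pericentromeric regions sit on a small central shell
  and each chromosome loops outward and back (the rice-like arrangement
  around the nucleolus).

Contacts are sampled from bin-pair probabilities decaying exponentially
with 3D distance, the simplest monotone stand-in for proximity ligation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .contacts_io import ContactTable
from .genome_model import DEFAULT_BIN_SIZE, GenomeBins, make_bins

import pandas as pd

__all__ = ["make_rabl", "make_rosette", "sample_contacts", "make_interlocked_rings", "make_parallel_chains"]


def _walk_polyline(waypoints: np.ndarray, n_points: int) -> np.ndarray:
    """``n_points`` positions with exactly equal consecutive (chord)
    spacing, walking along a polyline.

    Each node is placed on the polyline at exact Euclidean distance
    ``total_arc/(n_points-1)`` from the previous node (sphere/segment
    intersection); if corners leave leftover arc at the end, the walk
    extends along the final direction.  Guarantees adjacent-node spacing
    equal to machine precision for any waypoint shape.
    """
    seg = np.diff(waypoints, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    step = float(seglen.sum()) / (n_points - 1)
    pts = [waypoints[0].astype(float)]
    cur = pts[0]
    si, t = 0, 0.0
    for _ in range(n_points - 1):
        found = None
        sj, tj = si, t
        while sj < len(seg):
            a, d = waypoints[sj], seg[sj]
            A = float(d @ d)
            rel = a - cur
            B = 2.0 * float(d @ rel)
            C = float(rel @ rel) - step * step
            disc = B * B - 4.0 * A * C
            if disc >= 0.0 and A > 0.0:
                u = (-B + np.sqrt(disc)) / (2.0 * A)  # forward root
                if tj - 1e-12 <= u <= 1.0 + 1e-12:
                    found = (sj, min(max(u, 0.0), 1.0))
                    break
            sj, tj = sj + 1, 0.0
        if found is None:  # leftover arc: continue straight past the end
            direction = seg[-1] / seglen[-1]
            cur = cur + step * direction
            si, t = len(seg) - 1, 1.0
        else:
            si, t = found
            cur = waypoints[si] + t * seg[si]
        pts.append(cur)
    return np.asarray(pts)


def _cyl(r: float, phi: float, z: float) -> list[float]:
    return [r * np.cos(phi), r * np.sin(phi), z]


def _fit_radius(positions: np.ndarray, R: float) -> np.ndarray:
    """Rescale uniformly so every node lies inside radius R (the equal-chord
    walk can overshoot the last anchor slightly); preserves spacing equality."""
    m = float(np.linalg.norm(positions, axis=1).max())
    return positions * (R / m) if m > R else positions


def _genome(n_chrom: int, bins_per_chrom: int, bin_size: int) -> GenomeBins:
    return make_bins(
        {f"chr{i + 1}": bins_per_chrom * bin_size for i in range(n_chrom)}, bin_size
    )


def make_rabl(
    n_chrom: int,
    bins_per_chrom: int,
    R: float,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> tuple[np.ndarray, GenomeBins]:
    """Rabl-like ground truth: hairpin chromosomes, telomeres at +z pole.

    Returns per-node positions (``n_chrom * (bins_per_chrom + 1)`` boundary
    nodes, ordered chromosome by chromosome) and the matching bin universe.
    Node spacing along each chain is exactly uniform; all nodes lie inside
    radius ``R``.
    """
    if n_chrom < 1 or bins_per_chrom < 4:
        raise ValueError("need n_chrom >= 1 and bins_per_chrom >= 4")
    bins = _genome(n_chrom, bins_per_chrom, bin_size)
    n_nodes = bins_per_chrom + 1
    out = []
    dphi = 2.0 * np.pi / n_chrom
    for c in range(n_chrom):
        phi = c * dphi
        arm = 0.25 * dphi  # azimuthal half-spread of the hairpin
        # telomeres pooled tightly at the +z pole (the Rabl telomere
        # cluster); centromeres fanned out at the -z pole
        t1 = _cyl(0.05 * R, phi - arm, +0.78 * R)
        cen = _cyl(0.50 * R, phi, -0.75 * R)
        t2 = _cyl(0.05 * R, phi + arm, +0.78 * R)
        out.append(_walk_polyline(np.array([t1, cen, t2]), n_nodes))
    return _fit_radius(np.concatenate(out), R), bins


def make_rosette(
    n_chrom: int,
    bins_per_chrom: int,
    R: float,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
    loop_return: float = 0.3,
) -> tuple[np.ndarray, GenomeBins]:
    """Rosette-like ground truth: central pericentromeres, radiating loops.

    Each chromosome starts and ends at radius ``loop_return * R`` near the
    core, loops out to 0.85 R apices, and dips to 0.12 R at the (mid-chain)
    centromere; chromosomes occupy disjoint angular sectors.
    """
    if n_chrom < 1 or bins_per_chrom < 4:
        raise ValueError("need n_chrom >= 1 and bins_per_chrom >= 4")
    bins = _genome(n_chrom, bins_per_chrom, bin_size)
    n_nodes = bins_per_chrom + 1
    out = []
    dphi = 2.0 * np.pi / n_chrom
    for c in range(n_chrom):
        phi = c * dphi
        arm = 0.30 * dphi
        way = np.array(
            [
                _cyl(loop_return * R, phi - arm, +0.10 * R),
                _cyl(0.85 * R, phi - 0.5 * arm, 0.0),
                _cyl(0.08 * R, phi, 0.0),
                _cyl(0.85 * R, phi + 0.5 * arm, 0.0),
                _cyl(loop_return * R, phi + arm, -0.10 * R),
            ]
        )
        out.append(_walk_polyline(way, n_nodes))
    return _fit_radius(np.concatenate(out), R), bins


def _bin_positions(positions: np.ndarray, bins: GenomeBins) -> np.ndarray:
    """Per-bin representative coordinates from per-bin or per-node input."""
    positions = np.asarray(positions, float)
    if len(positions) == bins.n_bins:
        return positions
    if len(positions) == bins.n_bins + bins.n_chrom:
        # boundary nodes: bin midpoint = mean of its two flanking nodes
        start_nodes = np.arange(bins.n_bins) + bins.bin_chrom
        return 0.5 * (positions[start_nodes] + positions[start_nodes + 1])
    raise ValueError(
        f"positions length {len(positions)} matches neither bins ({bins.n_bins}) "
        f"nor boundary nodes ({bins.n_bins + bins.n_chrom})"
    )


def sample_contacts(
    positions: np.ndarray,
    bins: GenomeBins,
    n_contacts: int,
    lam: float,
    seed: int = 0,
    *,
    subsample: float = 1.0,
) -> ContactTable:
    """Sample a Hi-C-like contact table from a known 3D configuration.

    ``n_contacts`` bin pairs are drawn (multinomially) with probability
    proportional to ``exp(-d_ij / lam)`` over all distinct bin pairs, where
    ``d`` is the Euclidean distance between bin representatives; counts are
    aggregated per pair.  No self-loops are produced.  ``subsample`` keeps
    each sampled contact with the given probability (single-cell-like
    sparsity).  Deterministic per ``seed``.
    """
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    if lam <= 0:
        raise ValueError("lambda (decay length) must be positive")
    if bins.n_bins < 2:
        raise ValueError("need at least two bins to form a contact pair")
    coords = _bin_positions(positions, bins)
    d = pdist(coords)
    logw = -d / lam
    w = np.exp(logw - logw.max())
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_contacts, p)
    if subsample < 1.0:
        counts = rng.binomial(counts, subsample)
    nz = np.nonzero(counts)[0]
    iu, ju = np.triu_indices(bins.n_bins, k=1)  # condensed pdist pair order
    return ContactTable(
        bins,
        pd.DataFrame(
            {"bin_i": iu[nz], "bin_j": ju[nz], "count": counts[nz].astype(np.int64)}
        ),
    )


def make_interlocked_rings(
    bins_per_ring: int = 20,
    spacing: float = 1.0,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
):
    """Two Hopf-linked rings of genomic edges, for untangling experiments.

    Each "chromosome" is a closed chain of ``bins_per_ring`` nodes (the
    genomic edges deliberately form cycles rather than paths: the fixture
    emulates topologically entangled chromatids, which no contact data can
    produce through :func:`~hicspring.genome_model.build_multigraph`).
    Ring A lies in the xy-plane about the origin; ring B in the xz-plane,
    centred on A's rim, threading through it.  Every edge starts exactly at
    its rest length ``spacing``.  Returns ``(multigraph, positions)``.
    """
    from .genome_model import Multigraph

    n = int(bins_per_ring)
    if n < 6:
        raise ValueError("need at least 6 bins per ring")
    r = spacing / (2.0 * np.sin(np.pi / n))
    th = 2.0 * np.pi * np.arange(n) / n
    ring_a = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
    ring_b = np.column_stack([r + r * np.cos(th), np.zeros(n), r * np.sin(th)])
    positions = np.vstack([ring_a, ring_b])
    bins = make_bins({"ringA": n * bin_size, "ringB": n * bin_size}, bin_size)
    edges = np.array(
        [(base + k, base + (k + 1) % n) for base in (0, n) for k in range(n)],
        dtype=np.int64,
    )
    mg = Multigraph(
        bins=bins,
        node_chrom=np.repeat([0, 1], n).astype(np.int32),
        node_bp=np.tile(np.arange(n) * bin_size, 2).astype(np.int64),
        genomic_edges=edges,
        genomic_rest=np.full(2 * n, float(spacing)),
        genomic_edge_bin=np.arange(2 * n, dtype=np.int64),
        contact_edges=np.empty((0, 2), dtype=np.int64),
        contact_weight=np.empty(0),
        contact_rest=np.empty(0),
    )
    return mg, positions


def make_parallel_chains(
    bins_per_chain: int = 20,
    spacing: float = 1.0,
    offset: float = 2.0,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
):
    """Two straight, unlinked chains side by side (separable control for
    the untangling experiment).  Returns ``(multigraph, positions)``."""
    from .genome_model import build_multigraph

    n = int(bins_per_chain)
    bins = make_bins({"chainA": n * bin_size, "chainB": n * bin_size}, bin_size)
    mg = build_multigraph(bins, L1=spacing)
    y = np.arange(n + 1) * spacing
    a = np.column_stack([np.zeros(n + 1), y, np.zeros(n + 1)])
    b = a + np.array([0.0, 0.0, offset])
    return mg, np.vstack([a, b])
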