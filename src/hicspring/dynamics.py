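"""Condensation and untangling dynamics.

A "simulated metaphase" shortens every genomic rest length (condensed
state), switches contact springs off, and drags each chromosome toward one
of two poles.  Topologically entangled conformations (e.g. interlocked
rings) get locked up — non-adjacent segments from different chromosomes
stay pressed together — unless genomic edges are allowed to break when
over-stretched, which lets the chains slip free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import Multigraph
from .layout_engine import (
    LayoutParams,
    LayoutState,
    compute_forces,
    run_layout,
    segment_min_distances,
    step,
)

__all__ = ["condense", "break_overstretched", "untangle_experiment", "UntangleReport"]


def condense(mg: Multigraph, factor: float) -> Multigraph:
    """Condensed copy: genomic rest lengths scaled by ``factor`` in (0, 1],
    all contact edges removed.  The input multigraph is untouched."""
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"condensation factor must be in (0, 1], got {factor}")
    out = mg.copy()
    out.genomic_rest = out.genomic_rest * factor
    out.contact_edges = np.empty((0, 2), dtype=np.int64)
    out.contact_weight = np.empty(0)
    out.contact_rest = np.empty(0)
    out.contact_stiffness = None
    return out


def break_overstretched(
    state: LayoutState,
    mg: Multigraph,
    beta: float,
    *,
    criterion: str = "ratio",
) -> tuple[Multigraph, list[tuple[str, int]]]:
    """Remove genomic edges stretched beyond ``beta`` times their rest length.

    Returns a copy of the multigraph without the broken edges, plus the
    broken-edge list as ``(chromosome name, global bin index)`` records.
    ``beta = inf`` is the identity.  Node count is never altered.

    The default ``"ratio"`` criterion (extension ratio > beta) is
    unit-independent; ``criterion="force"`` breaks edges whose spring
    tension ``k1 (length - rest)`` exceeds ``beta`` instead.
    """
    if criterion == "ratio" and beta <= 1.0:
        raise ValueError("beta must exceed 1")
    if criterion not in ("ratio", "force"):
        raise ValueError(f"criterion must be 'ratio' or 'force', got {criterion!r}")
    out = mg.copy()
    if mg.n_genomic_edges == 0:
        return out, []
    pos = state.positions
    length = np.linalg.norm(pos[mg.genomic_edges[:, 1]] - pos[mg.genomic_edges[:, 0]], axis=1)
    if criterion == "force":
        broken_mask = mg.k1 * (length - mg.genomic_rest) > beta
    else:
        broken_mask = length / mg.genomic_rest > beta
    broken = [
        (mg.bins.chrom_names[mg.bins.bin_chrom[b]], int(b))
        for b in mg.genomic_edge_bin[broken_mask]
    ]
    out.genomic_edges = mg.genomic_edges[~broken_mask]
    out.genomic_rest = mg.genomic_rest[~broken_mask]
    out.genomic_edge_bin = mg.genomic_edge_bin[~broken_mask]
    return out, broken


@dataclass
class UntangleReport:
    """Outcome of a simulated-metaphase untangling run."""

    centroid_distance: float  # mean pairwise chromosome-centroid distance
    residual_close_pairs: int  # inter-chromosome segment pairs closer than d_min
    n_breaks: int
    broken: list = field(default_factory=list)
    iterations: int = 0
    separated: bool = False  # no residual inter-chromosome close pairs


def _interchrom_close_pairs(positions: np.ndarray, mg: Multigraph, d_min: float) -> int:
    """Count genomic segment pairs from different chromosomes closer than d_min."""
    edges = mg.genomic_edges
    if len(edges) < 2:
        return 0
    chrom = mg.node_chrom[edges[:, 0]]
    i, j = np.triu_indices(len(edges), k=1)
    diff = chrom[i] != chrom[j]
    i, j = i[diff], j[diff]
    if len(i) == 0:
        return 0
    p = positions
    d, _, _ = segment_min_distances(
        p[edges[i, 0]], p[edges[i, 1]], p[edges[j, 0]], p[edges[j, 1]]
    )
    return int((d < d_min).sum())


def untangle_experiment(
    mg: Multigraph,
    params: LayoutParams | None = None,
    *,
    breaking: bool = False,
    beta: float = 2.5,
    factor: float = 0.5,
    positions: np.ndarray | None = None,
    f_pole: float = 0.5,
    n_iter: int | None = None,
    warmup: int = 100,
) -> UntangleReport:
    """Condense, pull chromosomes to opposite poles, optionally break edges.

    The multigraph is condensed by ``factor`` (contacts off) and every node
    is pulled with constant force ``f_pole`` toward one of two poles at
    ``(+-R/2, 0, 0)``, chromosomes assigned alternately.  When ``breaking``
    is on, edges stretched beyond ``beta`` are removed each iteration once
    the ``warmup`` phase (which lets condensation complete — immediately
    after condensation every edge sits at ratio ``1/factor``) has passed.

    ``positions`` provides the starting conformation; if omitted, an
    interphase layout of ``mg`` is computed first (same seed).  Deterministic
    per (inputs, params.seed).
    """
    params = params or LayoutParams()
    params.validate()
    if positions is None:
        positions = run_layout(mg, params).positions
    mgc = condense(mg, factor)
    R = params.resolve_radius(mg)
    poles = np.array([[+R / 2.0, 0.0, 0.0], [-R / 2.0, 0.0, 0.0]])
    node_pole = poles[mgc.node_chrom % 2]

    state = LayoutState(positions=np.array(positions, float), velocities=np.zeros_like(positions, dtype=float))
    n_iter = n_iter if n_iter is not None else params.max_iter
    broken_all: list[tuple[str, int]] = []
    for it in range(n_iter):
        to_pole = node_pole - state.positions
        dist = np.linalg.norm(to_pole, axis=1)
        pull = np.zeros_like(to_pole)
        far = dist > 1e-6
        pull[far] = f_pole * to_pole[far] / dist[far, None]
        step(state, mgc, params, extra_forces=pull)
        if breaking and it >= warmup:
            mgc, broken = break_overstretched(state, mgc, beta)
            broken_all.extend(broken)

    centroids = np.array(
        [state.positions[mgc.node_chrom == c].mean(axis=0) for c in range(mg.bins.n_chrom)]
    )
    if len(centroids) > 1:
        i, j = np.triu_indices(len(centroids), k=1)
        cdistm = float(np.linalg.norm(centroids[i] - centroids[j], axis=1).mean())
    else:
        cdistm = 0.0
    residual = _interchrom_close_pairs(state.positions, mgc, params.d_min)
    return UntangleReport(
        centroid_distance=cdistm,
        residual_close_pairs=residual,
        n_breaks=len(broken_all),
        broken=broken_all,
        iterations=n_iter,
        separated=residual == 0,
    )
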