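"""Quantitative analysis of pseudo-structures.

Chromosome territories are tested with the chromosome-level mean-distance
matrix: from the all-node distance matrix, entry (i, j) averages the
distances between nodes of chromosome i and chromosome j (diagonal over
distinct node pairs only).  If every diagonal entry is strictly the row
minimum, each chromosome's nodes are closest to their own chromosome —
distinct territories.  A telomere-clustering score compares distal-region
node spread to the overall spread, distinguishing Rabl-like (ends pooled
at a pole, score < 1) from Rosette-like arrangements.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .genome_model import Multigraph
from .layout_engine import LayoutState

__all__ = [
    "TerritoryMatrix",
    "territory_matrix",
    "is_territorial",
    "telomere_clustering",
    "overlay_annotation",
    "export_structure",
    "load_structure_json",
    "plot_territory_matrix",
]


@dataclass
class TerritoryMatrix:
    """Chromosome-level mean-distance matrix (symmetric, non-negative)."""

    matrix: pd.DataFrame  # chromosomes x chromosomes
    undefined: tuple[str, ...] = ()  # chromosomes with <2 nodes (NaN diagonal)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.matrix.index)


def territory_matrix(state: LayoutState, mg: Multigraph) -> TerritoryMatrix:
    """Mean Euclidean distance between node sets of chromosome pairs.

    Diagonal entries average over distinct node pairs only; a chromosome
    with fewer than two nodes gets a NaN diagonal and is flagged.
    """
    pos = state.positions
    names = mg.bins.chrom_names
    nc = len(names)
    M = np.zeros((nc, nc))
    undefined = []
    groups = [pos[mg.node_chrom == c] for c in range(nc)]
    for i in range(nc):
        ni = len(groups[i])
        if ni < 2:
            M[i, i] = np.nan
            undefined.append(names[i])
        else:
            M[i, i] = pdist(groups[i]).mean()
        for j in range(i + 1, nc):
            M[i, j] = M[j, i] = cdist(groups[i], groups[j]).mean()
    df = pd.DataFrame(M, index=list(names), columns=list(names))
    return TerritoryMatrix(df, tuple(undefined))


def is_territorial(tm: TerritoryMatrix) -> tuple[bool, dict[str, object]]:
    """Diagonal-minimum territory test.

    Returns the overall verdict and per-chromosome verdicts: True when the
    chromosome's self-distance is strictly the smallest entry of its row
    (ties fail), ``"indeterminate"`` when the diagonal is undefined.
    """
    M = tm.matrix.to_numpy()
    verdicts: dict[str, object] = {}
    for i, name in enumerate(tm.matrix.index):
        diag = M[i, i]
        if np.isnan(diag):
            verdicts[name] = "indeterminate"
            continue
        off = np.delete(M[i], i)
        verdicts[name] = bool(len(off) == 0 or diag < np.nanmin(off))
    overall = all(v is True for v in verdicts.values())
    return overall, verdicts


def _distal_node_mask(mg: Multigraph, end_fraction: float) -> np.ndarray:
    """Mark nodes in the distal (telomere-proximal) region of each chromosome."""
    if not 0.0 < end_fraction < 0.5:
        raise ValueError("end_fraction must be in (0, 0.5)")
    mask = np.zeros(mg.n_nodes, dtype=bool)
    offsets = mg.node_offsets()
    per_chrom = mg.bins.bins_per_chrom + 1
    for c in range(mg.bins.n_chrom):
        n = int(per_chrom[c])
        k = max(1, int(round(end_fraction * n)))
        base = int(offsets[c])
        mask[base : base + k] = True
        mask[base + n - k : base + n] = True
    return mask


def telomere_clustering(state: LayoutState, mg: Multigraph, end_fraction: float = 0.1) -> float:
    """Distal-node spread relative to overall spread.

    ``score = mean pairwise distance among distal nodes of all chromosomes
    / mean pairwise distance among all nodes``.  Scores below 1 indicate
    telomere clustering; the statistic is scale- and rigid-motion
    invariant.  Degenerate geometries (all nodes coincident) return 1.
    """
    pos = state.positions
    mask = _distal_node_mask(mg, end_fraction)
    overall = pdist(pos).mean() if len(pos) > 1 else 0.0
    if overall <= 0:
        return 1.0
    distal = pos[mask]
    if len(distal) < 2:
        return 1.0
    return float(pdist(distal).mean() / overall)


def overlay_annotation(mg: Multigraph, table) -> np.ndarray:
    """Attach per-bin scalar values to bin start nodes.

    ``table`` may be a mapping keyed by global bin index or ``(chrom,
    start_bp)``, or a DataFrame with columns ``(bin, value)`` or ``(chrom,
    start, value)``.  Returns a per-node float array with NaN as the
    "no-data" sentinel.  Unknown bins are skipped with a warning; duplicate
    keys keep the last value (with a warning).
    """
    bins = mg.bins
    values = np.full(mg.n_nodes, np.nan)

    if isinstance(table, pd.DataFrame):
        if {"chrom", "start", "value"} <= set(table.columns):
            items = [((r.chrom, int(r.start)), r.value) for r in table.itertuples()]
        elif {"bin", "value"} <= set(table.columns):
            items = [(int(r.bin), r.value) for r in table.itertuples()]
        else:
            raise ValueError("annotation DataFrame needs (bin, value) or (chrom, start, value) columns")
    else:
        items = list(table.items())

    seen: set = set()
    for key, val in items:
        if isinstance(key, tuple):
            chrom, start = key
            try:
                b = bins.bin_index(str(chrom), int(start))
            except (KeyError, ValueError) as exc:
                warnings.warn(f"annotation key {key!r} skipped: {exc}")
                continue
        else:
            b = int(key)
            if b < 0 or b >= bins.n_bins:
                warnings.warn(f"annotation bin {b} outside universe; skipped")
                continue
        if b in seen:
            warnings.warn(f"duplicate annotation for bin {b}; last value wins")
        seen.add(b)
        values[int(mg.start_node(b))] = float(val)
    return values


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def export_structure(state: LayoutState, mg: Multigraph, path, format: str = "xyz", annotations=None) -> None:
    """Write the pseudo-structure to disk.

    ``xyz``: per-node TSV (chrom, bp, x, y, z) with one header line.
    ``pdb``: one pseudo-atom per node, one chain per chromosome (max 62),
    consecutive nodes CONECTed, coordinates rescaled into the fixed-width
    columns.  ``json``: full model — nodes, both edge classes, annotations —
    with exact round-trip of coordinates.
    """
    pos = state.positions
    bins = mg.bins
    if format == "xyz":
        with open(path, "w") as fh:
            fh.write("chrom\tbp\tx\ty\tz\n")
            for v in range(mg.n_nodes):
                x, y, z = (float(w) for w in pos[v])
                fh.write(
                    f"{bins.chrom_names[mg.node_chrom[v]]}\t{int(mg.node_bp[v])}\t"
                    f"{x!r}\t{y!r}\t{z!r}\n"
                )
    elif format == "pdb":
        if bins.n_chrom > len(_CHAIN_IDS):
            raise ValueError(
                f"{bins.n_chrom} chromosomes exceed the {len(_CHAIN_IDS)} PDB chain ids; "
                "use the json format instead"
            )
        max_abs = float(np.abs(pos).max()) or 1.0
        scaled = pos * (99.0 / max_abs)  # fit the %8.3f coordinate columns
        with open(path, "w") as fh:
            for v in range(mg.n_nodes):
                x, y, z = scaled[v]
                chain = _CHAIN_IDS[int(mg.node_chrom[v])]
                serial = v + 1
                resseq = (v % 9999) + 1
                fh.write(
                    f"ATOM  {serial:>5d}  CA  BIN {chain}{resseq:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            for a, b in mg.genomic_edges:
                fh.write(f"CONECT{a + 1:>5d}{b + 1:>5d}\n")
            fh.write("END\n")
    elif format == "json":
        ann = None if annotations is None else [None if np.isnan(v) else float(v) for v in annotations]
        doc = {
            "bin_size": bins.bin_size,
            "chromosomes": [
                {"name": n, "length": int(l)} for n, l in zip(bins.chrom_names, bins.chrom_lengths)
            ],
            "nodes": [
                {
                    "chrom": bins.chrom_names[mg.node_chrom[v]],
                    "bp": int(mg.node_bp[v]),
                    "x": float(pos[v, 0]),
                    "y": float(pos[v, 1]),
                    "z": float(pos[v, 2]),
                }
                for v in range(mg.n_nodes)
            ],
            "genomic_edges": [[int(a), int(b)] for a, b in mg.genomic_edges],
            "contact_edges": [
                {"a": int(a), "b": int(b), "weight": float(w)}
                for (a, b), w in zip(mg.contact_edges, mg.contact_weight)
            ],
            "annotations": ann,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown structure format {format!r}")


def load_structure_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_territory_matrix(tm: TerritoryMatrix, ax=None):
    """Heatmap of the territory matrix, shaded row-wise so that white marks
    each row's minimum (the display convention for territory figures)."""
    import matplotlib.pyplot as plt

    M = tm.matrix.to_numpy(float).copy()
    shade = np.empty_like(M)
    for i in range(len(M)):
        row = M[i]
        lo, hi = np.nanmin(row), np.nanmax(row)
        shade[i] = (row - lo) / (hi - lo) if hi > lo else 0.0
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(shade, cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(tm.chromosomes)), tm.chromosomes, rotation=90)
    ax.set_yticks(range(len(tm.chromosomes)), tm.chromosomes)
    ax.set_title("mean inter-node distance (white = row minimum)")
    return ax
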