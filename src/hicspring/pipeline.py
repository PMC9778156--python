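"""End-to-end convenience: synthetic genome -> contacts -> filter ->
multigraph -> 3D layout -> structure statistics.

This is the "full circle" used throughout validation: contacts are sampled
from a known Rabl- or Rosette-like configuration, pushed through the same
filtering and layout machinery that real contact lists would use, and the
recovered pseudo-structure is scored for territories and telomere
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .contacts_io import (
    ContactTable,
    contact_distribution,
    filter_strong,
    percentile_to_threshold,
)
from .genome_model import Multigraph, build_multigraph
from .layout_engine import LayoutParams, LayoutState, run_layout
from .structure_analysis import is_territorial, telomere_clustering, territory_matrix
from .synthetic import make_rabl, make_rosette, sample_contacts

__all__ = ["FullCircleResult", "full_circle", "filter_at_percentile"]

#: pipeline default percentile order for the strong-interaction filter.
#: Synthetic per-bin totals are near-homogeneous (the geometry has no
#: mappability or coverage tail), so only the weakest decile is trimmed;
#: heavy-tailed experimental libraries warrant orders near 0.5.
DEFAULT_PERCENTILE_ORDER = 0.1


def filter_at_percentile(table: ContactTable, order: float = DEFAULT_PERCENTILE_ORDER) -> tuple[ContactTable, int]:
    """Strong-interaction filter at a percentile order; returns (table, threshold)."""
    dist = contact_distribution(table, "all")
    thr = percentile_to_threshold(dist, order)
    return filter_strong(table, dist, thr), thr


@dataclass
class FullCircleResult:
    mode: str
    table: ContactTable
    threshold: int
    multigraph: Multigraph
    state: LayoutState
    territorial: bool
    verdicts: dict
    telomere_score: float


def full_circle(
    mode: str = "rabl",
    n_chrom: int = 3,
    bins_per_chrom: int = 50,
    n_contacts: int = 50_000,
    *,
    R_truth: float = 17.0,
    lam: float = 0.8,
    seed: int = 0,
    percentile_order: float = DEFAULT_PERCENTILE_ORDER,
    params: LayoutParams | None = None,
) -> FullCircleResult:
    """Sample contacts from a known configuration and recover a structure.

    ``R_truth`` is the ground-truth nucleus radius (sized so that adjacent
    node spacing is about one layout unit for 50-bin chromosomes);
    ``lam`` the contact decay length in the same units.  The layout seed
    follows ``seed`` unless ``params`` overrides it.
    """
    maker = {"rabl": make_rabl, "rosette": make_rosette}.get(mode)
    if maker is None:
        raise ValueError(f"mode must be 'rabl' or 'rosette', got {mode!r}")
    truth, bins = maker(n_chrom, bins_per_chrom, R_truth)
    table = sample_contacts(truth, bins, n_contacts, lam, seed=seed)
    filtered, thr = filter_at_percentile(table, percentile_order)
    if params is None:
        params = LayoutParams(seed=seed, max_iter=1500)
    mg = build_multigraph(bins, filtered, params)
    state = run_layout(mg, params)
    tm = territory_matrix(state, mg)
    territorial, verdicts = is_territorial(tm)
    score = telomere_clustering(state, mg)
    return FullCircleResult(mode, filtered, thr, mg, state, territorial, verdicts, score)
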