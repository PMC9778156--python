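"""Contact-list parsing, binning and percentile-based strong-interaction filtering.

Raw contact lists (5-column TSV or BEDPE) are mapped onto genome bins and
canonicalised into an upper-triangular table of ``(bin_i, bin_j, count)``
records.  The per-bin total contact count distribution drives the filter:
a count threshold is expressed as an empirical-percentile order over
contact-bearing bins, and only records whose two endpoint bins both reach
the threshold are kept ("strong interactions").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genome_model import GenomeBins

__all__ = [
    "ContactTable",
    "CountDistribution",
    "read_contacts",
    "write_contacts",
    "contact_distribution",
    "threshold_to_percentile",
    "percentile_to_threshold",
    "filter_strong",
    "filter_strong_edges",
]

Scope = Literal["intra", "inter", "all"]


class ContactParseError(ValueError):
    """Raised for malformed or inconsistent contact records, with line numbers."""


@dataclass
class ContactTable:
    """Canonical sparse contact list over a bin universe.

    ``records`` has columns ``bin_i``, ``bin_j``, ``count`` with
    ``bin_i <= bin_j``, no duplicates, sorted by ``(bin_i, bin_j)``; the
    derived boolean column ``intra`` flags same-chromosome records.
    """

    bins: GenomeBins
    records: pd.DataFrame

    def __post_init__(self):
        self.records = canonicalize(self.bins, self.records)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def total_count(self) -> float:
        return float(self.records["count"].sum())

    def scoped(self, scope: Scope = "all") -> pd.DataFrame:
        if scope == "all":
            return self.records
        if scope == "intra":
            return self.records[self.records["intra"]]
        if scope == "inter":
            return self.records[~self.records["intra"]]
        raise ValueError(f"scope must be intra/inter/all, got {scope!r}")

    def drop_self_loops(self) -> "ContactTable":
        rec = self.records[self.records["bin_i"] != self.records["bin_j"]]
        return ContactTable(self.bins, rec.reset_index(drop=True))


def canonicalize(bins: GenomeBins, records: pd.DataFrame) -> pd.DataFrame:
    """Order endpoints, merge duplicates, sort, and flag intra records."""
    if len(records) == 0:
        return pd.DataFrame(
            {"bin_i": pd.Series(dtype=np.int64), "bin_j": pd.Series(dtype=np.int64),
             "count": pd.Series(dtype=np.int64), "intra": pd.Series(dtype=bool)}
        )
    i = records["bin_i"].to_numpy(np.int64)
    j = records["bin_j"].to_numpy(np.int64)
    c = records["count"].to_numpy()
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    df = (
        pd.DataFrame({"bin_i": lo, "bin_j": hi, "count": c})
        .groupby(["bin_i", "bin_j"], as_index=False, sort=True)["count"]
        .sum()
    )
    df["intra"] = bins.same_chrom(df["bin_i"].to_numpy(), df["bin_j"].to_numpy())
    return df


def read_contacts(
    path,
    bins: GenomeBins,
    format: Literal["tsv5", "bedpe"] = "tsv5",
    *,
    drop_self_loops: bool = True,
) -> ContactTable:
    """Read a contact list and bin it.

    ``tsv5``: ``chrom1 pos1 chrom2 pos2 [count]`` (count defaults to 1).
    ``bedpe``: first six BEDPE columns; the midpoint of each interval is the
    contact position.  Malformed lines, unknown chromosomes and out-of-range
    positions raise :class:`ContactParseError` naming the offending line.
    Intra-bin contacts (self-loops) are discarded by default.
    """
    path = Path(path)
    c1, p1, c2, p2, cnt, errors = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "tsv5":
                    if len(parts) < 4:
                        raise ValueError("expected >=4 columns")
                    a_chrom, a_pos = parts[0], int(parts[1])
                    b_chrom, b_pos = parts[2], int(parts[3])
                    n = int(parts[4]) if len(parts) >= 5 else 1
                elif format == "bedpe":
                    if len(parts) < 6:
                        raise ValueError("expected >=6 BEDPE columns")
                    a_chrom = parts[0]
                    a_pos = (int(parts[1]) + int(parts[2])) // 2
                    b_chrom = parts[3]
                    b_pos = (int(parts[4]) + int(parts[5])) // 2
                    n = 1
                else:
                    raise ValueError(f"unknown format {format!r}")
                if n <= 0:
                    raise ValueError(f"non-positive count {n}")
                for ch, pos in ((a_chrom, a_pos), (b_chrom, b_pos)):
                    if ch not in bins.chrom_names:
                        raise ValueError(f"unknown chromosome {ch!r}")
                    if pos < 0 or pos >= bins.chrom_lengths[bins.chrom_index(ch)]:
                        raise ValueError(f"position {pos} outside chromosome {ch!r}")
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc} :: {line[:120]}")
                continue
            c1.append(a_chrom); p1.append(a_pos); c2.append(b_chrom); p2.append(b_pos); cnt.append(n)
    if errors:
        raise ContactParseError(
            f"{len(errors)} bad record(s) in {path.name}:\n" + "\n".join(errors[:20])
        )
    bi = [bins.bin_index(ch, pos) for ch, pos in zip(c1, p1)]
    bj = [bins.bin_index(ch, pos) for ch, pos in zip(c2, p2)]
    table = ContactTable(
        bins,
        pd.DataFrame({"bin_i": np.asarray(bi, np.int64), "bin_j": np.asarray(bj, np.int64), "count": cnt}),
    )
    return table.drop_self_loops() if drop_self_loops else table


def write_contacts(table: ContactTable, path) -> None:
    """Write a canonical table as tsv5, using each bin's start coordinate."""
    b = table.bins
    rec = table.records
    with open(path, "w") as fh:
        for i, j, c in zip(rec["bin_i"], rec["bin_j"], rec["count"]):
            fh.write(
                f"{b.chrom_names[b.bin_chrom[i]]}\t{b.bin_start[i]}\t"
                f"{b.chrom_names[b.bin_chrom[j]]}\t{b.bin_start[j]}\t{c}\n"
            )


@dataclass
class CountDistribution:
    """Per-bin total contact counts over contact-bearing bins."""

    totals: pd.Series  # index: global bin id, value: total count
    scope: str = "all"

    @property
    def histogram(self) -> dict[int, int]:
        """count value -> number of bins with that total."""
        return self.totals.value_counts().sort_index().to_dict()

    @property
    def n_bins(self) -> int:
        return len(self.totals)


def contact_distribution(table: ContactTable, scope: Scope = "all") -> CountDistribution:
    """Total contacts per bin (both endpoints of each record count)."""
    rec = table.scoped(scope)
    if len(rec) == 0:
        warnings.warn(f"no records in scope {scope!r}; empty distribution")
        return CountDistribution(pd.Series(dtype=np.int64), scope)
    ends = np.concatenate([rec["bin_i"].to_numpy(), rec["bin_j"].to_numpy()])
    cnts = np.concatenate([rec["count"].to_numpy(), rec["count"].to_numpy()])
    totals = pd.Series(cnts).groupby(ends).sum().sort_index()
    totals.index.name = "bin"
    return CountDistribution(totals, scope)


def threshold_to_percentile(dist: CountDistribution, threshold: float) -> float:
    """Empirical-CDF order of a count threshold.

    Returns ``(#bins with total < threshold) / (#bins with >=1 contact)``,
    the convention under which a published cutoff can be quoted as a
    percentile order (e.g. 0.512 / 0.524 for the barley 85-count cutoff).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if dist.n_bins == 0:
        return 0.0
    return float((dist.totals.to_numpy() < threshold).sum() / dist.n_bins)


def percentile_to_threshold(dist: CountDistribution, order: float) -> int:
    """Smallest observed total whose empirical-CDF order is >= ``order``."""
    if not 0.0 <= order <= 1.0:
        raise ValueError("order must be in [0, 1]")
    if dist.n_bins == 0:
        return 0
    totals = np.sort(dist.totals.to_numpy())
    k = int(np.ceil(order * len(totals)))
    return int(totals[min(k, len(totals) - 1)])


def filter_strong(
    table: ContactTable,
    dist: CountDistribution,
    threshold: float,
    *,
    inclusive: bool = True,
) -> ContactTable:
    """Keep records whose two endpoint bins both reach the count threshold.

    ``inclusive`` keeps bins with total equal to the threshold (the
    "this value or higher" rule); set False for a strict ``>`` cutoff.
    """
    rec = table.records
    if len(rec) == 0:
        return table
    totals = dist.totals.reindex(
        np.union1d(rec["bin_i"].unique(), rec["bin_j"].unique()), fill_value=0
    )
    ti = totals.loc[rec["bin_i"]].to_numpy()
    tj = totals.loc[rec["bin_j"]].to_numpy()
    keep = (ti >= threshold) & (tj >= threshold) if inclusive else (ti > threshold) & (tj > threshold)
    return ContactTable(table.bins, rec[keep].reset_index(drop=True))


def filter_strong_edges(table: ContactTable, threshold: float, *, inclusive: bool = True) -> ContactTable:
    """Alternative reading of the cutoff: filter on per-record counts."""
    rec = table.records
    keep = rec["count"] >= threshold if inclusive else rec["count"] > threshold
    return ContactTable(table.bins, rec[keep].reset_index(drop=True))
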