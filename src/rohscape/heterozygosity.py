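"""Depth-matched heterozygosity rates in SNPs/Mb.

The heterozygosity rate of a region is the number of heterozygous sites
falling in callable positions divided by the number of callable positions,
scaled to a million bases — numerator and denominator pass the same depth
and quality filters.  The module also builds the fixed non-overlapping
window table used by the ROH and enrichment stages, runs the minimum-depth
sensitivity sweep, and computes per-gene-set rates with their excess ratio
over a reference rate.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._intervals import (count_points_in, intersect, merge_intervals,
                         total_length)
from .variant_io import (CallabilityTrack, DepthTrack, FilterPolicy,
                         build_callability, filter_genotypes)

MB = 1_000_000

WINDOW_SIZE_DEFAULT = 100_000


@dataclass(frozen=True)
class HetRate:
    """A heterozygosity rate with its numerator and denominator."""

    n_het_sites: int
    n_callable_sites: int

    @property
    def rate_snps_per_mb(self) -> float:
        return self.n_het_sites * MB / self.n_callable_sites

    def rounded(self) -> float:
        """Rate at reporting precision: integer above 100 SNPs/Mb, one decimal below."""
        r = self.rate_snps_per_mb
        return float(round(r)) if r >= 100 else round(r, 1)


def het_sites(records: pd.DataFrame) -> pd.DataFrame:
    """The heterozygous subset of a (filtered) variant table, 0-based positions."""
    h = records[records["genotype_class"] == "het"]
    return pd.DataFrame({"scaffold": h["scaffold"].to_numpy(),
                         "pos": h["pos"].to_numpy() - 1})


def genome_het_rate(het: pd.DataFrame, callability: CallabilityTrack) -> HetRate:
    """Genome-wide rate: het sites inside callable intervals / callable sites."""
    n_callable = callability.total_callable()
    if n_callable == 0:
        raise ValueError("zero callable sites")
    n_het = count_points_in(het, callability.intervals)
    return HetRate(n_het, n_callable)


def depth_sweep(records: pd.DataFrame, track: DepthTrack, policy: FilterPolicy,
                mean_depth: float, scaffold_table: pd.DataFrame,
                min_depths=range(4, 21, 2)) -> pd.DataFrame:
    """Heterozygosity rate as a function of the minimum depth of coverage.

    For each minimum depth the variant filters and the callability
    denominator are rebuilt with that floor (the 2x-mean ceiling is held
    fixed); the callable count is non-increasing in the floor.
    """
    rows = []
    for md in min_depths:
        pol = replace(policy, min_depth=int(md))
        call = build_callability(track, pol, mean_depth, scaffold_table)
        filt = filter_genotypes(records, pol, mean_depth)
        h = het_sites(filt)
        n_callable = call.total_callable()
        n_het = count_points_in(h, call.intervals) if n_callable else 0
        rate = n_het * MB / n_callable if n_callable else np.nan
        rows.append((int(md), n_het, n_callable, rate))
    return pd.DataFrame(rows, columns=["min_depth", "n_het", "n_callable",
                                       "rate_snps_per_mb"])


def window_het_counts(het: pd.DataFrame, scaffold_table: pd.DataFrame,
                      window_size: int = WINDOW_SIZE_DEFAULT,
                      callability: CallabilityTrack | None = None
                      ) -> pd.DataFrame:
    """Heterozygous-site counts in fixed non-overlapping windows.

    Windows tile each scaffold from coordinate 0; the partial remainder at
    the scaffold end is excluded.  If a callability track is given, a
    ``callable_fraction`` column reports the callable share of each window
    (the labelling itself imposes no callable-fraction requirement).
    """
    parts = []
    call_by_scaf = (dict(tuple(callability.intervals.groupby("scaffold")))
                    if callability is not None else None)
    het_by_scaf = dict(tuple(het.groupby("scaffold"))) if len(het) else {}
    for row in scaffold_table.itertuples(index=False):
        n_win = row.length // window_size
        if n_win == 0:
            continue
        starts = np.arange(n_win, dtype=np.int64) * window_size
        counts = np.zeros(n_win, dtype=np.int64)
        if row.scaffold in het_by_scaf:
            pos = het_by_scaf[row.scaffold]["pos"].to_numpy()
            pos = pos[pos < n_win * window_size]
            counts = np.bincount(pos // window_size, minlength=n_win)
        part = pd.DataFrame({"scaffold": row.scaffold, "start": starts,
                             "end": starts + window_size,
                             "het_count": counts})
        if call_by_scaf is not None:
            part["callable_fraction"] = _window_callable_fraction(
                call_by_scaf.get(row.scaffold), starts, window_size)
        parts.append(part)
    if not parts:
        cols = ["scaffold", "start", "end", "het_count"]
        if callability is not None:
            cols.append("callable_fraction")
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)


def _window_callable_fraction(call_df, starts, window_size):
    if call_df is None or len(call_df) == 0:
        return np.zeros(len(starts))
    cs = call_df["start"].to_numpy()
    ce = call_df["end"].to_numpy()
    # cumulative callable bp before position x
    cum = np.concatenate([[0], np.cumsum(ce - cs)])

    def callable_before(x):
        i = np.searchsorted(cs, x, side="right")
        extra = np.clip(x - cs[i - 1], 0, ce[i - 1] - cs[i - 1]) if i > 0 else 0
        return cum[i - 1] + extra if i > 0 else 0

    vals = np.array([callable_before(s + window_size) - callable_before(s)
                     for s in starts], dtype=float)
    return vals / window_size


def gene_set_het(het: pd.DataFrame, exons: pd.DataFrame,
                 callability: CallabilityTrack,
                 reference_rate: float | None = None,
                 name: str = "gene_set") -> tuple[HetRate, float | None]:
    """Heterozygosity of a gene set's exons, with excess over a reference.

    The numerator counts het sites inside exon positions that are callable;
    the denominator is the callable portion of the (merged) exon intervals.
    ``reference_rate`` is an explicit caller-chosen baseline (for example
    the genome-wide rate); the excess ratio is gene-set rate / reference.
    """
    merged = merge_intervals(exons[["scaffold", "start", "end"]])
    callable_exons = intersect(merged, callability.intervals)
    denom = total_length(callable_exons)
    if denom == 0:
        raise ValueError(f"gene set {name!r}: zero callable exon positions")
    n_het = count_points_in(het, callable_exons)
    rate = HetRate(n_het, denom)
    excess = (rate.rate_snps_per_mb / reference_rate
              if reference_rate else None)
    return rate, excess
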