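"""Runs of homozygosity: window labelling, a scanning-window caller,
run merging, the length spectrum and cross-method comparison.

Two callers are implemented.  The window method labels each complete
100-kb window ROH iff it contains no heterozygous site; the genomic
inbreeding coefficient F_ROH is the labelled share of windows.  The scan
method ("scan50") is a deliberately simplified emulation of the classic
site-window scan: a called site supports ROH iff at least one 50-site
window covering it holds at most one heterozygote, and maximal supported
stretches spanning >= 100 kb become runs.  It does not reproduce the
window-hit-proportion machinery of the original tool and is tagged
"scan50" in all outputs to avoid claiming equivalence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LONG_ROH_BP = 1_000_000


@dataclass
class ROHLabeling:
    """A window table with per-window ROH labels.

    windows : DataFrame with scaffold, start, end, het_count and a boolean
        ``roh`` column (het_count <= max_het).
    """

    windows: pd.DataFrame
    max_het_per_window: int = 0

    @property
    def f_roh(self) -> float:
        return float(self.windows["roh"].mean())

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def window_roh(windows: pd.DataFrame, max_het: int = 0) -> ROHLabeling:
    """Label windows with at most ``max_het`` heterozygous sites as ROH."""
    if len(windows) == 0:
        raise ValueError("zero windows")
    out = windows.copy()
    out["roh"] = out["het_count"] <= max_het
    return ROHLabeling(out, max_het)


def merge_runs(labeling: ROHLabeling, method: str = "window100k"
               ) -> pd.DataFrame:
    """Merge consecutive ROH windows into maximal runs.

    Runs never cross scaffold boundaries; the summed run length equals the
    number of labelled windows times the window size.
    """
    rows = []
    for scaf, grp in labeling.windows.groupby("scaffold", sort=False):
        g = grp.sort_values("start")
        lab = g["roh"].to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        i = 0
        while i < len(lab):
            if lab[i]:
                j = i
                while j + 1 < len(lab) and lab[j + 1] and ends[j] == starts[j + 1]:
                    j += 1
                rows.append((scaf, int(starts[i]), int(ends[j])))
                i = j + 1
            else:
                i += 1
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    df["length"] = df["end"] - df["start"]
    df["method"] = method
    return df


def scan_roh(calls: pd.DataFrame, snp_window: int = 50,
             max_het_in_window: int = 1, min_run_bp: int = 100_000
             ) -> pd.DataFrame:
    """Scanning-window ROH over called variant sites ("scan50").

    ``calls`` needs columns scaffold, pos (0-based) and is_het, covering all
    called sites (homozygous and heterozygous).  A site is ROH-supporting
    iff some window of ``snp_window`` consecutive sites containing it has at
    most ``max_het_in_window`` heterozygotes; maximal supported stretches
    spanning at least ``min_run_bp`` become runs.  Scaffolds with fewer
    than ``snp_window`` called sites are skipped with a warning.
    """
    rows = []
    for scaf, grp in calls.groupby("scaffold", sort=False):
        g = grp.sort_values("pos")
        pos = g["pos"].to_numpy()
        h = g["is_het"].to_numpy().astype(np.int64)
        n = len(pos)
        if n < snp_window:
            warnings.warn(f"scaffold {scaf}: fewer than {snp_window} called "
                          "sites; skipped by scan_roh")
            continue
        cum = np.concatenate([[0], np.cumsum(h)])
        win_het = cum[snp_window:] - cum[:-snp_window]   # window j: sites j..j+w-1
        passing = win_het <= max_het_in_window
        # a site is supported iff covered by >= 1 passing window
        cover = np.zeros(n + 1, dtype=np.int64)
        idx = np.flatnonzero(passing)
        np.add.at(cover, idx, 1)
        np.add.at(cover, idx + snp_window, -1)
        supported = np.cumsum(cover[:-1]) > 0
        # maximal supported stretches
        edges = np.flatnonzero(np.diff(np.concatenate([[0], supported.view(np.int8),
                                                       [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            start, end = int(pos[a]), int(pos[b - 1]) + 1
            if end - start >= min_run_bp:
                rows.append((scaf, start, end))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    df["length"] = df["end"] - df["start"]
    df["method"] = "scan50"
    return df


@dataclass
class LengthSpectrum:
    """Cumulative genome fraction in ROH, by run length."""

    lengths: np.ndarray           # sorted run lengths, bp
    cumulative_fraction: np.ndarray
    genome_length: int
    short_fraction: float         # runs <= long_threshold
    long_fraction: float          # runs > long_threshold
    long_threshold: int = LONG_ROH_BP


def length_spectrum(runs: pd.DataFrame, genome_length: int,
                    long_threshold: int = LONG_ROH_BP) -> LengthSpectrum:
    """Cumulative fraction-in-ROH versus run length, with the 1-Mb split.

    The cumulative curve at length L is the genome fraction in runs of
    length <= L; it is non-decreasing and ends at the total F-by-length.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if len(runs) == 0:
        return LengthSpectrum(np.array([]), np.array([]), genome_length,
                              0.0, 0.0, long_threshold)
    lengths = np.sort(runs["length"].to_numpy())
    cum = np.cumsum(lengths) / genome_length
    short = float(lengths[lengths <= long_threshold].sum() / genome_length)
    longf = float(lengths[lengths > long_threshold].sum() / genome_length)
    return LengthSpectrum(lengths, cum, genome_length, short, longf,
                          long_threshold)


def compare_methods(f_estimates: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Pearson correlations of F estimates across individuals.

    ``f_estimates`` is indexed by individual with one column per method.
    Needs at least 3 individuals; a constant method yields NaN correlations.
    Returns (correlation matrix, per-method means).
    """
    if len(f_estimates) < 3:
        raise ValueError("compare_methods needs at least 3 individuals")
    return f_estimates.corr(method="pearson"), f_estimates.mean()
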