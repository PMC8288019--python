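"""Half-open integer interval arithmetic on (scaffold, start, end) frames.

All genomic intervals in this package are 0-based half-open [start, end),
stored as pandas DataFrames with at least the columns ``scaffold``, ``start``
and ``end``.  These helpers are deliberately small: the package only ever
needs merge / complement / intersection / point-membership, and each is
cross-checked against brute-force oracles in the test suite.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLS = ["scaffold", "start", "end"]


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"scaffold": pd.Series(dtype=object),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def _as_frame(scaffold, starts, ends) -> pd.DataFrame:
    return pd.DataFrame({"scaffold": scaffold,
                         "start": np.asarray(starts, dtype=np.int64),
                         "end": np.asarray(ends, dtype=np.int64)})


def validate_intervals(df: pd.DataFrame) -> None:
    """Raise ValueError on malformed (start >= end or negative) intervals."""
    if len(df) == 0:
        return
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"malformed interval {first['scaffold']}:{first['start']}-{first['end']}"
        )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping or touching intervals, per scaffold."""
    if len(df) == 0:
        return empty_intervals()
    out = []
    for scaf, grp in df.groupby("scaffold", sort=True):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy(dtype=np.int64)
        ends = g["end"].to_numpy(dtype=np.int64)
        keep_s = [starts[0]]
        keep_e = [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= keep_e[-1]:
                keep_e[-1] = max(keep_e[-1], e)
            else:
                keep_s.append(s)
                keep_e.append(e)
        out.append(_as_frame(scaf, keep_s, keep_e))
    return pd.concat(out, ignore_index=True)


def complement(df: pd.DataFrame, scaffold_lengths: dict[str, int]) -> pd.DataFrame:
    """Complement of a set of intervals within the given scaffold lengths."""
    merged = merge_intervals(df)
    out = []
    by_scaf = dict(tuple(merged.groupby("scaffold"))) if len(merged) else {}
    for scaf, length in scaffold_lengths.items():
        if scaf not in by_scaf:
            out.append(_as_frame(scaf, [0], [length]))
            continue
        g = by_scaf[scaf]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        gap_s = np.concatenate([[0], ends])
        gap_e = np.concatenate([starts, [length]])
        keep = gap_s < gap_e
        if keep.any():
            out.append(_as_frame(scaf, gap_s[keep], gap_e[keep]))
    if not out:
        return empty_intervals()
    return pd.concat(out, ignore_index=True)


def total_length(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection of two interval sets (each merged internally first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return empty_intervals()
    out = []
    b_by = dict(tuple(b.groupby("scaffold")))
    for scaf, ga in a.groupby("scaffold"):
        if scaf not in b_by:
            continue
        gb = b_by[scaf]
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        i = j = 0
        rs, re = [], []
        while i < len(sa) and j < len(sb):
            s = max(sa[i], sb[j])
            e = min(ea[i], eb[j])
            if s < e:
                rs.append(s)
                re.append(e)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
        if rs:
            out.append(_as_frame(scaf, rs, re))
    if not out:
        return empty_intervals()
    return pd.concat(out, ignore_index=True)


def points_in_sorted(positions: np.ndarray, starts: np.ndarray,
                     ends: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in sorted disjoint [start, end) intervals."""
    positions = np.asarray(positions)
    if len(starts) == 0 or len(positions) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(positions), dtype=bool)
    inside[ok] = positions[ok] < ends[idx[ok]]
    return inside


def count_points_in(points: pd.DataFrame, intervals: pd.DataFrame) -> int:
    """Count rows of ``points`` (scaffold, pos) falling in the interval set."""
    if len(points) == 0 or len(intervals) == 0:
        return 0
    merged = merge_intervals(intervals)
    by_scaf = dict(tuple(merged.groupby("scaffold")))
    n = 0
    for scaf, grp in points.groupby("scaffold"):
        if scaf not in by_scaf:
            continue
        g = by_scaf[scaf]
        inside = points_in_sorted(grp["pos"].to_numpy(),
                                  g["start"].to_numpy(), g["end"].to_numpy())
        n += int(inside.sum())
    return n
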