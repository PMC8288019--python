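"""Variant and depth-track input/output plus the genotype filters.

The analysis treats two inputs as authoritative:

* a per-individual VCF with one called variant per site (GT, DP per genotype,
  QUAL per site), read through :func:`read_variants` into a flat record table;
* a per-individual depth track (BEDGRAPH, 0-based half-open) describing the
  read depth of *every* position, from which the callability denominator is
  derived.  Callability is a property of the depth track alone: the number of
  heterozygous sites only ever enters the numerator of a rate whose
  denominator passed the same depth filters.

Genotype filters follow a quality floor (variant quality >= 30), a depth
floor (>= 10 by default) and a depth ceiling of twice the individual's mean
genome-wide depth, applied identically to numerator sites and to the
callable-site denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, total_length

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt", "missing")

VARIANT_COLUMNS = ["scaffold", "pos", "genotype_class", "qual", "depth", "is_snp"]


@dataclass(frozen=True)
class FilterPolicy:
    """Site-level genotype filters.

    min_quality
        Minimum Phred-scaled variant quality (QUAL).
    min_depth
        Minimum read depth for a genotype (and for a position to be callable).
    max_depth_factor
        Depth ceiling expressed as a multiple of the individual's mean
        genome-wide depth; guards against collapsed repeats.
    snps_only
        Keep single-nucleotide variants only (indels are discarded).
    """

    min_quality: float = 30.0
    min_depth: int = 10
    max_depth_factor: float = 2.0
    snps_only: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_depth_factor <= 0:
            raise ValueError("max_depth_factor must be > 0")

    def max_depth(self, mean_depth: float) -> float:
        return self.max_depth_factor * mean_depth


class DepthTrack:
    """Run-length encoded per-position read depth.

    Stores one row per maximal run of constant depth: (scaffold, start, end,
    depth), 0-based half-open.  Every position of every scaffold must be
    covered exactly once (depth 0 is an explicit value, not a gap).
    """

    def __init__(self, intervals: pd.DataFrame, scaffold_lengths: dict[str, int]):
        idx = intervals.index
        if not (isinstance(idx, pd.RangeIndex) and idx.start == 0
                and idx.step == 1):
            intervals = intervals.reset_index(drop=True)
        self.intervals = intervals
        self.scaffold_lengths = dict(scaffold_lengths)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_arrays(cls, per_scaffold: dict[str, np.ndarray]) -> "DepthTrack":
        """Build a track from per-site depth arrays (RLE-compressed)."""
        rows = []
        lengths = {}
        for scaf, depths in per_scaffold.items():
            depths = np.asarray(depths)
            lengths[scaf] = len(depths)
            if len(depths) == 0:
                continue
            change = np.flatnonzero(np.diff(depths)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(depths)]])
            rows.append(pd.DataFrame({"scaffold": scaf, "start": starts,
                                      "end": ends, "depth": depths[starts]}))
        df = (pd.concat(rows, ignore_index=True) if rows else
              pd.DataFrame(columns=["scaffold", "start", "end", "depth"]))
        return cls(df, lengths)

    @classmethod
    def from_bedgraph(cls, path, scaffold_lengths: dict[str, int]) -> "DepthTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["scaffold", "start", "end", "depth"],
                         dtype={"scaffold": str})
        return cls(df, scaffold_lengths)

    # -- queries ------------------------------------------------------
    def total_sites(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def mean_depth(self) -> float:
        """Length-weighted mean depth over all covered positions."""
        if len(self.intervals) == 0:
            raise ValueError("empty depth track")
        span = (self.intervals["end"] - self.intervals["start"]).to_numpy()
        return float((span * self.intervals["depth"].to_numpy()).sum() / span.sum())

    def scaffold_mean_depth(self) -> pd.Series:
        """Per-scaffold length-weighted mean depth."""
        df = self.intervals
        w = (df["end"] - df["start"])
        tot = (w * df["depth"]).groupby(df["scaffold"]).sum()
        n = w.groupby(df["scaffold"]).sum()
        return (tot / n).rename("mean_depth")

    def depth_at(self, scaffold: str, positions: np.ndarray) -> np.ndarray:
        """Depth of the track at the given 0-based positions."""
        g = self.intervals[self.intervals["scaffold"] == scaffold]
        starts = g["start"].to_numpy()
        depths = g["depth"].to_numpy()
        idx = np.searchsorted(starts, np.asarray(positions), side="right") - 1
        if (idx < 0).any():
            raise ValueError(f"positions before track start on {scaffold}")
        return depths[idx]

    # -- output -------------------------------------------------------
    def to_bedgraph(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CallabilityTrack:
    """Positions passing the depth filters; the heterozygosity denominator.

    intervals : DataFrame (scaffold, start, end)
        Sorted, disjoint half-open callable intervals.
    min_depth : int
        The depth floor used to build the track.
    """

    intervals: pd.DataFrame
    min_depth: int
    max_depth: float = field(default=np.inf)

    def total_callable(self) -> int:
        return total_length(self.intervals)

    def per_scaffold_callable(self) -> pd.Series:
        df = self.intervals
        return ((df["end"] - df["start"]).groupby(df["scaffold"]).sum()
                .rename("callable_sites"))

    def restrict(self, scaffolds) -> "CallabilityTrack":
        """Callability restricted to a set of scaffold names."""
        keep = self.intervals["scaffold"].isin(set(scaffolds))
        return CallabilityTrack(self.intervals[keep].reset_index(drop=True),
                                self.min_depth, self.max_depth)


# ----------------------------------------------------------------------
# VCF reading / writing
# ----------------------------------------------------------------------

def read_variants(path) -> pd.DataFrame:
    """Read a single-sample VCF into a flat variant-record table.

    Returns a DataFrame with columns scaffold, pos (1-based), genotype_class,
    qual, depth, is_snp.  Raises if the VCF carries no GT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    if len(vcf.samples) != 1:
        raise ValueError(f"expected a single-sample VCF, found {len(vcf.samples)}"
                         f" samples in {path}")
    rows = []
    for v in vcf:
        gts = v.genotypes
        if not gts:
            raise ValueError(f"missing GT at {v.CHROM}:{v.POS}")
        a, b = gts[0][0], gts[0][1] if len(gts[0]) > 2 else gts[0][0]
        if a < 0 or b < 0:
            klass = "missing"
        elif a == b == 0:
            klass = "hom_ref"
        elif a == b:
            klass = "hom_alt"
        else:
            klass = "het"
        dp_arr = v.format("DP")
        dp = int(dp_arr[0][0]) if dp_arr is not None else int(v.gt_depths[0])
        rows.append((v.CHROM, v.POS, klass,
                     float(v.QUAL) if v.QUAL is not None else np.nan,
                     max(dp, 0), bool(v.is_snp)))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_FOR_CLASS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
                 "missing": "./."}
# fixed REF/ALT pairs; the downstream statistics only use positions and
# genotype classes, not the actual nucleotides
_ALLELES = {True: ("A", "T"), False: ("AT", "A")}


def write_vcf(variants: pd.DataFrame, scaffold_lengths: dict[str, int], path,
              sample: str = "sim") -> None:
    """Write a variant-record table as a minimal single-sample VCFv4.2 file."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for scaf, length in scaffold_lengths.items():
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        df = variants.sort_values(["scaffold", "pos"])
        for row in df.itertuples(index=False):
            ref, alt = _ALLELES[bool(row.is_snp)]
            gt = _GT_FOR_CLASS[row.genotype_class]
            fh.write(f"{row.scaffold}\t{row.pos}\t.\t{ref}\t{alt}\t"
                     f"{row.qual:.1f}\t.\t.\tGT:DP\t{gt}:{row.depth}\n")


def read_scaffold_table(path) -> pd.DataFrame:
    """Two-column (name, length) scaffold table, FAI-style."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["scaffold", "length"], dtype={"scaffold": str})
    return df


def write_scaffold_table(scaffold_lengths: dict[str, int], path) -> None:
    pd.DataFrame({"scaffold": list(scaffold_lengths),
                  "length": list(scaffold_lengths.values())}
                 ).to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# Filters and callability
# ----------------------------------------------------------------------

def mean_genome_depth(track: DepthTrack) -> float:
    """Length-weighted mean genome-wide depth of a track."""
    return track.mean_depth()


def filter_genotypes(records: pd.DataFrame, policy: FilterPolicy,
                     mean_depth: float) -> pd.DataFrame:
    """Apply the site filters; genotype classes are preserved.

    Retains records with qual >= min_quality, min_depth <= depth <= cap and,
    if snps_only, is_snp.  Idempotent; the result is a subset of the input.
    """
    cap = policy.max_depth(mean_depth)
    keep = ((records["qual"] >= policy.min_quality)
            & (records["depth"] >= policy.min_depth)
            & (records["depth"] <= cap))
    if policy.snps_only:
        keep &= records["is_snp"]
    return records[keep].reset_index(drop=True)


def build_callability(track: DepthTrack, policy: FilterPolicy,
                      mean_depth: float,
                      scaffold_table: pd.DataFrame) -> CallabilityTrack:
    """Positions whose track depth lies within [min_depth, cap].

    Raises if the track extends beyond the scaffold bounds of the table.
    Scaffolds absent from the table are ignored.
    """
    cap = policy.max_depth(mean_depth)
    lengths = dict(zip(scaffold_table["scaffold"], scaffold_table["length"]))
    df = track.intervals
    df = df[df["scaffold"].isin(lengths)]
    ends = df["end"].to_numpy()
    bounds = df["scaffold"].map(lengths).to_numpy()
    if (ends > bounds).any():
        bad = df[ends > bounds].iloc[0]
        raise ValueError(f"depth track exceeds scaffold bounds at "
                         f"{bad['scaffold']}:{bad['start']}-{bad['end']}")
    ok = df[(df["depth"] >= policy.min_depth) & (df["depth"] <= cap)]
    intervals = merge_intervals(ok[["scaffold", "start", "end"]])
    return CallabilityTrack(intervals, policy.min_depth, cap)


def read_exon_bed(path, gene_set: str | None = None) -> pd.DataFrame:
    """BED6 exon annotations (name = gene-set:gene:exon)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["scaffold", "start", "end", "name", "score",
                            "strand"],
                     dtype={"scaffold": str})
    out = df[["scaffold", "start", "end", "name"]].copy()
    out["gene_set"] = (gene_set if gene_set is not None
                       else out["name"].str.split(":").str[0])
    return out


def write_exon_bed(exons: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"scaffold": exons["scaffold"],
                        "start": exons["start"], "end": exons["end"],
                        "name": exons["name"], "score": 0, "strand": "+"})
    out.to_csv(path, sep="\t", header=False, index=False)


def write_filtered_bed(records: pd.DataFrame, path) -> None:
    """Filtered site list as BED3 plus a genotype-class column."""
    out = pd.DataFrame({"scaffold": records["scaffold"],
                        "start": records["pos"] - 1,
                        "end": records["pos"],
                        "genotype": records["genotype_class"]})
    out.to_csv(path, sep="\t", header=False, index=False)
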