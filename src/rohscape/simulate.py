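"""Synthetic diploid genomes with known truth.

The generator emulates the data a single-individual genome scan consumes —
a variant table (written as single-sample VCF), a read-depth track
(BEDGRAPH), exon annotations for clustered gene families (BED) and a
scaffold-length table — together with the ground truth that produced them:

* heterozygous sites are a homogeneous Poisson process at ``theta`` sites
  per Mb on non-autozygous sequence and rate 0 inside planted autozygous
  (ROH) tracts;
* ROH tract lengths come from a two-component exponential mixture (a short
  and a long class), planted per scaffold to a target genome fraction F by
  stick-breaking with flat-Dirichlet gaps;
* gene families are clustered; their exons multiply the local heterozygosity
  rate, and may be placed rejecting overlap with planted ROH to emulate
  selection against homozygosity at those loci;
* read depth is Poisson per site with a mean scaled by copy number / 2, so a
  female X carries the autosomal mean, a male X half of it and a male Y half
  of it (a female Y has depth 0);
* variant quality grows with supporting reads (QUAL ~ Normal(q_per_read * DP,
  sd)), which is what makes low-coverage genomes lose heterozygote calls
  under a fixed quality floor.

Everything is reproducible from the integer seed carried by the genome
description.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import (complement, empty_intervals, intersect,
                         merge_intervals, points_in_sorted, total_length)
from .variant_io import VARIANT_COLUMNS, DepthTrack

MB = 1_000_000

#: diploid copy number of each scaffold class, by individual sex
COPY_NUMBER = {
    "female": {"autosome": 2, "X": 2, "Y": 0},
    "male": {"autosome": 2, "X": 1, "Y": 1},
}


@dataclass(frozen=True)
class DepthModel:
    """Per-site Poisson depth model.

    ``resolution`` > 1 draws one Poisson value per ``resolution``-bp bin
    (constant within the bin); the per-site marginal distribution is
    unchanged while the emitted track stays compact for large genomes.
    """

    mean_depth: float = 30.0
    resolution: int = 1


@dataclass(frozen=True)
class GeneSetSpec:
    """A clustered gene family with a heterozygosity multiplier on its exons.

    ``het_multiplier`` scales the local heterozygous-site rate inside exons
    (>= 0; values > 1 emulate balancing selection, < 1 depressed diversity).
    ``roh_avoidance`` places clusters rejecting overlap with planted ROH.
    """

    name: str
    n_genes: int
    exons_per_gene: int
    exon_len_bp: int
    het_multiplier: float = 1.0
    n_clusters: int = 1
    roh_avoidance: bool = False
    intron_len_bp: int = 2_000
    gene_gap_bp: int = 5_000

    def gene_span(self) -> int:
        return (self.exons_per_gene * self.exon_len_bp
                + (self.exons_per_gene - 1) * self.intron_len_bp)

    def cluster_span(self) -> int:
        per = math.ceil(self.n_genes / self.n_clusters)
        return per * self.gene_span() + (per - 1) * self.gene_gap_bp


@dataclass(frozen=True)
class ScaffoldDef:
    name: str
    length: int
    sex_class: str = "autosome"  # autosome | X | Y


@dataclass(frozen=True)
class SimulatedGenomeSpec:
    """Full description of one simulated individual genome."""

    scaffolds: tuple[ScaffoldDef, ...]
    theta: float = 200.0              # het sites / Mb outside ROH
    target_f: float = 0.0             # genome fraction in planted ROH
    roh_length_mix: tuple[float, float, float] = (0.5, 500_000, 5_000_000)
    gene_sets: tuple[GeneSetSpec, ...] = ()
    depth: DepthModel | None = DepthModel()
    hom_alt_ratio: float = 0.5        # hom-alt site rate as a multiple of theta
    qual_per_read: float = 3.0
    qual_sd: float = 6.0
    sex: str = "female"
    seed: int = 0

    def validate(self) -> None:
        if not self.scaffolds:
            raise ValueError("at least one scaffold required")
        if not 0.0 <= self.target_f <= 1.0:
            raise ValueError("target_f must lie in [0, 1]")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if any(s.length <= 0 for s in self.scaffolds):
            raise ValueError("scaffold lengths must be > 0")
        if any(g.het_multiplier < 0 for g in self.gene_sets):
            raise ValueError("het_multiplier must be >= 0")
        if self.sex not in COPY_NUMBER:
            raise ValueError(f"sex must be one of {sorted(COPY_NUMBER)}")
        p_short, m_short, m_long = self.roh_length_mix
        if not 0.0 <= p_short <= 1.0 or m_short <= 0 or m_long <= 0:
            raise ValueError("invalid roh_length_mix")
        if self.target_f > 0:
            mean_mix = p_short * m_short + (1 - p_short) * m_long
            if mean_mix > max(s.length for s in self.autosomes()):
                raise ValueError("mean ROH tract length exceeds every "
                                 "autosomal scaffold; target_f unreachable")

    def autosomes(self) -> list[ScaffoldDef]:
        return [s for s in self.scaffolds if s.sex_class == "autosome"]

    def scaffold_lengths(self) -> dict[str, int]:
        return {s.name: s.length for s in self.scaffolds}


@dataclass
class SimTruth:
    """Ground truth of one simulated genome, for tests and benchmarks."""

    roh_intervals: pd.DataFrame        # scaffold, start, end (autosomes)
    true_theta: float
    true_f: float                      # realized planted fraction
    gene_truth: pd.DataFrame           # gene_set, exon_bp, het_count, rate, multiplier
    sex_labels: dict[str, str]


@dataclass
class SimulatedIndividual:
    variants: pd.DataFrame
    depth_track: DepthTrack | None
    exons: pd.DataFrame                # scaffold, start, end, name, gene_set
    scaffold_table: pd.DataFrame       # scaffold, length
    truth: SimTruth


# ----------------------------------------------------------------------
# ROH planting
# ----------------------------------------------------------------------

def _sample_tract_lengths(rng, goal: float, mix, max_len: int) -> list[int]:
    """Mixture draws until the summed length reaches ``goal`` (final clipped)."""
    p_short, m_short, m_long = mix
    lengths: list[int] = []
    total = 0.0
    while total < goal:
        mean = m_short if rng.random() < p_short else m_long
        ell = rng.exponential(mean)
        for _ in range(1000):
            if ell <= max_len:
                break
            ell = rng.exponential(mean)
        ell = min(ell, goal - total)
        ell = max(1, int(round(ell)))
        lengths.append(ell)
        total += ell
    return lengths


def _plant_roh(rng, scaffold: ScaffoldDef, target_f: float, mix,
               avoid: pd.DataFrame | None) -> pd.DataFrame:
    """Plant non-overlapping tracts on one scaffold to the target fraction.

    Stick-breaking: tract lengths are drawn first, then placed left to right
    with gaps proportional to a flat Dirichlet over the free space.  When
    ``avoid`` intervals are present the whole layout is rejected and redrawn
    if any tract overlaps them (feasible at the fractions used here).
    """
    goal = target_f * scaffold.length
    if goal < 1:
        return empty_intervals()
    for attempt in range(200):
        lengths = _sample_tract_lengths(rng, goal, mix, scaffold.length)
        free = scaffold.length - sum(lengths)
        if free < 0:  # rounding pushed past the scaffold; retry
            continue
        n = len(lengths)
        gaps = rng.dirichlet(np.ones(n + 1)) * free
        bounds = []
        pos = 0.0
        for g, ell in zip(gaps, lengths):
            pos += g
            start = int(round(pos))
            pos += ell
            end = int(round(pos))
            if end > start:
                bounds.append((start, min(end, scaffold.length)))
        df = pd.DataFrame({"scaffold": scaffold.name,
                           "start": [b[0] for b in bounds],
                           "end": [b[1] for b in bounds]})
        df = merge_intervals(df)
        if avoid is not None and len(avoid) and len(intersect(df, avoid)):
            continue
        return df
    raise ValueError(f"could not plant ROH on {scaffold.name} "
                     f"(target_f={target_f}) without overlapping "
                     "avoided intervals")


# ----------------------------------------------------------------------
# Gene clusters
# ----------------------------------------------------------------------

def _place_gene_set(rng, gs: GeneSetSpec, autosomes: list[ScaffoldDef],
                    roh: pd.DataFrame, occupied: pd.DataFrame) -> pd.DataFrame:
    span = gs.cluster_span()
    if span > max(s.length for s in autosomes):
        raise ValueError(f"gene set {gs.name!r}: cluster span {span} bp "
                         "exceeds every autosomal scaffold")
    weights = np.array([max(s.length - span, 0) for s in autosomes], float)
    if weights.sum() == 0:
        raise ValueError(f"gene set {gs.name!r}: no scaffold can hold a cluster")
    weights /= weights.sum()
    per_cluster = math.ceil(gs.n_genes / gs.n_clusters)
    rows = []
    taken = occupied
    gene_id = 0
    for c in range(gs.n_clusters):
        placed = False
        for _ in range(2000):
            scaf = autosomes[rng.choice(len(autosomes), p=weights)]
            start = int(rng.integers(0, scaf.length - span + 1))
            cand = pd.DataFrame({"scaffold": [scaf.name], "start": [start],
                                 "end": [start + span]})
            if gs.roh_avoidance and len(roh) and len(intersect(cand, roh)):
                continue
            if len(taken) and len(intersect(cand, taken)):
                continue
            placed = True
            break
        if not placed:
            raise ValueError(f"gene set {gs.name!r}: could not place cluster "
                             f"{c} (roh_avoidance={gs.roh_avoidance})")
        taken = pd.concat([taken, cand], ignore_index=True)
        pos = start
        for _g in range(per_cluster):
            if gene_id >= gs.n_genes:
                break
            for e in range(gs.exons_per_gene):
                rows.append((scaf.name, pos, pos + gs.exon_len_bp,
                             f"{gs.name}:g{gene_id}:e{e}", gs.name))
                pos += gs.exon_len_bp + gs.intron_len_bp
            pos += gs.gene_gap_bp - gs.intron_len_bp
            gene_id += 1
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "name", "gene_set"])


# ----------------------------------------------------------------------
# Main entry points
# ----------------------------------------------------------------------

def _poisson_positions(rng, intervals: pd.DataFrame, rate_per_bp: float
                       ) -> dict[str, np.ndarray]:
    """Homogeneous Poisson points on an interval set, per scaffold."""
    out: dict[str, list[np.ndarray]] = {}
    for row in intervals.itertuples(index=False):
        n = rng.poisson(rate_per_bp * (row.end - row.start))
        if n == 0:
            continue
        pos = rng.integers(row.start, row.end, size=n)
        out.setdefault(row.scaffold, []).append(pos)
    return {k: np.unique(np.concatenate(v)) for k, v in out.items()}


def simulate_diploid_genome(spec: SimulatedGenomeSpec) -> SimulatedIndividual:
    """Generate one individual's variant, depth and annotation data.

    Heterozygous sites appear at rate theta x multiplier outside planted
    ROH and rate 0 inside; homozygous-alternative sites appear at
    ``hom_alt_ratio`` x theta everywhere (an autozygous tract is homozygous,
    not necessarily reference-like).  Sex scaffolds follow copy number: no
    heterozygotes on hemizygous scaffolds, no data at copy number 0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = spec.scaffold_lengths()
    autosomes = spec.autosomes()
    auto_lengths = {s.name: s.length for s in autosomes}

    # gene clusters that must avoid ROH are placed after planting; the rest
    # before, so avoidance only ever rejects against the final ROH layout
    roh_parts = []
    for scaf in autosomes:
        roh_parts.append(_plant_roh(rng, scaf, spec.target_f,
                                    spec.roh_length_mix, None))
    roh = (pd.concat(roh_parts, ignore_index=True) if roh_parts
           else empty_intervals())

    exon_parts = []
    occupied = empty_intervals()
    for gs in spec.gene_sets:
        exons = _place_gene_set(rng, gs, autosomes, roh, occupied)
        occupied = pd.concat(
            [occupied, exons[["scaffold", "start", "end"]]], ignore_index=True)
        exon_parts.append(exons)
    all_exons = (pd.concat(exon_parts, ignore_index=True) if exon_parts else
                 pd.DataFrame(columns=["scaffold", "start", "end",
                                       "name", "gene_set"]))

    # heterozygous sites on diploid sequence outside ROH
    copy = COPY_NUMBER[spec.sex]
    diploid = [s for s in spec.scaffolds if copy[s.sex_class] == 2]
    diploid_lengths = {s.name: s.length for s in diploid}
    free = complement(roh, diploid_lengths)
    het_by_scaf = _poisson_positions(rng, free, spec.theta / MB)

    # exon multiplier: extra points for m > 1, thinning for m < 1
    for gs in spec.gene_sets:
        gexons = all_exons[all_exons["gene_set"] == gs.name]
        gfree = intersect(gexons[["scaffold", "start", "end"]], free)
        if gs.het_multiplier > 1:
            extra = _poisson_positions(
                rng, gfree, (gs.het_multiplier - 1) * spec.theta / MB)
            for scaf, pos in extra.items():
                prev = het_by_scaf.get(scaf, np.array([], dtype=np.int64))
                het_by_scaf[scaf] = np.unique(np.concatenate([prev, pos]))
        elif gs.het_multiplier < 1:
            for scaf, grp in gfree.groupby("scaffold"):
                if scaf not in het_by_scaf:
                    continue
                pos = het_by_scaf[scaf]
                inside = points_in_sorted(pos,
                                          grp["start"].to_numpy(),
                                          grp["end"].to_numpy())
                drop = inside & (rng.random(len(pos)) > gs.het_multiplier)
                het_by_scaf[scaf] = pos[~drop]

    # homozygous-alternative sites everywhere with copy number >= 1
    present = [s for s in spec.scaffolds if copy[s.sex_class] >= 1]
    present_df = pd.DataFrame({"scaffold": [s.name for s in present],
                               "start": 0,
                               "end": [s.length for s in present]})
    hom_by_scaf = _poisson_positions(
        rng, present_df, spec.hom_alt_ratio * spec.theta / MB)

    mean_depth = spec.depth.mean_depth if spec.depth else 30.0
    var_rows = []
    for s in spec.scaffolds:
        c = copy[s.sex_class]
        if c == 0:
            continue
        het = het_by_scaf.get(s.name, np.array([], dtype=np.int64))
        hom = hom_by_scaf.get(s.name, np.array([], dtype=np.int64))
        hom = hom[~np.isin(hom, het)]
        pos = np.concatenate([het, hom])
        klass = np.array(["het"] * len(het) + ["hom_alt"] * len(hom))
        order = np.argsort(pos, kind="stable")
        pos, klass = pos[order], klass[order]
        dp = rng.poisson(mean_depth * c / 2, size=len(pos))
        qual = np.clip(rng.normal(spec.qual_per_read * dp, spec.qual_sd), 1.0,
                       None)
        var_rows.append(pd.DataFrame({
            "scaffold": s.name, "pos": pos + 1,  # VCF coordinates are 1-based
            "genotype_class": klass,
            "qual": np.round(qual, 1), "depth": dp, "is_snp": True}))
    variants = (pd.concat(var_rows, ignore_index=True) if var_rows else
                pd.DataFrame(columns=VARIANT_COLUMNS))

    track = _simulate_depth_track(rng, spec) if spec.depth else None

    roh = merge_intervals(roh) if len(roh) else roh
    # planted autozygous tracts must contain no heterozygous site
    if len(roh):
        from ._intervals import count_points_in
        het_pts = pd.DataFrame(
            {"scaffold": np.concatenate(
                [np.repeat(k, len(v)) for k, v in het_by_scaf.items()])
             if het_by_scaf else np.array([], dtype=object),
             "pos": np.concatenate(list(het_by_scaf.values()))
             if het_by_scaf else np.array([], dtype=np.int64)})
        assert count_points_in(het_pts, roh) == 0
    true_f = (total_length(roh) / sum(auto_lengths.values())
              if auto_lengths else 0.0)
    gene_truth = _gene_truth(all_exons, spec, het_by_scaf)
    truth = SimTruth(
        roh_intervals=roh,
        true_theta=spec.theta,
        true_f=true_f,
        gene_truth=gene_truth,
        sex_labels={s.name: s.sex_class for s in spec.scaffolds},
    )
    scaffold_table = pd.DataFrame({"scaffold": list(lengths),
                                   "length": list(lengths.values())})
    return SimulatedIndividual(variants, track, all_exons, scaffold_table,
                               truth)


def _gene_truth(all_exons, spec, het_by_scaf) -> pd.DataFrame:
    rows = []
    for gs in spec.gene_sets:
        gexons = all_exons[all_exons["gene_set"] == gs.name]
        merged = merge_intervals(gexons[["scaffold", "start", "end"]])
        bp = total_length(merged)
        n = 0
        for scaf, grp in merged.groupby("scaffold"):
            pos = het_by_scaf.get(scaf)
            if pos is None:
                continue
            n += int(points_in_sorted(pos, grp["start"].to_numpy(),
                                      grp["end"].to_numpy()).sum())
        rows.append((gs.name, bp, n, n * MB / bp if bp else np.nan,
                     gs.het_multiplier))
    return pd.DataFrame(rows, columns=["gene_set", "exon_bp", "het_count",
                                       "rate", "multiplier"])


def _simulate_depth_track(rng, spec: SimulatedGenomeSpec) -> DepthTrack:
    model = spec.depth
    copy = COPY_NUMBER[spec.sex]
    parts = []
    for s in spec.scaffolds:
        c = copy[s.sex_class]
        if c == 0:
            parts.append(pd.DataFrame({"scaffold": [s.name], "start": [0],
                                       "end": [s.length], "depth": [0]}))
            continue
        mean = model.mean_depth * c / 2
        r = model.resolution
        n_bins = math.ceil(s.length / r)
        depths = rng.poisson(mean, size=n_bins)
        change = np.flatnonzero(np.diff(depths)) + 1
        run_start_bins = np.concatenate([[0], change])
        starts = run_start_bins * r
        ends = np.minimum(np.concatenate([change, [n_bins]]) * r, s.length)
        parts.append(pd.DataFrame({"scaffold": s.name, "start": starts,
                                   "end": ends,
                                   "depth": depths[run_start_bins]}))
    df = pd.concat(parts, ignore_index=True)
    return DepthTrack(df, spec.scaffold_lengths())


# ----------------------------------------------------------------------
# Sex-coverage simulation and depth thinning
# ----------------------------------------------------------------------

def simulate_sex_coverage(spec: SimulatedGenomeSpec, n_sites_per_scaffold: int,
                          seed: int | None = None) -> pd.DataFrame:
    """Per-scaffold mean depth of a female and a male individual.

    Depth is Poisson per site with mean scaled by copy number / 2; the
    female:male ratio concentrates at 1 for autosomes, 2 for X and 0 for Y.
    """
    if n_sites_per_scaffold <= 0:
        raise ValueError("n_sites_per_scaffold must be > 0")
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mean = spec.depth.mean_depth if spec.depth else 30.0
    rows = []
    for s in spec.scaffolds:
        f_mean = _mean_poisson(rng, mean * COPY_NUMBER["female"][s.sex_class] / 2,
                               n_sites_per_scaffold)
        m_mean = _mean_poisson(rng, mean * COPY_NUMBER["male"][s.sex_class] / 2,
                               n_sites_per_scaffold)
        rows.append((s.name, s.length, s.sex_class, f_mean, m_mean))
    return pd.DataFrame(rows, columns=["scaffold", "length", "sex_class",
                                       "female_depth", "male_depth"])


def _mean_poisson(rng, mean: float, n: int) -> float:
    if mean == 0:
        return 0.0
    return float(rng.poisson(mean, size=n).mean())


def thin_depth(track: DepthTrack, retention: float,
               seed: int | None = None) -> DepthTrack:
    """Binomially thin every site's depth (emulates genome downsampling).

    Each site's depth is replaced by a Binomial(depth, retention) draw, so
    the mean depth scales by ``retention`` and zero-depth sites stay zero.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    if retention == 1:
        return DepthTrack(track.intervals.copy(), track.scaffold_lengths)
    rng = np.random.default_rng(seed)
    arrays = {}
    for scaf, grp in track.intervals.groupby("scaffold", sort=False):
        span = (grp["end"] - grp["start"]).to_numpy()
        depths = np.repeat(grp["depth"].to_numpy(), span)
        arrays[scaf] = rng.binomial(depths, retention)
    for scaf, length in track.scaffold_lengths.items():
        if scaf not in arrays:
            arrays[scaf] = np.zeros(length, dtype=np.int64)
    return DepthTrack.from_arrays(arrays)


def thin_variants(records: pd.DataFrame, retention: float,
                  qual_per_read: float = 3.0, qual_sd: float = 6.0,
                  seed: int | None = None) -> pd.DataFrame:
    """Thin variant depths binomially and redraw QUAL from the thinned depth.

    The companion of :func:`thin_depth` for the variant table: downsampling a
    genome reduces the reads supporting each call, and the call quality is
    redrawn from the same generative law used at simulation time.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = records.copy()
    dp = rng.binomial(records["depth"].to_numpy().astype(np.int64), retention)
    out["depth"] = dp
    out["qual"] = np.round(
        np.clip(rng.normal(qual_per_read * dp, qual_sd), 1.0, None), 1)
    return out
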