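"""Heterozygosity rates: arithmetic, windows, sweeps, gene-set excess."""
import numpy as np
import pandas as pd
import pytest

from rohscape import (CallabilityTrack, FilterPolicy, HetRate, depth_sweep,
                      gene_set_het, genome_het_rate, thin_depth,
                      thin_variants, window_het_counts)
from rohscape.heterozygosity import het_sites
from rohscape.variant_io import build_callability
from conftest import brute_force_window_counts


def _call(scaffold, length, min_depth=10):
    return CallabilityTrack(pd.DataFrame(
        {"scaffold": [scaffold], "start": [0], "end": [length]}), min_depth)


def _hets(scaffold, positions):
    return pd.DataFrame({"scaffold": scaffold, "pos": np.asarray(positions)})


def test_rate_arithmetic():
    # 120 het sites over 10 Mb callable -> 12 SNPs/Mb
    assert HetRate(120, 10_000_000).rate_snps_per_mb == 12.0
    assert HetRate(0, 10_000_000).rate_snps_per_mb == 0.0
    rate = genome_het_rate(_hets("s", np.arange(120) * 50_000),
                           _call("s", 10_000_000))
    assert rate.n_het_sites == 120
    assert rate.rate_snps_per_mb == 12.0


def test_rate_fails_without_callable_sites():
    empty = CallabilityTrack(pd.DataFrame(columns=["scaffold", "start",
                                                   "end"]), 10)
    with pytest.raises(ValueError, match="callable"):
        genome_het_rate(_hets("s", [1]), empty)


def test_rate_recovers_theta_under_simulation(flat_genome):
    sim, spec = flat_genome
    table = pd.DataFrame({"scaffold": ["c1"], "length": [6_000_000]})
    call = build_callability(sim.depth_track, FilterPolicy(), 30.0, table)
    rate = genome_het_rate(het_sites(sim.variants), call)
    L = call.total_callable() / 1e6
    se = np.sqrt(spec.theta * L) / L
    assert abs(rate.rate_snps_per_mb - spec.theta) <= 3 * se


def test_rate_invariant_to_scaffold_order_and_chunking(small_genome):
    sim, _ = small_genome
    hets = het_sites(sim.variants)
    call = CallabilityTrack(pd.DataFrame(
        {"scaffold": ["s1", "s2"], "start": [0, 0],
         "end": [5_000_000, 5_000_000]}), 10)
    a = genome_het_rate(hets, call)
    shuffled = hets.sample(frac=1, random_state=0)
    b = genome_het_rate(shuffled, call)
    halves = pd.concat([hets.iloc[::2], hets.iloc[1::2]])
    c = genome_het_rate(halves, call)
    assert a == b == c


# -- windows -----------------------------------------------------------

def test_window_tiling_conventions():
    table = pd.DataFrame({"scaffold": ["a", "b"],
                          "length": [250_000, 99_999]})
    w = window_het_counts(_hets("a", [100_000]), table)
    # 250-kb scaffold -> 2 complete windows; 99,999 bp -> none
    assert len(w) == 2
    assert set(w["scaffold"]) == {"a"}
    # site at 0-based position 100,000 falls in the second window
    assert list(w["het_count"]) == [0, 1]


def test_window_counts_match_brute_force(small_genome):
    sim, spec = small_genome
    hets = het_sites(sim.variants)
    lengths = spec.scaffold_lengths()
    fast = window_het_counts(hets, sim.scaffold_table)
    slow = brute_force_window_counts(hets, lengths, 100_000)
    merged = fast.merge(slow, on=["scaffold", "start", "end"],
                        suffixes=("", "_oracle"))
    assert (merged["het_count"] == merged["het_count_oracle"]).all()


def test_window_counts_plus_remainder_conserve_total(small_genome):
    sim, spec = small_genome
    hets = het_sites(sim.variants)
    w = window_het_counts(hets, sim.scaffold_table)
    in_windows = int(w["het_count"].sum())
    covered = (w.groupby("scaffold")["end"].max()
               .reindex(spec.scaffold_lengths().keys()).fillna(0))
    in_remainder = sum(
        int((hets.loc[hets["scaffold"] == s, "pos"] >= covered[s]).sum())
        for s in spec.scaffold_lengths())
    assert in_windows + in_remainder == len(hets)


# -- depth sweep -------------------------------------------------------

def test_sweep_flat_for_uniform_depth():
    from rohscape import DepthTrack
    n = 200
    records = pd.DataFrame({
        "scaffold": "s1", "pos": np.arange(1, n + 1) * 1000,
        "genotype_class": "het", "qual": 90.0, "depth": 30, "is_snp": True})
    track = DepthTrack(pd.DataFrame(
        {"scaffold": ["s1"], "start": [0], "end": [1_000_000],
         "depth": [30]}), {"s1": 1_000_000})
    table = pd.DataFrame({"scaffold": ["s1"], "length": [1_000_000]})
    sweep = depth_sweep(records, track, FilterPolicy(), 30.0, table)
    assert sweep["rate_snps_per_mb"].nunique() == 1
    assert (np.diff(sweep["n_callable"]) <= 0).all()

    empty = records.iloc[:0]
    sweep0 = depth_sweep(empty, track, FilterPolicy(), 30.0, table)
    assert (sweep0["rate_snps_per_mb"] == 0).all()


def test_downsampling_underestimates_heterozygosity(flat_genome):
    """Thinning to 0.4x coverage loses low-confidence heterozygote calls
    faster than callable sites, so the estimated rate drops."""
    sim, spec = flat_genome
    table = pd.DataFrame({"scaffold": ["c1"], "length": [6_000_000]})
    pol = FilterPolicy()

    full = depth_sweep(sim.variants, sim.depth_track, pol, 30.0, table,
                       min_depths=[10])
    thin_track = thin_depth(sim.depth_track, 0.4, seed=99)
    thin_recs = thin_variants(sim.variants, 0.4, seed=100)
    thin_mean = thin_track.mean_depth()
    thin = depth_sweep(thin_recs, thin_track, pol, thin_mean, table,
                       min_depths=[10])
    assert (thin["rate_snps_per_mb"].iloc[0]
            < full["rate_snps_per_mb"].iloc[0])


# -- gene sets ---------------------------------------------------------

def test_gene_set_excess_worked_examples():
    """Ratio logic on published-scale rates: 2509/198 and 9018/459."""
    call = _call("s", 1_000_000)
    exons = pd.DataFrame({"scaffold": ["s"], "start": [0],
                          "end": [1_000_000]})
    rate, excess = gene_set_het(_hets("s", np.arange(2509)), exons, call,
                                reference_rate=198.0)
    assert rate.rate_snps_per_mb == 2509.0
    assert round(excess, 1) == 12.7
    _, excess2 = gene_set_het(_hets("s", np.arange(9018)), exons, call,
                              reference_rate=459.0)
    assert round(excess2, 1) == 19.6


def test_gene_set_denominator_is_callable_exon_portion():
    call = CallabilityTrack(pd.DataFrame(
        {"scaffold": ["s"], "start": [0], "end": [500]}), 10)
    exons = pd.DataFrame({"scaffold": ["s"], "start": [400], "end": [700]})
    rate, _ = gene_set_het(_hets("s", [450, 600]), exons, call)
    assert rate.n_callable_sites == 100     # only [400, 500) is callable
    assert rate.n_het_sites == 1            # the site at 600 is not callable


def test_gene_set_zero_callable_exons_fails():
    call = _call("s", 1000)
    exons = pd.DataFrame({"scaffold": ["other"], "start": [0], "end": [100]})
    with pytest.raises(ValueError, match="myset"):
        gene_set_het(_hets("s", [1]), exons, call, name="myset")


def test_simulated_multiplier_recovered_as_excess():
    from rohscape import GeneSetSpec, ScaffoldDef, SimulatedGenomeSpec, \
        simulate_diploid_genome
    gs = GeneSetSpec("fam", n_genes=80, exons_per_gene=4, exon_len_bp=500,
                     het_multiplier=5.0, n_clusters=16)
    spec = SimulatedGenomeSpec(
        scaffolds=(ScaffoldDef("s1", 40_000_000),), theta=200.0,
        target_f=0.0, gene_sets=(gs,), depth=None, seed=31)
    sim = simulate_diploid_genome(spec)
    call = _call("s1", 40_000_000)
    hets = het_sites(sim.variants)
    genome = genome_het_rate(hets, call)
    rate, excess = gene_set_het(hets, sim.exons, call,
                                reference_rate=genome.rate_snps_per_mb)
    # exon rate ~ Poisson(5*200/Mb * 160 kb): 3-SE band on the ratio
    exon_mb = rate.n_callable_sites / 1e6
    se = np.sqrt(1000 * exon_mb) / exon_mb / genome.rate_snps_per_mb
    assert abs(excess - 5.0) <= 3 * se
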