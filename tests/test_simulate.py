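"""Generator behaviour: planted truth, Poisson rates, determinism, thinning."""
import numpy as np
import pandas as pd
import pytest

from rohscape import (DepthModel, GeneSetSpec, ScaffoldDef,
                      SimulatedGenomeSpec, simulate_diploid_genome,
                      simulate_sex_coverage, thin_depth, write_vcf)
from rohscape._intervals import count_points_in
from rohscape.heterozygosity import het_sites


def _spec(**kw):
    base = dict(scaffolds=(ScaffoldDef("s1", 4_000_000),
                           ScaffoldDef("s2", 4_000_000)),
                theta=200.0, depth=None, seed=3)
    base.update(kw)
    return SimulatedGenomeSpec(**base)


def test_full_autozygosity_leaves_no_heterozygotes():
    sim = simulate_diploid_genome(_spec(target_f=1.0))
    assert (sim.variants["genotype_class"] != "het").all()
    assert sim.truth.true_f == 1.0


def test_zero_theta_zero_f_gives_empty_variant_set_but_depth():
    sim = simulate_diploid_genome(_spec(theta=0.0, target_f=0.0,
                                        depth=DepthModel(30.0, 1000)))
    assert len(sim.variants) == 0
    assert sim.depth_track is not None
    assert sim.depth_track.mean_depth() == pytest.approx(30.0, abs=1.0)


def test_het_count_matches_poisson_expectation_and_bernoulli_oracle():
    # 100 Mb at theta=200/Mb: count within 3*sqrt(20000) of 20000
    spec = _spec(scaffolds=(ScaffoldDef("big", 100_000_000),), seed=5)
    sim = simulate_diploid_genome(spec)
    n_het = int((sim.variants["genotype_class"] == "het").sum())
    assert abs(n_het - 20_000) <= 3 * np.sqrt(20_000)

    # independent per-base Bernoulli oracle on a 1-Mb instance
    rng = np.random.default_rng(12)
    oracle = int((rng.random(1_000_000) < 200 / 1e6).sum())
    sim1 = simulate_diploid_genome(
        _spec(scaffolds=(ScaffoldDef("m", 1_000_000),), seed=13))
    n1 = int((sim1.variants["genotype_class"] == "het").sum())
    # both are draws from (approximately) Poisson(200)
    assert abs(n1 - 200) <= 3 * np.sqrt(200)
    assert abs(oracle - 200) <= 3 * np.sqrt(200)


@pytest.mark.parametrize("target_f", [0.11, 0.45, 0.70])
def test_planted_roh_contains_no_het_and_realized_f_matches(target_f):
    spec = _spec(scaffolds=(ScaffoldDef("s1", 20_000_000),), target_f=target_f,
                 seed=int(target_f * 100))
    sim = simulate_diploid_genome(spec)
    hets = het_sites(sim.variants)
    assert count_points_in(hets, sim.truth.roh_intervals) == 0
    total = (sim.truth.roh_intervals["end"]
             - sim.truth.roh_intervals["start"]).sum()
    assert sim.truth.true_f == pytest.approx(total / 20_000_000)
    # stick-breaking with a clipped final tract lands on target
    mean_mix = 0.5 * 0.5e6 + 0.5 * 5e6
    assert abs(sim.truth.true_f - target_f) <= mean_mix / 20_000_000


def test_same_seed_byte_identical_outputs(tmp_path):
    spec = _spec(target_f=0.3, depth=DepthModel(30.0, 1000))
    a = simulate_diploid_genome(spec)
    b = simulate_diploid_genome(spec)
    pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_vcf(a.variants, spec.scaffold_lengths(), pa)
    write_vcf(b.variants, spec.scaffold_lengths(), pb)
    assert pa.read_bytes() == pb.read_bytes()
    pd.testing.assert_frame_equal(a.depth_track.intervals,
                                  b.depth_track.intervals)


def test_gene_multiplier_raises_exon_rate():
    gs = GeneSetSpec("fam", n_genes=60, exons_per_gene=4, exon_len_bp=500,
                     het_multiplier=5.0, n_clusters=12)
    spec = _spec(scaffolds=(ScaffoldDef("s1", 30_000_000),), theta=200.0,
                 gene_sets=(gs,), seed=21)
    sim = simulate_diploid_genome(spec)
    truth = sim.truth.gene_truth.iloc[0]
    # expected rate 1000/Mb over 120 kb of exon: 3-SE Poisson band
    expected = 5.0 * 200.0
    se = np.sqrt(expected * truth["exon_bp"] / 1e6) / (truth["exon_bp"] / 1e6)
    assert abs(truth["rate"] - expected) <= 3 * se


def test_roh_avoidance_keeps_clusters_outside_roh():
    gs = GeneSetSpec("fam", n_genes=40, exons_per_gene=4, exon_len_bp=150,
                     het_multiplier=1.0, n_clusters=16, roh_avoidance=True)
    spec = _spec(scaffolds=(ScaffoldDef("s1", 10_000_000),
                            ScaffoldDef("s2", 10_000_000)),
                 target_f=0.45, gene_sets=(gs,), seed=8)
    sim = simulate_diploid_genome(spec)
    from rohscape._intervals import intersect
    overlap = intersect(sim.exons[["scaffold", "start", "end"]],
                        sim.truth.roh_intervals)
    assert len(overlap) == 0


def test_unreachable_target_f_fails():
    spec = SimulatedGenomeSpec(scaffolds=(ScaffoldDef("tiny", 100_000),),
                               theta=100.0, target_f=0.5, depth=None)
    with pytest.raises(ValueError, match="unreachable"):
        spec.validate()


def test_oversized_gene_cluster_fails():
    gs = GeneSetSpec("huge", n_genes=500, exons_per_gene=10,
                     exon_len_bp=1_000, n_clusters=1)
    spec = _spec(gene_sets=(gs,))
    with pytest.raises(ValueError, match="exceeds every"):
        simulate_diploid_genome(spec)


# -- sex coverage ------------------------------------------------------

def test_sex_coverage_ratios_concentrate_at_copy_number():
    spec = SimulatedGenomeSpec(
        scaffolds=(ScaffoldDef("a", 100_000), ScaffoldDef("x", 100_000, "X"),
                   ScaffoldDef("y", 100_000, "Y")),
        depth=DepthModel(30.0), seed=2)
    cov = simulate_sex_coverage(spec, n_sites_per_scaffold=10_000, seed=2)
    cov = cov.set_index("sex_class")
    ratio = cov["female_depth"] / cov["male_depth"]
    se_x = np.sqrt(30 / 10_000) / 15 * 2  # delta-method SE of the X ratio
    assert abs(ratio["X"] - 2.0) <= 3 * se_x * 2
    assert ratio["Y"] == 0.0
    assert cov.loc["Y", "female_depth"] == 0.0
    assert ratio["autosome"] == pytest.approx(1.0, abs=0.05)


def test_sex_coverage_zero_sites_fails():
    spec = _spec()
    with pytest.raises(ValueError):
        simulate_sex_coverage(spec, 0)


# -- depth thinning ----------------------------------------------------

def test_thin_depth_identity_mean_and_zeros(flat_genome):
    sim, spec = flat_genome
    track = sim.depth_track
    same = thin_depth(track, 1.0)
    pd.testing.assert_frame_equal(same.intervals, track.intervals)

    half = thin_depth(track, 0.5, seed=4)
    n = track.total_sites()
    se = np.sqrt(30 * 0.5 / n)  # variance of a thinned-Poisson mean
    assert abs(half.mean_depth() - 15.0) <= 3 * se * 3
    # zero-depth sites stay zero (female Y is all zero by construction)
    yspec = SimulatedGenomeSpec(scaffolds=(ScaffoldDef("y", 50_000, "Y"),),
                                sex="female", seed=0)
    ytrack = simulate_diploid_genome(yspec).depth_track
    thinned = thin_depth(ytrack, 0.3, seed=1)
    assert (thinned.intervals["depth"] == 0).all()


def test_thin_depth_rejects_bad_retention(flat_genome):
    sim, _ = flat_genome
    for r in (0.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            thin_depth(sim.depth_track, r)
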