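"""Simulate one diploid genome with planted ROH and inspect its truth.

Builds a 20-Mb two-scaffold genome with 45% of its length in autozygous
tracts, heterozygous sites at 200 SNPs/Mb elsewhere, and per-site Poisson
read depth, then prints what was planted.
"""
from rohscape import (DepthModel, ScaffoldDef, SimulatedGenomeSpec,
                      simulate_diploid_genome)

spec = SimulatedGenomeSpec(
    scaffolds=(ScaffoldDef("sc1", 10_000_000), ScaffoldDef("sc2", 10_000_000)),
    theta=200.0,            # heterozygous sites per Mb outside ROH
    target_f=0.45,          # genome fraction in planted ROH
    depth=DepthModel(30.0, resolution=1000),
    seed=1)
sim = simulate_diploid_genome(spec)

n_het = (sim.variants["genotype_class"] == "het").sum()
print(f"planted ROH fraction (truth): {sim.truth.true_f:.4f}")
print(f"planted tracts: {len(sim.truth.roh_intervals)}")
print(f"heterozygous sites emitted: {n_het} "
      f"(expectation ~ theta x non-ROH Mb = {200 * 20 * 0.55:.0f})")
print(f"mean track depth: {sim.depth_track.mean_depth():.2f} (model: 30)")
# The variant table, depth track, exon BED and scaffold table can be written
# with write_vcf / DepthTrack.to_bedgraph / write_exon_bed /
# write_scaffold_table for use by the pipeline or external tools.
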