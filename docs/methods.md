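# Methods

## Setting and quantities

`rohscape` analyses one diploid genome at a time. The two central
quantities are the **heterozygosity rate** — heterozygous sites per million
callable bases, with the numerator and denominator passing identical depth
and quality filters — and the **genomic inbreeding coefficient**
`F_ROH` — the fraction of the autosomal genome lying in runs of
homozygosity (ROH), segments where the two haplotypes are identical by
descent. Short runs (<= 1 Mb) mostly record old population bottlenecks;
long runs (> 1 Mb) record inbreeding in the last few generations, because
recombination has not yet broken them up.

## Filters and the callability denominator

A genotype is kept when its variant quality is at least `min_quality`
(default 30, Phred scale), its depth lies in
`[min_depth, max_depth_factor x mean depth]` (defaults 10 and 2.0 — the
ceiling guards against collapsed repeats attracting paralogous reads), and
it is a SNP. The denominator is built from the depth track alone: a
position is callable iff its depth passes the same floor and ceiling.
Variant quality has no denominator analogue — per-position confidence of
*not* having a variant is not available from a variant-only file — which
is the one intended asymmetry between numerator and denominator (see
"Coverage and underestimation" below).

Scaffold-length thresholds: > 40 kb for calling-based statistics, > 100 kb
for ROH (windows need room); both are configurable because reasonable
pipelines differ here.

## Sex-linked scaffolds

With one female and at least one male at comparable autosomal depth, the
per-scaffold female:male mean-depth ratio separates into three groups by
copy number: ~1 (autosome 2:2), ~2 (X 2:1) and ~0 (Y 0:1). Scaffolds with
a ratio in the closed interval [0, 0.04] are labelled Y, in [1.5, 2.5] X,
and everything else autosomal (the residual class; a ratio of +inf from a
zero male depth also lands there, with a warning). With several males the
per-male classifications must be unanimous; disagreements fall back to
autosome with a warning. At 30x depth and >= 40 kb scaffolds the sampling
noise of the ratio is far smaller than the gaps between groups, so
misclassification is negligible.

## ROH callers

**Window method.** Complete, non-overlapping 100-kb windows tile each
scaffold from coordinate 0 (partial terminal windows are dropped). A
window is ROH iff it contains at most `max_het` heterozygous sites
(default 0); `F_ROH` is the labelled share of windows. No per-window
callable fraction is required, but the fraction is emitted so users can
post-filter.

**scan50.** A deliberately simplified emulation of site-count scanning
callers: over the sorted called sites (homozygous and heterozygous), a
site supports ROH iff at least one window of 50 consecutive sites
containing it has <= 1 heterozygote; maximal supported stretches spanning
>= 100 kb become runs. The window-hit-proportion machinery of the
original tools is intentionally not reproduced, and outputs are tagged
`scan50` so no equivalence is claimed. Because its unit is *sites*, its
effective genomic resolution degrades in low-diversity genomes; on sparse
scaffolds (< 50 called sites) it skips with a warning.

The two methods are compared across individuals by Pearson correlation of
their F estimates, not by their absolute levels, which depend on
parameter conventions. The report schema keeps per-method columns so
externally computed estimates (e.g. HMM-based callers) can sit alongside.

### Known bias of the window method

Zero-heterozygote windows conflate autozygosity with low diversity. At
background rate θ (SNPs/Mb) a non-ROH window of size w is labelled ROH
with probability `e^{-θw}` (negligible for θ >= 200, substantial for
θ ~ 12 — the demo's least diverse genome overestimates F for exactly this
reason). Conversely each true tract boundary falls inside a window whose
non-autozygous remainder usually carries a heterozygote, so roughly one
window per tract is lost: the estimator is biased downward by about
`0.9 x w x F / mean tract length` for θ around 200. With ~2.75-Mb mean
tracts this is ≈ 0.005 at F = 0.11 and grows to ≈ 0.028 at F = 0.70 —
worth remembering when comparing highly inbred genomes.

## Exon-in-ROH deficiency test

Each exon is assigned to the window containing its midpoint (deterministic
and counted once; an "any overlap" rule would double-count
boundary-spanning exons — it is available behind a flag of the assignment
for sensitivity work). The observed statistic is the share of assigned
exons in ROH windows; its expectation under no association is `F_ROH`.
The null shuffles the ROH/non-ROH labels uniformly over windows, keeping
the ROH count fixed, 1,000 times; exons clustered in one window move
together, which correctly widens the null for clustered families. The
p-value is one-sided (deficiency) with the add-one correction
`p = (1 + #{replicates <= observed}) / (n + 1)`, so it is valid and never
zero. Replicates are seeded per (individual, gene set) from the run seed.
No multiple-testing correction is applied across gene sets; per-set
p-values are reported side by side.

## Synthetic genomes

The generator's purpose is statistical, not sequence-level realism: it
emulates exactly the objects the estimators consume.

- **Heterozygous sites** are a homogeneous Poisson process at rate θ
  outside planted ROH and 0 inside. No linkage disequilibrium is
  modelled — the downstream statistics use positions only.
- **ROH tracts** come from a two-component exponential mixture,
  `p_short = 0.5`, means 0.5 Mb and 5 Mb, mimicking the short/long
  dichotomy while staying analytically tractable (the populations the
  package targets have no known tract-length law; these are modelling
  choices). Tracts are drawn per scaffold until the target fraction F is
  met, the final draw clipped to the deficit, and placed with
  flat-Dirichlet gaps, so realized F equals the target almost exactly and
  the truth table records it.
- **Gene families** are clustered (genes laid out head-to-tail with fixed
  exon/intron geometry); exons multiply the local heterozygosity rate.
  With `roh_avoidance` the clusters are placed rejecting any overlap with
  planted ROH — emulating selection against homozygosity at those loci.
  Each simulated individual gets its own placement, which is a synthetic
  simplification: a real cohort shares one annotation, and the pipeline
  accepts either a shared exon BED or per-individual ones.
- **Depth** is Poisson per site with mean scaled by copy number/2
  (female X two copies, male X and Y one, female Y zero). For large
  genomes the track can be drawn per `resolution`-bp bin (one Poisson
  value per bin) — the per-site marginal is unchanged, only within-bin
  correlation is introduced, and the emitted BEDGRAPH stays compact.
  There is no mapping-bias or error model.
- **Variant records** are emitted for heterozygous sites plus homozygous-
  alternative sites at 0.5 x θ everywhere (autozygous tracts are
  homozygous, not reference-like), so the discard-homozygotes step is
  exercised and scan50 has called sites inside ROH. Variant quality is
  drawn as `Normal(3.0 x DP, 6)` (clipped at 1): call confidence grows
  with supporting reads, at roughly 30 Phred per 10 reads.

What passing tests on these genomes do **not** show: robustness to
alignment artefacts, LD structure, genotype-likelihood miscalibration, or
reference bias. They do show that the estimators recover planted truth
under the stated stochastic model.

## Coverage and underestimation

`thin_depth` replaces each site's depth with a `Binomial(depth,
retention)` draw; `thin_variants` does the same for record depths and
re-draws QUAL from the generative law above. Because the depth floor and
ceiling apply symmetrically to numerator and denominator, thinning alone
is rate-neutral in expectation; the underestimation seen in downsampled
real genomes enters through the quality floor, which prunes only the
numerator once call qualities shrink with depth. This is the mechanism
the simulator reproduces, and it also drives the directional fact that
downsampling never decreases window-method F (lost heterozygotes can only
empty windows).

## Pedigree simulation

Founder haplotypes carry unique allele labels; gametes are formed with a
Poisson number of crossovers (no interference — standard at this scale)
at uniform genetic positions. An offspring's realized autozygosity is the
physical fraction of the genome where maternal and paternal labels
coincide. Offspring are drawn from independent families so the sample
mean converges to the pedigree expectation (0.25 for full sibs, 0.5 for
selfing a non-inbred founder); within one family the mean would converge
to that pair's realized kinship instead. Physical position is linear in
genetic position per chromosome; a 0-Morgan chromosome behaves as a
single locus.

## Numerical conventions and degenerate inputs

All intervals are 0-based half-open; VCF positions convert on input.
Windows anchor at coordinate 0 (no offset scanning). Rates are reported
to the integer above 100 SNPs/Mb and one decimal below. Runs never cross
scaffold boundaries. Ties: a run length of exactly 1 Mb counts as short;
classification ranges are closed at both ends. Degenerate inputs fail
loudly with the offending object named: empty depth tracks, zero callable
sites, zero assigned exons, malformed intervals, unreachable target F
(mean tract longer than every scaffold), oversized gene clusters, empty
chromosome maps. Empty *results* (no autosomal scaffolds, no runs) warn
instead of failing.

## Problem sizes used in the test suite

The suite simulates genomes of 4–100 Mb; estimator-recovery checks use a
single 100-Mb scaffold (1,000 windows) with three replicates per
condition, the permutation-calibration check uses 500 small (10-Mb)
genomes with 1,000 permutations each, and pedigree checks use 2,000
offspring at 10 Morgans. These sizes put Monte-Carlo error well below
each assertion's tolerance while keeping the default run on one CPU in a
few minutes.
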